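"""Parsimony and reproducibility machinery on top of the CV grid.

Given the aggregates of the iterated-CV sweep, this module

1. restricts the tuning grid to the bounded region
   B = {(α, λ) | mean active count ≤ p1, mean AUC ≥ q1} (defaults 75, 0.90);
2. at every point of B computes the strength threshold ξ — the empirical
   top-τ_S (default 10%) cut of the feature-wise mean |coefficient| — and
   the strong set S(α, λ) of features at or above it;
3. forms the consistency set C of features belonging to S(α, λ) in at least
   τ_C (default 90%) of the points of B, reporting per-feature strength and
   selection-rate percentages and the direction of effect;
4. searches for minimal feature subsets of C that perfectly separate the two
   groups.  Perfect separation is decided by a linear-feasibility program
   (with the adjustment covariates always included in the hyperplane),
   because a maximum-likelihood logistic fit diverges exactly when such a
   separator exists.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._linsep import find_strict_separator, separation_holds
from .cv import CVGridResult
from .data import CohortDesign, FeatureMatrix, InputError

__all__ = [
    "BoundedRegion",
    "SelectionReport",
    "SeparationSearchResult",
    "bounded_region",
    "strength_threshold",
    "strong_set",
    "consistency_set",
    "minimal_separating_subsets",
]


@dataclass(frozen=True)
class BoundedRegion:
    """Grid points satisfying the parsimony/accuracy bounds."""

    mask: np.ndarray  # (G,) boolean
    p1: float
    q1: float

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    @property
    def size(self) -> int:
        return int(self.mask.sum())


@dataclass
class SelectionReport:
    """Consistency set C with Table-style per-feature statistics.

    ``table`` lists every feature of the screened set, sorted by strength
    percentage: the fraction of bounded-region points at which the feature is
    in the top-τ_S by mean |coefficient| (strength_pct) or by selection
    proportion (selection_rate_pct), and the direction of its B-averaged
    mean coefficient.  ``consistency_features`` are those with
    strength_pct ≥ 100·τ_C.
    """

    table: pd.DataFrame
    consistency_features: list[str]
    tau_s: float
    tau_c: float
    region: BoundedRegion

    @property
    def n_selected(self) -> int:
        return len(self.consistency_features)

    def consistency_table(self) -> pd.DataFrame:
        return self.table[self.table["in_consistency_set"]].reset_index(drop=True)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.table.to_csv(Path(path), sep=sep, index=False)


def bounded_region(
    grid_result: CVGridResult, p1: float = 75.0, q1: float = 0.90
) -> BoundedRegion:
    """Filter grid points on mean active count ≤ p1 and mean AUC ≥ q1."""
    auc = grid_result.mean_auc
    active = grid_result.mean_active
    mask = (active <= p1) & (auc >= q1) & np.isfinite(auc)
    if not mask.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            best_auc = float(np.nanmax(auc))
            min_active = float(np.nanmin(active))
            best_auc_under_p1 = float(
                np.nanmax(np.where(active <= p1, auc, np.nan))
            ) if np.any(active <= p1) else float("nan")
        raise InputError(
            "bounded region is empty: no grid point attains "
            f"mean_active ≤ {p1} and mean AUC ≥ {q1}. Achievable frontier: "
            f"max mean AUC {best_auc:.3f} (any activity), min mean active "
            f"{min_active:.1f}, max mean AUC at ≤{p1} active "
            f"{best_auc_under_p1:.3f}. Relax p1/q1."
        )
    return BoundedRegion(mask=mask, p1=float(p1), q1=float(q1))


def strength_threshold(values: np.ndarray, tau_s: float = 0.10) -> float:
    """Empirical top-τ_S cut ξ of the per-feature statistics at one grid point.

    ξ is the smallest value such that the fraction of features with value ≥ ξ
    is as close to τ_S as ties allow without exceeding it — except under
    exact ties at ξ, which are all included (the rule uses ≥).  With p
    features and distinct values, exactly floor(τ_S · p) features pass.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise InputError(f"need at least 10 features, got {v.size}")
    if not 0 < tau_s < 1:
        raise InputError("tau_s must be in (0, 1)")
    m = max(int(math.floor(tau_s * v.size)), 1)
    return float(np.sort(v)[::-1][m - 1])


def strong_set(values: np.ndarray, tau_s: float = 0.10) -> np.ndarray:
    """Indices of features at or above the strength threshold."""
    xi = strength_threshold(values, tau_s)
    return np.flatnonzero(np.asarray(values, dtype=float) >= xi)


def consistency_set(
    grid_result: CVGridResult,
    region: BoundedRegion,
    tau_s: float = 0.10,
    tau_c: float = 0.90,
) -> SelectionReport:
    """Features consistently in the strong set across the bounded region.

    strength_pct uses the top-τ_S rule on mean |coefficient|;
    selection_rate_pct applies the same construction to the selection
    proportion (fraction of training samples with a nonzero coefficient).
    Direction is the sign of the B-averaged mean coefficient.
    """
    if region.size == 0:
        raise InputError("bounded region is empty")
    pts = region.indices
    p = len(grid_result.feature_names)
    strength_hits = np.zeros(p)
    selrate_hits = np.zeros(p)
    for g in pts:
        strength_hits[strong_set(grid_result.mean_abs_coef[g], tau_s)] += 1
        selrate_hits[strong_set(grid_result.selection_proportion[g], tau_s)] += 1
    strength_pct = 100.0 * strength_hits / pts.size
    selrate_pct = 100.0 * selrate_hits / pts.size
    mean_coef_B = grid_result.mean_coef[pts].mean(axis=0)
    direction = np.sign(mean_coef_B).astype(int)
    if np.any(direction == 0):
        warnings.warn("a feature has an exactly zero B-averaged coefficient; "
                      "its direction is reported as 0", RuntimeWarning,
                      stacklevel=2)
    in_c = strength_pct >= 100.0 * tau_c - 1e-9
    table = pd.DataFrame(
        {
            "feature": grid_result.feature_names,
            "modality": grid_result.modalities,
            "strength_pct": strength_pct,
            "selection_rate_pct": selrate_pct,
            "direction": direction,
            "in_consistency_set": in_c,
        }
    ).sort_values("strength_pct", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
    members = table.loc[table["in_consistency_set"], "feature"].tolist()
    return SelectionReport(table, members, tau_s, tau_c, region)


@dataclass
class SeparationSearchResult:
    """Outcome of the minimal separating-subset enumeration."""

    min_size: int | None        # None when no subset up to k_max separates
    subsets: list[tuple[str, ...]]
    k_max: int
    n_candidates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subset": [" + ".join(s) for s in self.subsets],
                "size": [len(s) for s in self.subsets],
            }
        )


def minimal_separating_subsets(
    X: FeatureMatrix,
    design: CohortDesign,
    feature_names: list[str] | None = None,
    k_max: int = 3,
    margin: float = 1e-6,
    max_combinations: int = 10**6,
) -> SeparationSearchResult:
    """Enumerate the smallest feature subsets achieving perfect separation.

    For k = 1..k_max all subsets of the candidate features are tested; a
    subset separates iff a strict linear separator exists in the space of
    (subset features + adjustment covariates + intercept), decided by linear
    feasibility on column-normalized data.  All subsets at the minimal
    separating size are returned (and none below it exist by construction).
    Every reported subset is re-checked for strict separation on the raw
    (unnormalized) data.
    """
    if feature_names is None:
        feature_names = list(X.feature_names)
    if not feature_names:
        raise InputError("no candidate features supplied")
    idx = [X.feature_names.index(f) for f in feature_names]
    y = design.labels
    Z = design.covariate_matrix()
    q = 0 if Z is None else Z.shape[1]

    def normalize(cols: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        c = cols.mean(axis=0)
        s = cols.std(axis=0)
        s = np.where(s == 0, 1.0, s)
        return (cols - c) / s, c, s

    Zn = None
    Zc = Zs = None
    if q:
        Zn, Zc, Zs = normalize(Z)
    Fn, Fc, Fs = normalize(X.values[:, idx])

    for k in range(1, k_max + 1):
        n_comb = math.comb(len(idx), k)
        if n_comb > max_combinations:
            raise InputError(
                f"{n_comb} subsets of size {k} exceed the enumeration guard "
                f"of {max_combinations}; restrict the candidate set"
            )
        found: list[tuple[str, ...]] = []
        for combo in itertools.combinations(range(len(idx)), k):
            cols = Fn[:, combo]
            design_cols = np.column_stack([cols, Zn]) if q else cols
            ok, w, b = find_strict_separator(design_cols, y, margin)
            if not ok:
                continue
            # map the separator back to raw coordinates and re-check strict
            # separation on the unnormalized data
            centers = np.concatenate([Fc[list(combo)], Zc]) if q else Fc[list(combo)]
            scales = np.concatenate([Fs[list(combo)], Zs]) if q else Fs[list(combo)]
            w_raw = w / scales
            b_raw = b - float(np.sum(w * centers / scales))
            raw_cols = X.values[:, [idx[i] for i in combo]]
            raw_design = np.column_stack([raw_cols, Z]) if q else raw_cols
            if not separation_holds(raw_design, y, w_raw, b_raw):
                warnings.warn(
                    "LP found a separator that failed the strict recheck; "
                    "subset dropped", RuntimeWarning, stacklevel=2,
                )
                continue
            found.append(tuple(feature_names[i] for i in combo))
        if found:
            return SeparationSearchResult(k, found, k_max, len(feature_names))
    return SeparationSearchResult(None, [], k_max, len(feature_names))
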