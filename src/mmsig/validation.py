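"""Robustness analyses: null randomization and screening-within-CV.

Two checks guard against inflated accuracy and against leakage from running
univariate screening outside the cross-validation loop:

* the **null randomization experiment** permutes the group labels (group
  sizes preserved), reruns the iterated-CV sweep, and verifies that the mean
  held-out AUC is at chance — the ROC should track the 45° line;
* the **screening sensitivity analysis** recomputes plain (non-bootstrap)
  univariate screening inside each of the 200 CV training samples of the
  primary run and compares the features passing the 75% rule with the
  primary consistency set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cv import CVConfig, CVGridResult, TuningGrid, run_iterated_cv
from .data import CohortDesign, FeatureMatrix, InputError
from .enet import EnetSpec
from .screening import ScreeningConfig, _pvalues_matrix

__all__ = [
    "NullExperimentResult",
    "SensitivityResult",
    "null_randomization",
    "cv_screening_sensitivity",
]


@dataclass
class NullExperimentResult:
    """Per-repeat chance-level AUCs and the verdict against 0.5."""

    per_repeat_mean_auc: np.ndarray   # grid-averaged mean AUC per permutation
    per_repeat_best_auc: np.ndarray   # grid-maximum mean AUC per permutation
    all_iteration_aucs: np.ndarray    # pooled per-iteration AUCs, all repeats
    n_repeats: int
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_repeat_mean_auc))

    def confidence_interval(self, z: float = 1.96) -> tuple[float, float]:
        m = self.mean_auc
        se = float(np.std(self.per_repeat_mean_auc, ddof=1)
                   / np.sqrt(self.n_repeats)) if self.n_repeats > 1 else 0.0
        return m - z * se, m + z * se

    @property
    def chance_level(self) -> bool:
        lo, hi = self.confidence_interval()
        return lo <= 0.5 <= hi

    def verdict(self) -> str:
        lo, hi = self.confidence_interval()
        status = "consistent with chance" if self.chance_level else \
            "NOT consistent with chance — possible leakage"
        return (f"null randomization: mean AUC {self.mean_auc:.3f} "
                f"(95% CI {lo:.3f}–{hi:.3f}) over {self.n_repeats} "
                f"permutations; {status}")


@dataclass
class SensitivityResult:
    """Per-feature pass counts over the CV training samples."""

    pass_counts: np.ndarray      # of n_training_samples
    n_training_samples: int
    pass_mask: np.ndarray        # counts ≥ pass_proportion rule
    feature_names: list[str]
    pass_proportion: float
    overlap_with_primary: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "pass_count": self.pass_counts,
                "pass_fraction": self.pass_counts / self.n_training_samples,
                "passes": self.pass_mask,
            }
        )


def null_randomization(
    X: FeatureMatrix,
    design: CohortDesign,
    grid: TuningGrid,
    cv_cfg: CVConfig | None = None,
    enet_spec: EnetSpec | None = None,
    n_repeats: int = 20,
    seed: int = 0,
    n_jobs: int = 1,
) -> NullExperimentResult:
    """Rerun the iterated-CV sweep on permuted labels, n_repeats times.

    Each repeat permutes the label vector once (preserving the group sizes)
    and reruns the full iterated CV; per-repeat summaries are the grid-mean
    and grid-max of the mean AUC.  Deterministic under ``seed``.
    """
    cv_cfg = cv_cfg or CVConfig()
    mean_aucs = np.empty(n_repeats)
    best_aucs = np.empty(n_repeats)
    all_iter: list[np.ndarray] = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(rep,))
        )
        perm_labels = rng.permutation(design.labels)
        perm_design = CohortDesign(
            perm_labels,
            design.covariates.copy() if design.covariates is not None else None,
            list(design.subject_ids),
        )
        res = run_iterated_cv(
            X, perm_design, grid,
            CVConfig(
                n_iter=cv_cfg.n_iter, k=cv_cfg.k,
                seed=cv_cfg.seed + rep + 1,
                stratified=cv_cfg.stratified, pooling=cv_cfg.pooling,
                standardize_mode=cv_cfg.standardize_mode,
            ),
            enet_spec, n_jobs=n_jobs, store_scores=False,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_aucs[rep] = float(np.nanmean(res.mean_auc))
            best_aucs[rep] = float(np.nanmax(res.mean_auc))
        all_iter.append(res.auc_per_iter[np.isfinite(res.auc_per_iter)].ravel())
    return NullExperimentResult(
        per_repeat_mean_auc=mean_aucs,
        per_repeat_best_auc=best_aucs,
        all_iteration_aucs=np.concatenate(all_iter) if all_iter else np.array([]),
        n_repeats=n_repeats,
        seed=seed,
    )


def cv_screening_sensitivity(
    X: FeatureMatrix,
    design: CohortDesign,
    cv_result: CVGridResult,
    screening_cfg: ScreeningConfig | None = None,
    primary_selection: list[str] | None = None,
    expected_seed: int | None = None,
) -> SensitivityResult:
    """Univariate screening inside each CV training sample of the primary run.

    Uses the fold assignments stored on ``cv_result`` (the same 200 training
    samples as the elastic-net stage); no bootstrap is run inside the folds.
    A feature passes when its plain univariate p-value beats its modality
    threshold in at least ``pass_proportion`` of the training samples.
    """
    cfg = screening_cfg or ScreeningConfig()
    if expected_seed is not None and expected_seed != cv_result.seed:
        raise InputError(
            f"fold seed mismatch: primary CV used seed {cv_result.seed}, "
            f"expected {expected_seed}"
        )
    if not np.array_equal(cv_result.labels, design.labels):
        raise InputError("cv_result labels do not match the supplied design")
    folds = cv_result.fold_assignments
    y = design.labels.astype(float)
    Z = design.covariate_matrix() if cfg.adjust_covariates else None
    p0 = cfg.p0_for(X.modalities)
    counts = np.zeros(X.n_features, dtype=int)
    n_samples = 0
    k = int(folds.max()) + 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for it in range(folds.shape[0]):
            for f in range(k):
                train = folds[it] != f
                pvals, _ = _pvalues_matrix(
                    X.values[train], y[train],
                    None if Z is None else Z[train], cfg.test_kind,
                )
                counts += pvals < p0
                n_samples += 1
    need = int(np.ceil(cfg.pass_proportion * n_samples - 1e-9))
    mask = counts >= need
    overlap = None
    if primary_selection is not None:
        passing = {X.feature_names[j] for j in np.flatnonzero(mask)}
        primary = set(primary_selection)
        overlap = {
            "n_primary": len(primary),
            "n_passing": len(passing),
            "n_overlap": len(primary & passing),
            "primary_not_passing": sorted(primary - passing),
        }
    return SensitivityResult(
        pass_counts=counts,
        n_training_samples=n_samples,
        pass_mask=mask,
        feature_names=list(X.feature_names),
        pass_proportion=cfg.pass_proportion,
        overlap_with_primary=overlap,
    )
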