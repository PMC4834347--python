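"""Iterated two-fold cross-validation over an elastic-net tuning grid.

The design: at every (α, λ) on the grid, subjects are randomly
halved, the model is fitted on one half and applied to the other, the halves
are swapped, and the two held-out probability vectors are pooled into one
ROC/AUC per iteration.  With 100 iterations of two folds this yields 200
training samples per grid point.  Per-feature coefficient statistics (mean
|β|, selection proportion, mean sign) are aggregated over those 200 fits.

Fold assignment is stratified by class by default so every training half is
estimable; each iteration derives its random state from the master seed and
the iteration index only, so results are independent of scheduling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats
from sklearn.metrics import roc_curve

from .data import CohortDesign, FeatureMatrix, InputError, write_json, read_json
from .enet import ElasticNetLogistic, EnetSpec, standardize

__all__ = [
    "TuningGrid",
    "CVConfig",
    "CVGridResult",
    "make_fold_iterations",
    "roc_auc",
    "run_iterated_cv",
    "average_roc",
]


@dataclass(frozen=True)
class TuningGrid:
    """Cartesian grid of elastic-net tuning parameters.

    ``from_spec`` builds the canonical construction: ``n_alpha`` evenly
    spaced mixing values on [0, 1] and a log-spaced λ ladder with
    ``points_per_decade`` points per decade, endpoints inclusive, so the λ
    count is points_per_decade × decades + 1 (151 for 10⁻⁵…10¹ at 25 per
    decade).
    """

    alphas: tuple[float, ...]
    lams: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.alphas or not self.lams:
            raise InputError("grid must be non-empty")
        if any(not 0 <= a <= 1 for a in self.alphas):
            raise InputError("alphas must lie in [0, 1]")
        if any(l <= 0 for l in self.lams):
            raise InputError("lams must be positive")

    @classmethod
    def from_spec(
        cls,
        n_alpha: int = 51,
        lam_min: float = 1e-5,
        lam_max: float = 10.0,
        points_per_decade: int = 25,
    ) -> "TuningGrid":
        decades = math.log10(lam_max / lam_min)
        n_lam = round(points_per_decade * decades) + 1
        alphas = np.linspace(0.0, 1.0, n_alpha)
        lams = np.logspace(math.log10(lam_min), math.log10(lam_max), n_lam)
        return cls(tuple(alphas.tolist()), tuple(lams.tolist()))

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.alphas), len(self.lams)

    @property
    def n_points(self) -> int:
        return len(self.alphas) * len(self.lams)

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """(alpha, lam) of every grid point, flattened row-major by alpha."""
        a, l = np.meshgrid(self.alphas, self.lams, indexing="ij")
        return a.ravel(), l.ravel()


@dataclass(frozen=True)
class CVConfig:
    n_iter: int = 100
    k: int = 2
    seed: int = 0
    stratified: bool = True
    pooling: str = "iteration"  # one ROC per iteration; "fold" averages per-fold AUC
    standardize_mode: str = "train"  # or "global" (single full-sample standardization)

    def __post_init__(self) -> None:
        if self.pooling not in ("iteration", "fold"):
            raise InputError(f"unknown pooling {self.pooling!r}")
        if self.standardize_mode not in ("train", "global"):
            raise InputError(f"unknown standardize_mode {self.standardize_mode!r}")


def make_fold_iterations(
    labels: np.ndarray,
    n_iter: int = 100,
    k: int = 2,
    seed: int = 0,
    stratified: bool = True,
) -> np.ndarray:
    """Random k-way fold assignments, one row per iteration.

    Stratified assignment keeps per-fold class counts within one of each
    other (e.g. 14 cases + 7 controls in each fold of a 28/14 cohort).
    """
    y = np.asarray(labels)
    n = y.size
    if n < 2 * k:
        raise InputError(f"need at least {2 * k} subjects for k={k}")
    if stratified:
        for cls in np.unique(y):
            if np.sum(y == cls) < k:
                raise InputError(f"class {cls} too small to stratify into {k} folds")
    out = np.empty((n_iter, n), dtype=np.int64)
    for it in range(n_iter):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(it,))
        )
        fold = np.empty(n, dtype=np.int64)
        if stratified:
            for cls in np.unique(y):
                idx = rng.permutation(np.flatnonzero(y == cls))
                for f, part in enumerate(np.array_split(idx, k)):
                    fold[part] = f
        else:
            idx = rng.permutation(n)
            for f, part in enumerate(np.array_split(idx, k)):
                fold[part] = f
        out[it] = fold
    return out


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank (Mann–Whitney) formulation; ties contribute ½."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise InputError("both classes must be present to compute AUC")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def average_roc(
    curves: list[tuple[np.ndarray, np.ndarray]], n_grid: int = 101
) -> tuple[np.ndarray, np.ndarray]:
    """Vertical (TPR) average of step ROC curves on a fixed FPR grid."""
    if not curves:
        raise InputError("need at least one ROC curve")
    fpr_grid = np.linspace(0.0, 1.0, n_grid)
    tprs = np.empty((len(curves), n_grid))
    for i, (fpr, tpr) in enumerate(curves):
        fpr = np.asarray(fpr, float)
        tpr = np.asarray(tpr, float)
        pos = np.searchsorted(fpr, fpr_grid, side="right") - 1
        tprs[i] = tpr[np.clip(pos, 0, fpr.size - 1)]
    return fpr_grid, tprs.mean(axis=0)


@dataclass
class CVGridResult:
    """Aggregates over all training samples for every grid point.

    Arrays indexed by flattened grid point g (row-major over alphas, then
    lams) and, where applicable, feature j.
    """

    grid: TuningGrid
    mean_auc: np.ndarray           # (G,)
    auc_per_iter: np.ndarray       # (G, n_iter), NaN where an iteration failed
    mean_active: np.ndarray        # (G,)
    mean_abs_coef: np.ndarray      # (G, p), standardized scale
    selection_proportion: np.ndarray  # (G, p), steps of 1/(k·n_iter)
    mean_sign: np.ndarray          # (G, p)
    mean_coef: np.ndarray          # (G, p)
    n_fits: np.ndarray             # (G,)
    n_failed: np.ndarray           # (G,)
    feature_names: list[str]
    modalities: np.ndarray
    fold_assignments: np.ndarray   # (n_iter, n)
    labels: np.ndarray             # (n,)
    seed: int
    config: CVConfig
    scores: np.ndarray | None = field(default=None, repr=False)  # (G, n_iter, n)

    # -- indexing ----------------------------------------------------------
    @property
    def alpha_grid(self) -> np.ndarray:
        return self.grid.flat()[0]

    @property
    def lam_grid(self) -> np.ndarray:
        return self.grid.flat()[1]

    def point_index(self, alpha: float, lam: float) -> int:
        a = int(np.argmin(np.abs(np.asarray(self.grid.alphas) - alpha)))
        l = int(np.argmin(np.abs(np.log(np.asarray(self.grid.lams)) - np.log(lam))))
        return a * len(self.grid.lams) + l

    def best_point(self) -> int:
        """Grid point with the maximum mean AUC."""
        return int(np.nanargmax(self.mean_auc))

    # -- views -------------------------------------------------------------
    def summary_frame(self) -> pd.DataFrame:
        a, l = self.grid.flat()
        return pd.DataFrame(
            {
                "alpha": a,
                "lam": l,
                "mean_auc": self.mean_auc,
                "mean_active_count": self.mean_active,
                "n_fits": self.n_fits,
                "n_failed": self.n_failed,
            }
        )

    def feature_frame(self, g: int) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "modality": self.modalities,
                "mean_abs_coef": self.mean_abs_coef[g],
                "selection_proportion": self.selection_proportion[g],
                "mean_sign": self.mean_sign[g],
                "mean_coef": self.mean_coef[g],
            }
        )

    def roc_curves(self, g: int) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-iteration ROC step curves at grid point g (requires stored scores)."""
        if self.scores is None:
            raise InputError("scores were not stored; rerun with store_scores=True")
        curves = []
        for it in range(self.scores.shape[1]):
            s = self.scores[g, it]
            if np.all(np.isfinite(s)):
                fpr, tpr, _ = roc_curve(self.labels, s)
                curves.append((fpr, tpr))
        return curves

    def mean_roc(self, g: int, n_grid: int = 101) -> tuple[np.ndarray, np.ndarray]:
        return average_roc(self.roc_curves(g), n_grid)

    # -- persistence -------------------------------------------------------
    def to_dir(self, path: str | Path, sep: str = "\t") -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.summary_frame().to_csv(path / "grid_summary.tsv", sep=sep, index=False)
        a, l = self.grid.flat()
        frames = []
        for g in range(self.mean_auc.size):
            frame = self.feature_frame(g)
            frame.insert(0, "lam", l[g])
            frame.insert(0, "alpha", a[g])
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(
            path / "feature_stats.tsv", sep=sep, index=False
        )
        pd.DataFrame(self.auc_per_iter).to_csv(path / "auc_per_iteration.tsv",
                                               sep=sep, index=False)
        pd.DataFrame(self.fold_assignments).to_csv(path / "fold_assignments.tsv",
                                                   sep=sep, index=False)
        write_json(
            {
                "seed": self.seed,
                "labels": self.labels,
                "alphas": list(self.grid.alphas),
                "lams": list(self.grid.lams),
                "feature_names": self.feature_names,
                "modalities": list(map(str, self.modalities)),
                "config": {
                    "n_iter": self.config.n_iter,
                    "k": self.config.k,
                    "seed": self.config.seed,
                    "stratified": self.config.stratified,
                    "pooling": self.config.pooling,
                    "standardize_mode": self.config.standardize_mode,
                },
            },
            path / "manifest.json",
        )

    @classmethod
    def from_dir(cls, path: str | Path, sep: str = "\t") -> "CVGridResult":
        path = Path(path)
        man = read_json(path / "manifest.json")
        grid = TuningGrid(tuple(man["alphas"]), tuple(man["lams"]))
        summary = pd.read_csv(path / "grid_summary.tsv", sep=sep)
        stats_long = pd.read_csv(path / "feature_stats.tsv", sep=sep)
        auc_it = pd.read_csv(path / "auc_per_iteration.tsv", sep=sep).to_numpy(float)
        folds = pd.read_csv(path / "fold_assignments.tsv", sep=sep).to_numpy(int)
        G = grid.n_points
        p = len(man["feature_names"])
        def pivot(col):
            return stats_long[col].to_numpy(float).reshape(G, p)
        return cls(
            grid=grid,
            mean_auc=summary["mean_auc"].to_numpy(float),
            auc_per_iter=auc_it,
            mean_active=summary["mean_active_count"].to_numpy(float),
            mean_abs_coef=pivot("mean_abs_coef"),
            selection_proportion=pivot("selection_proportion"),
            mean_sign=pivot("mean_sign"),
            mean_coef=pivot("mean_coef"),
            n_fits=summary["n_fits"].to_numpy(int),
            n_failed=summary["n_failed"].to_numpy(int),
            feature_names=list(man["feature_names"]),
            modalities=np.asarray(man["modalities"], dtype=object),
            fold_assignments=folds,
            labels=np.asarray(man["labels"], dtype=int),
            seed=int(man["seed"]),
            config=CVConfig(**man["config"]),
        )


def _run_one_iteration(
    it: int,
    fold: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None,
    grid: TuningGrid,
    cfg: CVConfig,
    spec: EnetSpec,
    global_std: tuple[np.ndarray, np.ndarray, np.ndarray] | None,
):
    """All fits of one CV iteration; returns per-iteration accumulators."""
    n, p = X.shape
    A, L = grid.shape
    G = A * L
    sum_abs = np.zeros((G, p))
    sum_signed = np.zeros((G, p))
    sum_sign = np.zeros((G, p))
    sel_count = np.zeros((G, p))
    active_sum = np.zeros(G)
    fit_count = np.zeros(G, dtype=int)
    fail_count = np.zeros(G, dtype=int)
    probs = np.full((G, n), np.nan)
    fold_auc = np.full((G, cfg.k), np.nan)
    lam_order = np.argsort(grid.lams)[::-1]  # large→small for warm starts
    for f in range(cfg.k):
        val = fold == f
        train = ~val
        try:
            if global_std is not None:
                Xs_full, _, _ = global_std
                model = ElasticNetLogistic(
                    y[train], Xs_full[train],
                    None if Z is None else Z[train], standardize=False,
                )
                X_val = Xs_full[val]
            else:
                model = ElasticNetLogistic(
                    y[train], X[train],
                    None if Z is None else Z[train], standardize=True,
                )
                X_val = X[val]
        except InputError:
            fail_count += 1
            continue
        Z_val = None if Z is None else Z[val]
        for a_idx, alpha in enumerate(grid.alphas):
            warm = None
            for l_idx in lam_order:
                g = a_idx * L + l_idx
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        res = model.fit(
                            EnetSpec(
                                alpha=alpha,
                                lam=grid.lams[l_idx],
                                penalize_intercept=spec.penalize_intercept,
                                coef_tol=spec.coef_tol,
                                solver_tol=spec.solver_tol,
                                max_iter=spec.max_iter,
                            ),
                            warm_start=warm,
                        )
                except Exception:
                    fail_count[g] += 1
                    warm = None
                    continue
                warm = res.theta
                absb = np.abs(res.beta)
                nz = absb > spec.coef_tol
                sum_abs[g] += absb
                sum_signed[g] += res.beta
                sum_sign[g] += np.sign(res.beta)
                sel_count[g] += nz
                active_sum[g] += nz.sum()
                fit_count[g] += 1
                pr = res.predict_proba(X_val, Z_val)
                probs[g, val] = pr
                if cfg.pooling == "fold":
                    try:
                        fold_auc[g, f] = roc_auc(pr, y[val])
                    except InputError:
                        pass
    if cfg.pooling == "iteration":
        auc = np.full(G, np.nan)
        complete = np.all(np.isfinite(probs), axis=1)
        for g in np.flatnonzero(complete):
            auc[g] = roc_auc(probs[g], y)
    else:
        auc = np.nanmean(fold_auc, axis=1)
    return (sum_abs, sum_signed, sum_sign, sel_count, active_sum, fit_count,
            fail_count, auc, probs)


def run_iterated_cv(
    X: FeatureMatrix,
    design: CohortDesign,
    grid: TuningGrid,
    cv_cfg: CVConfig | None = None,
    enet_spec: EnetSpec | None = None,
    n_jobs: int = 1,
    store_scores: bool = True,
) -> CVGridResult:
    """Run the iterated k-fold CV sweep over the tuning grid.

    Any individual fit failure is recorded per (α, λ, iteration) and excluded
    from the aggregates rather than aborting the sweep.
    """
    cv_cfg = cv_cfg or CVConfig()
    enet_spec = enet_spec or EnetSpec()
    y = design.labels.astype(float)
    Z = design.covariate_matrix()
    folds = make_fold_iterations(
        design.labels, cv_cfg.n_iter, cv_cfg.k, cv_cfg.seed, cv_cfg.stratified
    )
    global_std = None
    if cv_cfg.standardize_mode == "global":
        global_std = standardize(X.values, X.feature_names)
    jobs = (
        delayed(_run_one_iteration)(
            it, folds[it], X.values, y, Z, grid, cv_cfg, enet_spec, global_std
        )
        for it in range(cv_cfg.n_iter)
    )
    results = Parallel(n_jobs=n_jobs)(jobs)

    G = grid.n_points
    p = X.n_features
    n = X.n_subjects
    sum_abs = np.zeros((G, p))
    sum_signed = np.zeros((G, p))
    sum_sign = np.zeros((G, p))
    sel_count = np.zeros((G, p))
    active_sum = np.zeros(G)
    fit_count = np.zeros(G, dtype=int)
    fail_count = np.zeros(G, dtype=int)
    auc_per_iter = np.full((G, cv_cfg.n_iter), np.nan)
    scores = np.full((G, cv_cfg.n_iter, n), np.nan) if store_scores else None
    for it, (sa, ss, sg, sc, asum, fc, flc, auc, probs) in enumerate(results):
        sum_abs += sa
        sum_signed += ss
        sum_sign += sg
        sel_count += sc
        active_sum += asum
        fit_count += fc
        fail_count += flc
        auc_per_iter[:, it] = auc
        if store_scores:
            scores[:, it, :] = probs

    denom = np.maximum(fit_count, 1).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_auc = np.nanmean(auc_per_iter, axis=1)
    return CVGridResult(
        grid=grid,
        mean_auc=mean_auc,
        auc_per_iter=auc_per_iter,
        mean_active=active_sum / denom,
        mean_abs_coef=sum_abs / denom[:, None],
        selection_proportion=sel_count / denom[:, None],
        mean_sign=sum_sign / denom[:, None],
        mean_coef=sum_signed / denom[:, None],
        n_fits=fit_count,
        n_failed=fail_count,
        feature_names=list(X.feature_names),
        modalities=np.asarray(X.modalities),
        fold_assignments=folds,
        labels=design.labels.copy(),
        seed=cv_cfg.seed,
        config=cv_cfg,
        scores=scores,
    )
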