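"""Model/Results facade tying the pipeline stages together.

``MultimodalSignatureModel`` is built from a feature matrix and a cohort
design; ``fit()`` runs bootstrap screening, the iterated-CV elastic-net
sweep and the consistency selection, returning a ``SignatureResults`` that
carries every stage's output, a ``summary()`` table, the separating-subset
search, the robustness checks and plotting helpers.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cv import CVConfig, CVGridResult, TuningGrid, run_iterated_cv
from .data import CohortDesign, FeatureMatrix, InputError
from .enet import EnetSpec
from .screening import ScreeningConfig, ScreeningResult, bootstrap_screen
from .selection import (
    BoundedRegion,
    SelectionReport,
    SeparationSearchResult,
    bounded_region,
    consistency_set,
    minimal_separating_subsets,
)
from .validation import (
    NullExperimentResult,
    SensitivityResult,
    cv_screening_sensitivity,
    null_randomization,
)

__all__ = ["SelectionConfig", "MultimodalSignatureModel", "SignatureResults"]


@dataclass(frozen=True)
class SelectionConfig:
    p1: float = 75.0
    q1: float = 0.90
    tau_s: float = 0.10
    tau_c: float = 0.90
    k_max: int = 3


class MultimodalSignatureModel:
    """End-to-end signature-discovery model for a two-group cohort.

    Parameters
    ----------
    features, design
        The subjects × features matrix and the labels/covariates.
    screening
        ``ScreeningConfig`` for the bootstrap screening stage, or None to
        skip screening and sweep all features.
    grid, cv, enet, selection
        Stage configurations; defaults follow the reference analysis
        (51 × 151 grid, 100 × 2-fold CV, p1 = 75, q1 = 0.90,
        τ_S = 0.10, τ_C = 0.90).
    """

    def __init__(
        self,
        features: FeatureMatrix,
        design: CohortDesign,
        screening: ScreeningConfig | None = ScreeningConfig(),
        grid: TuningGrid | None = None,
        cv: CVConfig | None = None,
        enet: EnetSpec | None = None,
        selection: SelectionConfig | None = None,
    ) -> None:
        if features.n_subjects != design.n_subjects:
            raise InputError("features and design have different subject counts")
        self.features = features
        self.design = design
        self.screening_cfg = screening
        self.grid = grid or TuningGrid.from_spec()
        self.cv_cfg = cv or CVConfig()
        self.enet_spec = enet or EnetSpec()
        self.selection_cfg = selection or SelectionConfig()

    @classmethod
    def from_dataframe(
        cls,
        features_frame: pd.DataFrame,
        labels,
        modalities,
        covariates: pd.DataFrame | None = None,
        **kwargs,
    ) -> "MultimodalSignatureModel":
        fm = FeatureMatrix.from_frame(features_frame, modalities)
        design = CohortDesign(np.asarray(labels), covariates,
                              [str(i) for i in features_frame.index])
        return cls(fm, design, **kwargs)

    def fit(self, n_jobs: int = 1, store_scores: bool = True) -> "SignatureResults":
        """Run screening → iterated CV → bounded region → consistency set."""
        if self.screening_cfg is not None:
            screening = bootstrap_screen(self.features, self.design,
                                         self.screening_cfg)
            if screening.n_retained == 0:
                raise InputError("screening retained no features; relax p0/r")
            X_used = self.features.subset(screening.retained_mask)
        else:
            screening = None
            X_used = self.features
        cv_result = run_iterated_cv(
            X_used, self.design, self.grid, self.cv_cfg, self.enet_spec,
            n_jobs=n_jobs, store_scores=store_scores,
        )
        sel = self.selection_cfg
        region = report = None
        region_note = ""
        try:
            region = bounded_region(cv_result, sel.p1, sel.q1)
            report = consistency_set(cv_result, region, sel.tau_s, sel.tau_c)
        except InputError as exc:
            region_note = str(exc)
        return SignatureResults(
            model=self,
            screening=screening,
            screened_features=X_used,
            cv_result=cv_result,
            region=region,
            report=report,
            region_note=region_note,
        )


@dataclass
class SignatureResults:
    """Fitted signature analysis: all stage outputs plus reporting helpers."""

    model: MultimodalSignatureModel
    screening: ScreeningResult | None
    screened_features: FeatureMatrix
    cv_result: CVGridResult
    region: BoundedRegion | None
    report: SelectionReport | None
    region_note: str = ""

    # -- headline quantities ----------------------------------------------
    @property
    def consistency_features(self) -> list[str]:
        return [] if self.report is None else list(self.report.consistency_features)

    def best_point(self) -> tuple[float, float, float]:
        """(alpha, lam, mean AUC) at the grid point with maximum mean AUC."""
        g = self.cv_result.best_point()
        return (
            float(self.cv_result.alpha_grid[g]),
            float(self.cv_result.lam_grid[g]),
            float(self.cv_result.mean_auc[g]),
        )

    # -- downstream analyses ----------------------------------------------
    def separating_subsets(
        self, k_max: int | None = None, margin: float = 1e-6
    ) -> SeparationSearchResult:
        """Minimal perfectly-separating subsets of the consistency set."""
        if not self.consistency_features:
            raise InputError("consistency set is empty; nothing to search")
        return minimal_separating_subsets(
            self.screened_features,
            self.model.design,
            self.consistency_features,
            k_max=k_max if k_max is not None else self.model.selection_cfg.k_max,
            margin=margin,
        )

    def null_check(
        self,
        n_repeats: int = 20,
        grid: TuningGrid | None = None,
        seed: int = 0,
        n_jobs: int = 1,
    ) -> NullExperimentResult:
        """Permute labels and rerun the CV sweep (reduced grid by default)."""
        reduced = grid or TuningGrid.from_spec(
            n_alpha=3, lam_min=1e-5, lam_max=10.0, points_per_decade=1
        )
        return null_randomization(
            self.screened_features, self.model.design, reduced,
            self.model.cv_cfg, self.model.enet_spec,
            n_repeats=n_repeats, seed=seed, n_jobs=n_jobs,
        )

    def screening_sensitivity(self) -> SensitivityResult:
        """Univariate screening recomputed inside the primary CV folds."""
        cfg = self.model.screening_cfg or ScreeningConfig()
        return cv_screening_sensitivity(
            self.screened_features, self.model.design, self.cv_result,
            cfg, self.consistency_features or None,
        )

    # -- reporting ----------------------------------------------------------
    def summary(self, top: int = 10) -> str:
        m = self.model
        n0, n1 = m.design.class_counts()
        buf = io.StringIO()
        buf.write("Multimodal signature analysis\n")
        buf.write("=" * 64 + "\n")
        buf.write(f"Subjects: {m.design.n_subjects} ({n1} cases / {n0} controls)\n")
        sizes = ", ".join(f"{k}: {v}" for k, v in m.features.block_sizes().items())
        buf.write(f"Candidate features: {m.features.n_features} ({sizes})\n")
        if self.screening is not None:
            by_mod = ", ".join(
                f"{k}: {v}" for k, v in self.screening.counts_by_modality().items()
            )
            buf.write(
                f"Screening (B={self.screening.config.n_boot}, "
                f"r={self.screening.config.pass_proportion}): retained "
                f"{self.screening.n_retained} ({by_mod})\n"
            )
        else:
            buf.write("Screening: skipped\n")
        A, L = self.cv_result.grid.shape
        cfg = self.cv_result.config
        alpha, lam, auc = self.best_point()
        g = self.cv_result.best_point()
        buf.write(
            f"CV: {cfg.n_iter} × {cfg.k}-fold over a {A} × {L} grid; "
            f"max mean AUC {auc:.3f} at (alpha={alpha:.3g}, lam={lam:.3g}), "
            f"mean active count {self.cv_result.mean_active[g]:.1f}\n"
        )
        sel = m.selection_cfg
        if self.region is not None:
            buf.write(
                f"Bounded region (active ≤ {sel.p1:g}, AUC ≥ {sel.q1:g}): "
                f"{self.region.size} of {self.cv_result.mean_auc.size} points\n"
            )
            buf.write(
                f"Consistency set (tau_s={sel.tau_s:g}, tau_c={sel.tau_c:g}): "
                f"{len(self.consistency_features)} features\n"
            )
            table = self.report.table.head(top)
            buf.write("\nTop features by strength over the bounded region:\n")
            buf.write(
                table.to_string(
                    index=False,
                    formatters={
                        "strength_pct": "{:.1f}".format,
                        "selection_rate_pct": "{:.1f}".format,
                    },
                )
            )
            buf.write("\n")
        else:
            buf.write(f"Bounded region: EMPTY — {self.region_note}\n")
        return buf.getvalue()

    # -- plotting -----------------------------------------------------------
    def plot_auc_grid(self, ax=None):
        """Heat map of mean AUC over the (α, λ) grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        A, L = self.cv_result.grid.shape
        auc = self.cv_result.mean_auc.reshape(A, L)
        lams = np.asarray(self.cv_result.grid.lams)
        alphas = np.asarray(self.cv_result.grid.alphas)
        mesh = ax.pcolormesh(np.log10(lams), alphas, auc, shading="nearest")
        ax.set_xlabel(r"$\log_{10}\lambda$")
        ax.set_ylabel(r"$\alpha$")
        ax.figure.colorbar(mesh, ax=ax, label="mean AUC")
        return ax

    def plot_strength_vs_selection(self, g: int | None = None, ax=None):
        """Scatter of mean |coefficient| vs selection proportion at one point."""
        import matplotlib.pyplot as plt

        from .selection import strength_threshold

        if ax is None:
            _, ax = plt.subplots()
        if g is None:
            g = (self.region.indices[self.region.size // 2]
                 if self.region is not None else self.cv_result.best_point())
        frame = self.cv_result.feature_frame(g)
        for mod, sub in frame.groupby("modality"):
            ax.scatter(sub["selection_proportion"], sub["mean_abs_coef"],
                       s=12, label=str(mod))
        try:
            xi = strength_threshold(frame["mean_abs_coef"].to_numpy(),
                                    self.model.selection_cfg.tau_s)
            ax.axhline(xi, color="k", lw=0.8, ls="--")
        except InputError:
            pass
        ax.set_xlabel("selection proportion over training samples")
        ax.set_ylabel("mean |coefficient| (standardized)")
        ax.legend(fontsize=8)
        return ax

    def plot_mean_roc(self, g: int | None = None, ax=None):
        """Average ROC (vertical TPR average) at one grid point."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if g is None:
            g = self.cv_result.best_point()
        fpr, tpr = self.cv_result.mean_roc(g)
        ax.plot(fpr, tpr)
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        return ax
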