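"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a 28-patient / 14-control cohort: five modality
blocks of correlated Gaussian features (exchangeable within-block
correlation ρ), a handful of planted features whose case means are shifted
by a specified standardized difference, and covariates matching the study's
demographics — ages drawn per group (cases 61.9 ± 8.7 years, controls
71.4 ± 5.8), exactly 13 female cases and 8 female controls, and a head-coil
indicator with 36 subjects on coil A and 6 on coil B (5 cases, 1 control).
Ground truth (planted indices and effect sizes) is recorded so selection
reports can be scored for recovery.

Default total dimension is 500 features (100 VBM, 50 fALFF, 250 FC, 50 FA,
50 SC) so that full grid sweeps finish in minutes; the full 46,580-feature
combinatorics are exercised in the feature-construction layer without the
statistical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CohortDesign, FeatureMatrix, InputError, RegionalTimecourses
from .selection import SelectionReport

__all__ = [
    "EffectSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_timecourses",
    "score_recovery",
    "DEFAULT_P_BY_BLOCK",
]

DEFAULT_P_BY_BLOCK = {"VBM": 100, "fALFF": 50, "FC": 250, "FA": 50, "SC": 50}

# group demographics being emulated
_AGE_CASE = (61.9, 8.7)
_AGE_CONTROL = (71.4, 5.8)
_N_FEMALE_CASE = 13
_N_FEMALE_CONTROL = 8
_N_COIL_B_CASE = 5
_N_COIL_B_CONTROL = 1


@dataclass(frozen=True)
class EffectSpec:
    """Planted group effects and feature dependence structure.

    ``n_planted`` features (chosen at random unless ``planted_indices`` is
    given) receive a case-minus-control mean shift of ``effect_size``
    standard deviations.  ``rho`` is the exchangeable correlation between
    features of the same modality block; ``noise_scale`` multiplies the
    feature noise.
    """

    n_planted: int = 5
    effect_size: float = 2.0
    planted_indices: tuple[int, ...] | None = None
    effect_sizes: tuple[float, ...] | None = None
    rho: float = 0.2
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 0.95:
            raise InputError("rho must lie in [0, 0.95]")
        if self.effect_sizes is not None and self.planted_indices is not None:
            if len(self.effect_sizes) != len(self.planted_indices):
                raise InputError("effect_sizes and planted_indices length mismatch")
        if not np.all(np.isfinite(self.effect_size)):
            raise InputError("effect sizes must be finite")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    features: FeatureMatrix
    design: CohortDesign
    planted_indices: np.ndarray
    effect_sizes: np.ndarray
    seed: int

    @property
    def planted_features(self) -> list[str]:
        return [self.features.feature_names[i] for i in self.planted_indices]


def generate_cohort(
    n_case: int = 28,
    n_control: int = 14,
    p_by_block: dict[str, int] | None = None,
    effect: EffectSpec | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a two-group cohort with planted feature effects.

    Features are drawn per modality block from a correlated Gaussian with
    exchangeable correlation ρ (shared factor construction), then planted
    columns are mean-shifted in cases by the standardized effect size.
    Fully deterministic under ``seed``.
    """
    p_by_block = dict(p_by_block or DEFAULT_P_BY_BLOCK)
    effect = effect or EffectSpec()
    n = n_case + n_control
    p = int(sum(p_by_block.values()))
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    labels = np.concatenate([np.ones(n_case, int), np.zeros(n_control, int)])

    # correlated Gaussian blocks: sqrt(rho)*shared + sqrt(1-rho)*idiosyncratic
    cols = []
    names = []
    mods = []
    for block, pb in p_by_block.items():
        shared = rng.standard_normal((n, 1))
        eps = rng.standard_normal((n, pb))
        vals = np.sqrt(effect.rho) * shared + np.sqrt(1 - effect.rho) * eps
        cols.append(effect.noise_scale * vals)
        names += [f"{block}:f{j:04d}" for j in range(pb)]
        mods += [block] * pb
    values = np.hstack(cols)

    if effect.planted_indices is not None:
        planted = np.asarray(effect.planted_indices, dtype=int)
        if planted.size and (planted.min() < 0 or planted.max() >= p):
            raise InputError(
                f"planted index out of range for p={p}: {planted.tolist()}"
            )
    else:
        planted = np.sort(rng.choice(p, size=effect.n_planted, replace=False))
    if effect.effect_sizes is not None:
        deltas = np.asarray(effect.effect_sizes, dtype=float)
    else:
        deltas = np.full(planted.size, float(effect.effect_size))
    for j, d in zip(planted, deltas):
        values[labels == 1, j] += d * effect.noise_scale

    # covariates: age per group, fixed female counts, fixed coil counts
    age = np.empty(n)
    age[labels == 1] = rng.normal(*_AGE_CASE, size=n_case)
    age[labels == 0] = rng.normal(*_AGE_CONTROL, size=n_control)
    sex = np.zeros(n)
    f_case = min(_N_FEMALE_CASE, n_case)
    f_ctrl = min(_N_FEMALE_CONTROL, n_control)
    sex[rng.choice(np.flatnonzero(labels == 1), f_case, replace=False)] = 1
    sex[rng.choice(np.flatnonzero(labels == 0), f_ctrl, replace=False)] = 1
    coil = np.zeros(n)
    b_case = min(_N_COIL_B_CASE, n_case)
    b_ctrl = min(_N_COIL_B_CONTROL, n_control)
    coil[rng.choice(np.flatnonzero(labels == 1), b_case, replace=False)] = 1
    coil[rng.choice(np.flatnonzero(labels == 0), b_ctrl, replace=False)] = 1
    covariates = pd.DataFrame({"age": age, "sex": sex, "coil": coil})

    subject_ids = [f"sub-{i:03d}" for i in range(n)]
    fm = FeatureMatrix(values, names, mods, subject_ids)
    design = CohortDesign(labels, covariates, subject_ids)
    return SyntheticCohort(fm, design, planted, deltas, seed)


def generate_timecourses(
    n_regions: int,
    n_frames: int = 140,
    tr_seconds: float = 3.0,
    target_correlation: np.ndarray | None = None,
    band: tuple[float, float] | None = (0.01, 0.10),
    band_fraction: float = 0.8,
    seed: int = 0,
    region_ids=None,
) -> RegionalTimecourses:
    """Gaussian regional time courses with a target correlation structure.

    Cross-region dependence is imposed with a symmetric square root of the
    target correlation matrix, so expected pairwise correlations equal the
    target and the empirical correlations converge to it as frames grow.
    Each series mixes a band-limited component (a ``band_fraction`` share of
    spectral amplitude inside ``band``) with broadband noise, so spectra
    concentrate in the configured band.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if target_correlation is None:
        target_correlation = np.eye(n_regions)
    C = np.asarray(target_correlation, dtype=float)
    if C.shape != (n_regions, n_regions) or not np.allclose(C, C.T, atol=1e-10):
        raise InputError("target correlation must be a symmetric R × R matrix")
    evals, evecs = np.linalg.eigh(C)
    if evals.min() < -1e-8:
        raise InputError(
            f"target correlation is not positive semi-definite "
            f"(smallest eigenvalue {evals.min():.3g})"
        )
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None))) @ evecs.T

    def unit_series(shape) -> np.ndarray:
        white = rng.standard_normal(shape)
        if band is None:
            return white
        low, high = band
        freqs = np.fft.rfftfreq(shape[1], d=tr_seconds)
        in_band = (freqs >= low) & (freqs <= high) & (freqs > 0)
        if not in_band.any():
            raise InputError("band contains no resolvable frequency bins")
        spec = np.fft.rfft(white, axis=1)
        narrow = np.fft.irfft(spec * in_band, n=shape[1], axis=1)
        broad = np.fft.irfft(spec * (freqs > 0), n=shape[1], axis=1)
        narrow /= narrow.std(axis=1, keepdims=True)
        broad /= broad.std(axis=1, keepdims=True)
        mix = band_fraction * narrow + (1 - band_fraction) * broad
        return mix / mix.std(axis=1, keepdims=True)

    series = root @ unit_series((n_regions, n_frames))
    if region_ids is None:
        region_ids = tuple(range(1, n_regions + 1))
    return RegionalTimecourses(series, tr_seconds, tuple(region_ids))


def score_recovery(
    report: SelectionReport, truth: SyntheticCohort
) -> dict[str, float]:
    """Sensitivity and false-selection count of C against the planted truth."""
    selected = set(report.consistency_features)
    planted = set(truth.planted_features)
    if not planted:
        raise InputError("cohort has no planted features to score against")
    hits = len(selected & planted)
    return {
        "sensitivity": hits / len(planted),
        "n_false": float(len(selected - planted)),
        "n_selected": float(len(selected)),
        "n_planted": float(len(planted)),
    }
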