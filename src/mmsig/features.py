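"""Multimodal feature construction.

Builds the candidate feature universe from regional/voxel-level inputs:

* ``regional_mean`` — average a voxel-level scalar map (VBM gray-matter
  density, FA) over the regions of a parcellation;
* ``falff`` — fractional amplitude of low-frequency fluctuation, the share
  of a series' spectral amplitude in a low-frequency band (0.01–0.10 Hz by
  default) relative to the whole positive-frequency spectrum;
* ``fc_features`` — Pearson correlations between regional time courses over
  all unordered region pairs;
* ``sc_features`` — symmetrized vectorization of a precomputed structural
  connectivity matrix over the same pair ordering;
* ``assemble_features`` — concatenate per-modality blocks into one
  :class:`~mmsig.data.FeatureMatrix` in the canonical block order.

With a 290-subregion parcellation for VBM/fALFF/FC and a 90-region
parcellation for FA/SC this yields 290 + 290 + 41,905 + 90 + 4,005 = 46,580
candidate features.

A note on fALFF and band-passed series: if the input time courses were
already band-pass filtered to the analysis band during preprocessing, the
fractional amplitude is close to 1 everywhere and carries no contrast.  The
function computes the ratio on whatever series it is given; supplying
unfiltered (or wider-band) series is the caller's responsibility.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .data import MODALITY_ORDER, FeatureMatrix, InputError, Parcellation, RegionalTimecourses

__all__ = [
    "regional_mean",
    "falff",
    "falff_regional",
    "fc_features",
    "sc_features",
    "pair_names",
    "assemble_features",
    "load_nifti_map",
]


def regional_mean(voxel_map: np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Arithmetic mean of ``voxel_map`` over each region of ``parcellation``.

    Returns a vector ordered by ``parcellation.label_ids``.  The map and the
    label volume must live on the same voxel grid; no resampling is done.
    """
    if parcellation.label_volume is None:
        raise InputError("parcellation has no label volume")
    voxel_map = np.asarray(voxel_map, dtype=float)
    labels = parcellation.label_volume
    if voxel_map.shape != labels.shape:
        raise InputError(
            f"voxel map shape {voxel_map.shape} does not match "
            f"label volume shape {labels.shape}"
        )
    ids = np.asarray(parcellation.label_ids)
    counts = ndimage.sum_labels(np.ones_like(labels, dtype=float), labels, ids)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise InputError(f"region {int(ids[empty[0]])} has no voxels")
    return np.asarray(ndimage.mean(voxel_map, labels=labels, index=ids), dtype=float)


def falff(
    series: np.ndarray,
    tr_seconds: float,
    low_hz: float = 0.01,
    high_hz: float = 0.10,
) -> float:
    """Fractional amplitude of low-frequency fluctuation of one series.

    The series is linearly detrended and its single-taper periodogram taken;
    spectral *amplitude* (square root of power, the convention of the fALFF
    literature) is summed over frequency bins whose centers fall in
    ``[low_hz, high_hz]`` (inclusive) and divided by the sum over all
    positive frequencies up to Nyquist.  The zero-frequency term is excluded,
    making the ratio invariant to adding a constant.  Result in [0, 1].
    """
    series = np.asarray(series, dtype=float).ravel()
    if series.size < 8:
        raise InputError(f"need at least 8 frames, got {series.size}")
    if tr_seconds <= 0:
        raise InputError("tr_seconds must be positive")
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0.0 < low_hz < high_hz):
        raise InputError("need 0 < low_hz < high_hz")
    if high_hz > nyquist + 1e-12:
        raise InputError(
            f"high_hz={high_hz} exceeds Nyquist {nyquist:.6g} Hz at TR={tr_seconds}s"
        )
    if np.ptp(series) == 0.0:
        warnings.warn("constant series has zero total power; fALFF set to 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    detrended = signal.detrend(series, type="linear")
    amp = np.abs(np.fft.rfft(detrended))
    freqs = np.fft.rfftfreq(series.size, d=tr_seconds)
    positive = freqs > 0
    total = float(np.sum(amp[positive]))
    if total == 0.0:
        warnings.warn("constant series has zero total power; fALFF set to 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    in_band = positive & (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    return float(np.sum(amp[in_band]) / total)


def falff_regional(tc: RegionalTimecourses, low_hz: float = 0.01,
                   high_hz: float = 0.10) -> np.ndarray:
    """fALFF of each regional time course, ordered by region id."""
    return np.array(
        [falff(row, tc.tr_seconds, low_hz, high_hz) for row in tc.values]
    )


def pair_names(region_ids: Sequence[int], prefix: str) -> list[str]:
    """Deterministic names for unordered region pairs, lexicographic i < j."""
    ids = list(region_ids)
    return [
        f"{prefix}:r{ids[i]:03d}-r{ids[j]:03d}"
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    ]


def fc_features(tc: RegionalTimecourses) -> pd.Series:
    """Pearson correlation for every unordered region pair.

    Pair ordering is strictly lexicographic over region index (i < j), so the
    output length is R(R−1)/2 and column identity is reproducible across
    runs.  A constant regional series makes its correlations undefined and is
    rejected with the offending region named.
    """
    if tc.n_regions < 2:
        raise InputError("need at least 2 regions for FC features")
    sd = tc.values.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise InputError(
            f"region {tc.region_ids[flat[0]]} has a constant time course; "
            "its correlations are undefined"
        )
    corr = np.corrcoef(tc.values)
    iu, ju = np.triu_indices(tc.n_regions, k=1)
    vals = np.clip(corr[iu, ju], -1.0, 1.0)
    return pd.Series(vals, index=pair_names(tc.region_ids, "FC"))


def sc_features(
    sc_matrix: np.ndarray, region_ids: Sequence[int] | None = None
) -> pd.Series:
    """Vectorize a structural-connectivity matrix over unordered pairs.

    The matrix is symmetrized as (M + Mᵀ)/2 first; pair ordering matches
    :func:`fc_features`.
    """
    m = np.asarray(sc_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InputError(f"SC matrix must be square, got shape {m.shape}")
    r = m.shape[0]
    if region_ids is None:
        region_ids = range(1, r + 1)
    region_ids = list(region_ids)
    if len(region_ids) != r:
        raise InputError("region_ids length does not match SC matrix size")
    sym = 0.5 * (m + m.T)
    iu, ju = np.triu_indices(r, k=1)
    return pd.Series(sym[iu, ju], index=pair_names(region_ids, "SC"))


def assemble_features(
    blocks: Mapping[str, pd.DataFrame],
    subject_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Concatenate per-modality feature blocks into one FeatureMatrix.

    Parameters
    ----------
    blocks
        Mapping modality → subjects × features DataFrame.  All blocks must
        share the same subject index in the same order.  Blocks are
        concatenated in the canonical order VBM, fALFF, FC, FA, SC (unknown
        blocks follow, alphabetically).
    """
    if not blocks:
        raise InputError("no feature blocks supplied")
    order = [m for m in MODALITY_ORDER if m in blocks]
    order += sorted(set(blocks) - set(MODALITY_ORDER))
    first = blocks[order[0]]
    index = list(first.index)
    for name in order:
        frame = blocks[name]
        if list(frame.index) != index:
            raise InputError(
                f"block {name!r} subject order differs from block {order[0]!r}"
            )
        counts = frame.notna().all(axis=1)
        if not counts.all():
            bad = counts.idxmin()
            raise InputError(f"subject {bad!r} has missing values in block {name!r}")
    values = np.hstack([blocks[m].to_numpy(float) for m in order])
    names = [c for m in order for c in blocks[m].columns]
    mods = [m for m in order for _ in range(blocks[m].shape[1])]
    if subject_ids is None:
        subject_ids = [str(i) for i in index]
    return FeatureMatrix(values, names, mods, subject_ids)


def blocks_from_subjects(
    per_subject: Mapping[str, Mapping[str, pd.Series]],
) -> dict[str, pd.DataFrame]:
    """Stack per-subject block vectors into per-modality DataFrames.

    Every subject must provide the same blocks with identical feature names
    in the same order; a mismatch is reported naming the subject and block.
    """
    if not per_subject:
        raise InputError("no subjects supplied")
    subjects = list(per_subject)
    ref = per_subject[subjects[0]]
    blocks: dict[str, pd.DataFrame] = {}
    for block, ref_vec in ref.items():
        rows = []
        for sub in subjects:
            if block not in per_subject[sub]:
                raise InputError(f"subject {sub!r} is missing block {block!r}")
            vec = per_subject[sub][block]
            if list(vec.index) != list(ref_vec.index):
                raise InputError(
                    f"subject {sub!r} block {block!r} feature names/length "
                    f"differ from subject {subjects[0]!r}"
                )
            rows.append(np.asarray(vec, dtype=float))
        blocks[block] = pd.DataFrame(rows, index=subjects, columns=list(ref_vec.index))
    for sub in subjects:
        extra = set(per_subject[sub]) - set(ref)
        if extra:
            raise InputError(
                f"subject {sub!r} has unexpected block {sorted(extra)[0]!r}"
            )
    return blocks


def load_nifti_map(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI scalar map, returning (data, affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine
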