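"""Core data containers shared across the pipeline.

The central exchange object is :class:`FeatureMatrix` — a subjects × features
array in which every column is tagged with the imaging modality block it came
from (VBM, fALFF, FC, FA or SC).  :class:`CohortDesign` carries the binary
group labels together with the adjustment covariates (age, sex, head coil).
Both round-trip through plain delimited text so that every pipeline stage can
be re-run from its on-disk artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical ordering of the five modality blocks.
MODALITY_ORDER: tuple[str, ...] = ("VBM", "fALFF", "FC", "FA", "SC")


class InputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class Parcellation:
    """An ordered set of integer region labels, optionally with a label volume.

    Parameters
    ----------
    label_ids
        Unique, sorted positive integer region labels (e.g. the 90 AAL
        regions or a 290-subregion refinement).
    level_name
        Free-text tag for the spatial scale, e.g. ``"AAL-90"``.
    label_volume
        Optional 3-D integer array with 0 marking background voxels.  Every
        nonzero value must appear in ``label_ids``.
    """

    label_ids: tuple[int, ...]
    level_name: str = ""
    label_volume: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        ids = np.asarray(self.label_ids, dtype=int)
        if ids.size == 0:
            raise InputError("parcellation needs at least one region label")
        if np.any(ids <= 0):
            raise InputError("region labels must be positive integers")
        if len(set(ids.tolist())) != ids.size:
            raise InputError("region labels must be unique")
        if not np.all(np.diff(ids) > 0):
            raise InputError("region labels must be sorted ascending")
        object.__setattr__(self, "label_ids", tuple(int(i) for i in ids))
        if self.label_volume is not None:
            vol = np.asarray(self.label_volume)
            if vol.ndim != 3:
                raise InputError("label volume must be a 3-D array")
            if not np.issubdtype(vol.dtype, np.integer):
                raise InputError("label volume must hold integers")
            present = set(np.unique(vol).tolist()) - {0}
            unknown = present - set(self.label_ids)
            if unknown:
                raise InputError(
                    f"label volume contains labels not in label_ids: {sorted(unknown)}"
                )
            object.__setattr__(self, "label_volume", vol)

    @property
    def n_regions(self) -> int:
        return len(self.label_ids)


@dataclass(frozen=True)
class RegionalTimecourses:
    """Regions × frames time-series matrix with its repetition time.

    The frame count must be at least 8 (shorter series cannot support a
    meaningful spectral band estimate) and all entries must be finite.
    """

    values: np.ndarray
    tr_seconds: float
    region_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise InputError("time courses must be a 2-D regions × frames array")
        if vals.shape[1] < 8:
            raise InputError(f"need at least 8 frames, got {vals.shape[1]}")
        if not np.all(np.isfinite(vals)):
            raise InputError("time courses contain non-finite entries")
        if self.tr_seconds <= 0:
            raise InputError("tr_seconds must be positive")
        ids = tuple(int(i) for i in self.region_ids)
        if len(ids) != vals.shape[0]:
            raise InputError(
                f"{len(ids)} region ids for {vals.shape[0]} time-course rows"
            )
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "region_ids", ids)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


class FeatureMatrix:
    """Subjects × features matrix with named, modality-tagged columns.

    Parameters
    ----------
    values : ndarray, shape (n_subjects, p)
    feature_names : sequence of unique str
        Identifiers encoding block and region(s), e.g. ``"FC:r017-r112"``.
    modalities : sequence of str, length p
        Modality block of each feature.
    subject_ids : optional sequence of str
    """

    def __init__(
        self,
        values: np.ndarray,
        feature_names: Sequence[str],
        modalities: Sequence[str],
        subject_ids: Sequence[str] | None = None,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise InputError("feature values must be 2-D (subjects × features)")
        names = [str(n) for n in feature_names]
        if len(names) != values.shape[1]:
            raise InputError(
                f"{len(names)} names for {values.shape[1]} feature columns"
            )
        if len(set(names)) != len(names):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))
            raise InputError(f"duplicate feature name: {dup!r}")
        mods = [str(m) for m in modalities]
        if len(mods) != len(names):
            raise InputError("modalities must have one entry per feature")
        if subject_ids is None:
            subject_ids = [f"sub-{i:03d}" for i in range(values.shape[0])]
        subject_ids = [str(s) for s in subject_ids]
        if len(subject_ids) != values.shape[0]:
            raise InputError("subject_ids must have one entry per row")
        self.values = values
        self.feature_names = names
        self.modalities = np.asarray(mods, dtype=object)
        self.subject_ids = subject_ids

    # -- basic protocol ----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def modality_of(self, name: str) -> str:
        return str(self.modalities[self.feature_names.index(name)])

    def block_sizes(self) -> dict[str, int]:
        """Feature count per modality block, in canonical order first."""
        uniq, counts = np.unique(self.modalities.astype(str), return_counts=True)
        raw = dict(zip(uniq.tolist(), counts.tolist()))
        ordered = {m: raw.pop(m) for m in MODALITY_ORDER if m in raw}
        ordered.update(sorted(raw.items()))
        return ordered

    def subset(self, mask_or_indices) -> "FeatureMatrix":
        """Column subset preserving names/modalities; accepts mask or indices."""
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureMatrix(
            self.values[:, idx],
            [self.feature_names[i] for i in idx],
            self.modalities[idx],
            self.subject_ids,
        )

    def __eq__(self, other) -> bool:  # value equality, used in round-trip tests
        return (
            isinstance(other, FeatureMatrix)
            and self.feature_names == other.feature_names
            and self.subject_ids == other.subject_ids
            and list(self.modalities) == list(other.modalities)
            and np.array_equal(self.values, other.values)
        )

    # -- pandas / disk interchange ----------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.subject_ids, columns=self.feature_names
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, modalities: Mapping[str, str] | Sequence[str]
    ) -> "FeatureMatrix":
        if isinstance(modalities, Mapping):
            try:
                mods = [modalities[c] for c in frame.columns]
            except KeyError as exc:
                raise InputError(f"no modality recorded for feature {exc}") from exc
        else:
            mods = list(modalities)
        return cls(frame.to_numpy(float), list(frame.columns), mods,
                   [str(i) for i in frame.index])

    def write(self, path: str | Path, sep: str = "\t") -> None:
        """Write values as delimited text plus a ``.modalities`` sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, sep=sep, index_label="subject")
        sidecar = pd.DataFrame(
            {"feature": self.feature_names, "modality": self.modalities}
        )
        sidecar.to_csv(path.with_suffix(path.suffix + ".modalities"), sep=sep,
                       index=False)

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t") -> "FeatureMatrix":
        path = Path(path)
        frame = pd.read_csv(path, sep=sep, index_col="subject")
        sidecar = pd.read_csv(path.with_suffix(path.suffix + ".modalities"), sep=sep)
        mapping = dict(zip(sidecar["feature"], sidecar["modality"]))
        return cls.from_frame(frame, mapping)


@dataclass
class CohortDesign:
    """Group labels and adjustment covariates for the cohort.

    ``labels`` is a binary 0/1 vector (1 = case).  ``covariates`` is a
    DataFrame aligned with the label order; the conventional columns are
    ``age`` (years), ``sex`` (1 = female) and ``coil`` (1 = second head
    coil), but any numeric columns are accepted.
    """

    labels: np.ndarray
    covariates: pd.DataFrame | None = None
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.labels)
        if not np.isin(y, (0, 1)).all():
            raise InputError("labels must be binary 0/1")
        self.labels = y.astype(int)
        n = self.labels.size
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{i:03d}" for i in range(n)]
        if len(self.subject_ids) != n:
            raise InputError("subject_ids length mismatch with labels")
        if self.covariates is not None and len(self.covariates) != n:
            raise InputError("covariate table length mismatch with labels")

    @property
    def n_subjects(self) -> int:
        return self.labels.size

    def covariate_matrix(self) -> np.ndarray | None:
        if self.covariates is None or self.covariates.shape[1] == 0:
            return None
        return self.covariates.to_numpy(float)

    def class_counts(self) -> tuple[int, int]:
        """(n_controls, n_cases)."""
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def write(self, path: str | Path, sep: str = "\t") -> None:
        frame = pd.DataFrame({"label": self.labels}, index=self.subject_ids)
        if self.covariates is not None:
            cov = self.covariates.copy()
            cov.index = frame.index
            frame = pd.concat([frame, cov], axis=1)
        frame.to_csv(path, sep=sep, index_label="subject")

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t") -> "CohortDesign":
        frame = pd.read_csv(path, sep=sep, index_col="subject")
        labels = frame.pop("label").to_numpy()
        cov = frame if frame.shape[1] else None
        return cls(labels, cov, [str(i) for i in frame.index])


def write_json(obj, path: str | Path) -> None:
    """Write ``obj`` as JSON, converting numpy scalars/arrays on the way."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
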