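"""Core domain types shared across the workflow.

Conventions used everywhere:

* missing intensity is ``NaN`` ("absent"), never zero — zeros would corrupt
  the medians used by normalization and batch correction;
* m/z arrays are sorted ascending within a scan;
* feature ids are assigned in m/z order and the feature m/z table is
  strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Scan",
    "SampleScanSet",
    "SampleMetadata",
    "PeakList",
    "FeatureMatrix",
    "CellCountTable",
    "WorkflowParams",
    "ROLES",
    "EXTRACTION_METHODS",
    "PulsedMSError",
    "EmptyInputError",
    "ValidationError",
    "UnsupportedDialectError",
    "EmptySelectionError",
    "NormalizationError",
]

ROLES = ("treated", "dmso_control", "death_control", "qc")
EXTRACTION_METHODS = ("all_scans", "on_scans", "on_scans_no_edge")


class PulsedMSError(Exception):
    """Base class for workflow errors."""


class EmptyInputError(PulsedMSError):
    """An input contained no usable records."""


class ValidationError(PulsedMSError):
    """An input failed a structural or semantic check."""


class UnsupportedDialectError(PulsedMSError):
    """The file is valid but in a dialect this reader does not handle."""


class EmptySelectionError(PulsedMSError):
    """Scan selection produced no scans for a sample."""


class NormalizationError(PulsedMSError):
    """A sample could not be normalized."""


@dataclass
class Scan:
    """One centroided mass spectrum."""

    index: int
    mz: np.ndarray
    intensity: np.ndarray
    time: float = 0.0
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValidationError(
                f"scan {self.index}: mz and intensity lengths differ "
                f"({self.mz.size} vs {self.intensity.size})"
            )
        if self.index < 0:
            raise ValidationError(f"scan index must be non-negative, got {self.index}")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValidationError(f"scan {self.index}: negative intensities")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def tic(self) -> float:
        """Total ion current: summed peak intensity."""
        return float(self.intensity.sum())


@dataclass
class SampleScanSet:
    """Ordered scans belonging to one well/sample."""

    sample_id: str
    scans: list[Scan]
    plate_id: str = ""
    well: str = ""

    def __post_init__(self) -> None:
        if not self.scans:
            raise EmptyInputError(f"sample {self.sample_id!r} has no scans")
        indices = [s.index for s in self.scans]
        if len(set(indices)) != len(indices):
            raise ValidationError(f"sample {self.sample_id!r}: duplicate scan indices")
        self.scans = sorted(self.scans, key=lambda s: s.index)

    def __len__(self) -> int:
        return len(self.scans)

    def __iter__(self) -> Iterator[Scan]:
        return iter(self.scans)


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    plate_id: str
    well: str
    role: str
    drug: str = ""
    concentration: float | None = None
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown role {self.role!r} "
                f"(allowed: {', '.join(ROLES)})"
            )
        if self.role == "treated" and (not self.drug or self.concentration is None):
            raise ValidationError(
                f"treated sample {self.sample_id!r} needs drug and concentration"
            )
        if self.concentration is not None and self.concentration < 0:
            raise ValidationError(f"sample {self.sample_id!r}: negative concentration")


@dataclass
class PeakList:
    """Per-sample extracted features.

    ``table`` columns: ``mz`` (centroid, Da), ``intensity`` (mean over
    selected scans where the feature occurs), ``occurrence`` (fraction of
    selected scans containing it), ``rsd`` (intra-sample RSD %, NaN when
    the feature occurs in fewer than 2 scans), ``snr`` (mean per-peak SNR).
    """

    sample_id: str
    table: pd.DataFrame
    n_selected_scans: int = 0
    collisions: int = 0

    COLUMNS = ("mz", "intensity", "occurrence", "rsd", "snr")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"PeakList missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.table)


class CellCountTable:
    """Per-well imaging cell counts, keyed by (plate_id, well).

    A single-plate table may be keyed by well alone (empty plate id).
    """

    def __init__(self, counts: Mapping[tuple[str, str], int]):
        self._counts: dict[tuple[str, str], int] = {}
        for key, value in counts.items():
            value = int(value)
            if value < 0:
                raise ValidationError(f"negative cell count for {key}")
            self._counts[key] = value

    def get(self, plate_id: str, well: str) -> int | None:
        if (plate_id, well) in self._counts:
            return self._counts[(plate_id, well)]
        return self._counts.get(("", well))

    def __len__(self) -> int:
        return len(self._counts)

    def items(self):
        return self._counts.items()


@dataclass(frozen=True)
class WorkflowParams:
    """All tunable thresholds of the workflow, with the optimized defaults."""

    snr_label_threshold: float = 15.0
    off_scan_tolerance: int = 3
    snr_retain_threshold: float = 3.0
    replicate_fraction: float = 0.5
    sample_fraction: float = 0.5
    missing_fraction: float = 0.5
    rsd_threshold: float = 40.0
    phenotype_quantile: float = 0.95
    mz_tolerance_ppm: float = 5.0
    extraction_method: str = "on_scans_no_edge"

    def __post_init__(self) -> None:
        for name in ("replicate_fraction", "sample_fraction", "missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("snr_label_threshold", "snr_retain_threshold",
                     "rsd_threshold", "mz_tolerance_ppm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.off_scan_tolerance < 0:
            raise ValidationError("off_scan_tolerance must be >= 0")
        if not 0.0 < self.phenotype_quantile < 1.0:
            raise ValidationError("phenotype_quantile must lie in (0, 1)")
        if self.extraction_method not in EXTRACTION_METHODS:
            raise ValidationError(
                f"unknown extraction method {self.extraction_method!r} "
                f"(allowed: {', '.join(EXTRACTION_METHODS)})"
            )

    def with_(self, **kwargs) -> "WorkflowParams":
        return replace(self, **kwargs)


@dataclass
class FeatureMatrix:
    """Samples x features intensity table with explicit missingness.

    ``intensities``: DataFrame indexed by sample_id, columns feature ids,
    NaN marks a missing observation. ``feature_mz``: Series feature_id -> m/z,
    strictly increasing. ``sample_meta``: DataFrame indexed by sample_id with
    columns plate_id, well, role, drug, concentration_M, replicate.
    """

    intensities: pd.DataFrame
    feature_mz: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.intensities.columns) != list(self.feature_mz.index):
            raise ValidationError("feature ids of intensities and feature_mz differ")
        if not self.intensities.index.equals(self.sample_meta.index):
            raise ValidationError("sample ids of intensities and sample_meta differ")
        mz = self.feature_mz.to_numpy(dtype=float)
        if mz.size > 1 and np.any(np.diff(mz) <= 0):
            raise ValidationError("feature m/z centroids must be strictly increasing")
        vals = self.intensities.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValidationError("negative intensities in feature matrix")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.intensities.isna()

    def select_features(self, feature_ids) -> "FeatureMatrix":
        return FeatureMatrix(
            intensities=self.intensities.loc[:, feature_ids],
            feature_mz=self.feature_mz.loc[feature_ids],
            sample_meta=self.sample_meta,
        )

    def select_samples(self, sample_ids) -> "FeatureMatrix":
        return FeatureMatrix(
            intensities=self.intensities.loc[sample_ids],
            feature_mz=self.feature_mz,
            sample_meta=self.sample_meta.loc[sample_ids],
        )

    def plate_partition(self) -> dict[str, list[str]]:
        """plate_id -> sample ids, covering every sample exactly once."""
        out: dict[str, list[str]] = {}
        for sid, plate in self.sample_meta["plate_id"].items():
            out.setdefault(str(plate), []).append(sid)
        return out
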