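"""m/z clustering and the five-stage feature/sample filter cascade.

Boundary semantics, fixed in one place:

==================  =========================================
filter              rule
==================  =========================================
SNR filter          retain SNR strictly > threshold
replicate filter    retain occurrence fraction >= threshold
sample filter       retain observed fraction >= threshold
missing-value       drop samples with missing fraction strictly > threshold
RSD filter          retain RSD <= threshold ("exceeded" = strict)
==================  =========================================
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import (
    EmptyInputError,
    FeatureMatrix,
    PeakList,
    ValidationError,
    WorkflowParams,
)

__all__ = [
    "cluster_mz_peaks",
    "snr_filter",
    "replicate_filter",
    "sample_filter",
    "missing_value_sample_filter",
    "rsd_filter",
    "assemble_feature_matrix",
]

logger = logging.getLogger(__name__)


def cluster_mz_peaks(mz, intensity, source, ppm: float = 5.0
                     ) -> tuple[list[np.ndarray], int]:
    """Single-linkage 1-D clustering of peaks on m/z.

    Consecutive peaks (sorted by m/z) join one cluster iff their gap is
    <= ppm * 1e-6 * mean of the two m/z values. When two peaks from the same
    source land in one cluster only the more intense is kept; the number of
    such collisions is returned alongside the clusters (index arrays into
    the input).
    """
    if ppm <= 0:
        raise ValidationError(f"ppm must be positive, got {ppm}")
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    source = np.asarray(source)
    if mz.size == 0:
        return [], 0

    order = np.argsort(mz, kind="stable")
    mz_s = mz[order]
    gaps = np.diff(mz_s)
    limits = ppm * 1e-6 * (mz_s[:-1] + mz_s[1:]) / 2.0
    breaks = np.nonzero(gaps > limits)[0] + 1
    boundaries = np.concatenate([[0], breaks, [mz_s.size]])

    clusters: list[np.ndarray] = []
    collisions = 0
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        members = order[lo:hi]
        # same-source dedup: keep the most intense peak per source
        best: dict = {}
        for idx in members:
            src = source[idx]
            if src in best:
                collisions += 1
                if intensity[idx] > intensity[best[src]]:
                    best[src] = idx
            else:
                best[src] = idx
        clusters.append(np.array(sorted(best.values()), dtype=int))
    return clusters, collisions


def snr_filter(peaks: PeakList, params: WorkflowParams | None = None) -> PeakList:
    """Retain features with SNR strictly above ``snr_retain_threshold``."""
    params = params or WorkflowParams()
    table = peaks.table[peaks.table["snr"] > params.snr_retain_threshold]
    return PeakList(sample_id=peaks.sample_id, table=table.reset_index(drop=True),
                    n_selected_scans=peaks.n_selected_scans,
                    collisions=peaks.collisions)


def replicate_filter(peaks: PeakList, params: WorkflowParams | None = None) -> PeakList:
    """Retain features occurring in >= ``replicate_fraction`` of selected scans."""
    params = params or WorkflowParams()
    table = peaks.table[peaks.table["occurrence"] >= params.replicate_fraction]
    return PeakList(sample_id=peaks.sample_id, table=table.reset_index(drop=True),
                    n_selected_scans=peaks.n_selected_scans,
                    collisions=peaks.collisions)


def sample_filter(matrix: FeatureMatrix,
                  params: WorkflowParams | None = None) -> FeatureMatrix:
    """Retain features observed in >= ``sample_fraction`` of ALL samples."""
    params = params or WorkflowParams()
    if matrix.n_samples < 1:
        raise EmptyInputError("sample filter needs >= 1 sample")
    frac = matrix.intensities.notna().sum(axis=0) / matrix.n_samples
    keep = frac.index[frac >= params.sample_fraction]
    return matrix.select_features(list(keep))


def missing_value_sample_filter(matrix: FeatureMatrix,
                                params: WorkflowParams | None = None
                                ) -> tuple[FeatureMatrix, list[str]]:
    """Drop samples whose missing fraction is strictly above the threshold.

    Returns the reduced matrix and the dropped sample ids. Raises
    :class:`EmptyInputError` if every sample would be dropped.
    """
    params = params or WorkflowParams()
    missing_frac = matrix.intensities.isna().sum(axis=1) / matrix.n_features
    dropped = list(missing_frac.index[missing_frac > params.missing_fraction])
    kept = [s for s in matrix.intensities.index if s not in set(dropped)]
    if not kept:
        raise EmptyInputError("missing-value filter dropped every sample")
    return matrix.select_samples(kept), dropped


def feature_rsd(matrix: FeatureMatrix, sample_ids: list[str]) -> pd.Series:
    """Per-feature RSD% over the non-missing values of the given samples.

    Uses the sample (n-1) standard deviation; features observed in fewer
    than 2 of the samples get NaN.
    """
    sub = matrix.intensities.loc[sample_ids]
    n = sub.notna().sum(axis=0)
    mean = sub.mean(axis=0, skipna=True)
    sd = sub.std(axis=0, ddof=1, skipna=True)
    rsd = 100.0 * sd / mean
    rsd[n < 2] = np.nan
    return rsd


def rsd_filter(matrix: FeatureMatrix, qc_sample_ids: list[str],
               params: WorkflowParams | None = None) -> FeatureMatrix:
    """Retain features whose RSD across QC samples is <= ``rsd_threshold``.

    Features observed in fewer than 2 QC samples have undefined RSD and are
    removed (logged). With fewer than 2 QC samples overall the filter is
    skipped with a warning and the matrix is returned unchanged — mirroring
    studies where intrastudy QC samples are unavailable.
    """
    params = params or WorkflowParams()
    qc_ids = [s for s in qc_sample_ids if s in matrix.intensities.index]
    if len(qc_ids) < 2:
        logger.warning("RSD filter skipped: %d QC sample(s) available (need >= 2)",
                       len(qc_ids))
        return matrix
    rsd = feature_rsd(matrix, qc_ids)
    undefined = rsd.index[rsd.isna()]
    if len(undefined):
        logger.info("RSD filter: %d feature(s) observed in < 2 QC samples, removed",
                    len(undefined))
    keep = rsd.index[rsd <= params.rsd_threshold]
    return matrix.select_features(list(keep))


def assemble_feature_matrix(peaklists: list[PeakList],
                            sample_meta: pd.DataFrame,
                            ppm: float = 5.0) -> FeatureMatrix:
    """Align per-sample peak lists into a study-wide feature matrix.

    Feature centroids are clustered across samples with the same
    single-linkage ppm rule used within samples; unobserved (sample,
    feature) cells are missing, never zero.
    """
    if not peaklists:
        raise EmptyInputError("no peak lists to assemble")
    mz = np.concatenate([p.table["mz"].to_numpy() for p in peaklists])
    inten = np.concatenate([p.table["intensity"].to_numpy() for p in peaklists])
    source = np.concatenate([np.full(len(p.table), i) for i, p in enumerate(peaklists)])
    clusters, _ = cluster_mz_peaks(mz, inten, source, ppm=ppm)

    centroids = []
    for cluster in clusters:
        w = inten[cluster]
        centroids.append(float(np.average(mz[cluster], weights=w)) if w.sum() > 0
                         else float(np.mean(mz[cluster])))
    order = np.argsort(centroids, kind="stable")
    width = max(4, len(str(len(clusters))))
    feature_ids = [f"F{i:0{width}d}" for i in range(len(clusters))]

    sample_ids = [p.sample_id for p in peaklists]
    values = np.full((len(peaklists), len(clusters)), np.nan)
    for col, ci in enumerate(order):
        for idx in clusters[ci]:
            values[int(source[idx]), col] = inten[idx]
    intensities = pd.DataFrame(values, index=sample_ids, columns=feature_ids)
    feature_mz = pd.Series([centroids[ci] for ci in order], index=feature_ids,
                           name="mz")
    meta = sample_meta.loc[sample_ids]
    return FeatureMatrix(intensities=intensities, feature_mz=feature_mz,
                         sample_meta=meta)
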