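"""Plate-wise probabilistic quotient normalization (PQN) and per-feature
plate batch correction.

The two steps run in a fixed order: PQN first, within each plate, against
the plate's mean spectrum; then every feature is divided by a plate
coefficient (plate median / grand median) so the within-plate medians line
up with the study-wide median.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import FeatureMatrix, NormalizationError, ValidationError

__all__ = ["pqn_normalize_plate", "pqn_normalize", "batch_correct"]

logger = logging.getLogger(__name__)


def pqn_normalize_plate(sub: pd.DataFrame, reference: pd.Series | None = None
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """PQN one plate's samples x features submatrix.

    The reference spectrum defaults to the per-feature mean over the plate's
    non-missing values. Each sample is divided by its quotient: the median
    of sample/reference ratios over the features observed in both. Missing
    values stay missing. Returns (normalized submatrix, per-sample quotients).

    Rescaling one sample by c > 0 leaves its normalized row unchanged when
    ``reference`` is supplied; with the default plate-mean reference the
    invariance is approximate, since the sample contributes to the mean.
    """
    if sub.shape[0] < 1:
        raise ValidationError("PQN needs >= 1 sample on the plate")
    if reference is None:
        reference = sub.mean(axis=0, skipna=True)
    quotients = {}
    for sid, row in sub.iterrows():
        ratios = row / reference
        ratios = ratios.dropna()
        if ratios.empty:
            raise NormalizationError(
                f"sample {sid!r} shares no feature with the plate reference"
            )
        q = float(ratios.median())
        if q <= 0:
            raise NormalizationError(f"sample {sid!r}: non-positive quotient {q}")
        quotients[sid] = q
    qs = pd.Series(quotients).loc[sub.index]
    return sub.div(qs, axis=0), qs


def pqn_normalize(matrix: FeatureMatrix,
                  partition: dict[str, list[str]] | None = None
                  ) -> tuple[FeatureMatrix, pd.Series]:
    """Apply PQN to each plate individually; returns (matrix, quotients)."""
    partition = partition or matrix.plate_partition()
    _check_partition(matrix, partition)
    normalized = matrix.intensities.copy()
    quotients = pd.Series(dtype=float)
    for plate_id, sample_ids in partition.items():
        sub_norm, qs = pqn_normalize_plate(matrix.intensities.loc[sample_ids])
        normalized.loc[sample_ids] = sub_norm
        quotients = pd.concat([quotients, qs])
    out = FeatureMatrix(intensities=normalized, feature_mz=matrix.feature_mz,
                        sample_meta=matrix.sample_meta)
    return out, quotients.loc[matrix.intensities.index]


def batch_correct(matrix: FeatureMatrix,
                  partition: dict[str, list[str]] | None = None
                  ) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Divide each feature by its plate coefficient.

    Coefficient c(f, p) = median of feature f within plate p / grand median
    of f over all samples (non-missing values only). Where the plate median
    is undefined (feature absent from the plate) or zero, c is set to 1 and
    the event is logged. After correction the within-plate median of every
    feature equals that feature's pre-correction grand median on every plate
    where it is observed.

    Returns (corrected matrix, coefficient table with columns feature_id,
    plate_id, coefficient).
    """
    partition = partition or matrix.plate_partition()
    _check_partition(matrix, partition)
    grand_median = matrix.intensities.median(axis=0, skipna=True)
    corrected = matrix.intensities.copy()
    rows = []
    for plate_id, sample_ids in partition.items():
        sub = matrix.intensities.loc[sample_ids]
        plate_median = sub.median(axis=0, skipna=True)
        coeff = plate_median / grand_median
        degenerate = coeff.isna() | (plate_median == 0) | (grand_median == 0)
        if degenerate.any():
            logger.info("batch correction: %d degenerate coefficient(s) on plate %s "
                        "set to 1", int(degenerate.sum()), plate_id)
        coeff = coeff.where(~degenerate, 1.0)
        corrected.loc[sample_ids] = sub.div(coeff, axis=1)
        for fid, c in coeff.items():
            rows.append({"feature_id": fid, "plate_id": plate_id,
                         "coefficient": float(c)})
    out = FeatureMatrix(intensities=corrected, feature_mz=matrix.feature_mz,
                        sample_meta=matrix.sample_meta)
    return out, pd.DataFrame(rows, columns=["feature_id", "plate_id", "coefficient"])


def _check_partition(matrix: FeatureMatrix, partition: dict[str, list[str]]) -> None:
    flat = [s for ids in partition.values() for s in ids]
    if len(flat) != len(set(flat)):
        raise ValidationError("plate partition assigns a sample to multiple plates")
    if set(flat) != set(matrix.intensities.index):
        raise ValidationError("plate partition does not cover all samples exactly once")
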