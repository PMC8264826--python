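"""Scan-level signal processing: per-peak SNR, on/off labeling, edge-aware
scan selection and per-sample spectrum extraction.

A pulsed ion source alternates between a charging ("on") phase that delivers
analyte and a discharge ("off") phase that does not, so each sample's scan
sequence interleaves signal-bearing and empty scans. Scans are classified by
counting peaks whose SNR exceeds a hard threshold; on-scans adjacent to an
off-scan ("edge" scans) show attenuated intensity and can be excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_filtering import cluster_mz_peaks
from .types import (
    EmptyInputError,
    EmptySelectionError,
    PeakList,
    SampleScanSet,
    Scan,
    ValidationError,
    WorkflowParams,
)

__all__ = [
    "estimate_scan_snr",
    "label_scans",
    "select_scans",
    "extract_sample_spectrum",
    "optimize_off_tolerance",
    "ScanLabelReport",
]

_NOISE_ESTIMATORS = ("median", "mean", "mad")


def estimate_scan_snr(scan: Scan, noise_estimator: str = "median") -> np.ndarray:
    """Per-peak SNR: peak intensity divided by a per-scan noise level.

    The default noise level is the median peak intensity of the scan, which
    is robust and makes the SNR invariant under uniform intensity rescaling.
    ``mean`` and ``mad`` (median + 1 MAD) estimators are provided as
    alternatives.
    """
    if scan.n_peaks == 0:
        raise EmptyInputError(f"scan {scan.index} has no peaks")
    if noise_estimator not in _NOISE_ESTIMATORS:
        raise ValidationError(f"unknown noise estimator {noise_estimator!r}")
    inten = scan.intensity
    if noise_estimator == "median":
        noise = float(np.median(inten))
    elif noise_estimator == "mean":
        noise = float(np.mean(inten))
    else:
        med = float(np.median(inten))
        noise = med + float(np.median(np.abs(inten - med)))
    if noise <= 0:
        # all-zero scan: no peak can rise above noise
        return np.zeros_like(inten)
    return inten / noise


@dataclass
class ScanLabelReport:
    """Per-scan labels with the evidence used to assign them.

    ``table`` columns: scan_index, label ("on"/"off"), n_high_snr (count of
    peaks with SNR strictly above the labeling threshold), tic.
    """

    sample_id: str
    table: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.table["label"])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "sample_id", self.sample_id)
        out.to_csv(path, index=False)


def label_scans(sample: SampleScanSet, params: WorkflowParams | None = None,
                noise_estimator: str = "median") -> ScanLabelReport:
    """Label each scan "on" or "off".

    A scan is "on" iff its count of peaks with SNR strictly above
    ``snr_label_threshold`` exceeds ``off_scan_tolerance`` — a tolerated
    number of high-SNR contaminant peaks (e.g. from the transfer line) may
    appear in off-scans without flipping the label.
    """
    params = params or WorkflowParams()
    rows = []
    for scan in sample:
        snr = estimate_scan_snr(scan, noise_estimator)
        n_high = int(np.count_nonzero(snr > params.snr_label_threshold))
        label = "on" if n_high > params.off_scan_tolerance else "off"
        scan.label = label
        rows.append({"scan_index": scan.index, "label": label,
                     "n_high_snr": n_high, "tic": scan.tic})
    return ScanLabelReport(sample_id=sample.sample_id,
                           table=pd.DataFrame(rows))


def _on_runs(labels: list[str]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive "on" labels as (start, stop) positions."""
    runs = []
    start = None
    for i, lab in enumerate(labels):
        if lab == "on" and start is None:
            start = i
        elif lab != "on" and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(labels)))
    return runs


def select_scans(report: ScanLabelReport, method: str) -> list[int]:
    """Select scan indices for extraction by one of the three methods.

    ``all_scans`` takes everything; ``on_scans`` the on-labeled scans;
    ``on_scans_no_edge`` the on-scans whose both neighbours exist and are
    also on (a missing neighbour at the sample boundary counts as off).
    An on-run of length <= 2 would contribute nothing under the no-edge
    rule, so its single highest-TIC member is rescued instead.
    """
    tbl = report.table
    indices = list(tbl["scan_index"])
    labels = list(tbl["label"])
    tics = list(tbl["tic"])

    if method == "all_scans":
        selected = indices
    elif method == "on_scans":
        selected = [i for i, lab in zip(indices, labels) if lab == "on"]
    elif method == "on_scans_no_edge":
        selected = []
        for start, stop in _on_runs(labels):
            if stop - start >= 3:
                selected.extend(indices[start + 1:stop - 1])
            else:
                best = max(range(start, stop), key=lambda p: tics[p])
                selected.append(indices[best])
    else:
        raise ValidationError(f"unknown extraction method {method!r}")

    if not selected:
        raise EmptySelectionError(
            f"sample {report.sample_id!r}: no scans selected by {method!r}"
        )
    return sorted(selected)


def extract_sample_spectrum(sample: SampleScanSet,
                            params: WorkflowParams | None = None) -> PeakList:
    """Extract one peak list per sample from its selected scans.

    Peaks across the selected scans are clustered into features by m/z
    (single-linkage within a ppm tolerance); each feature reports its mean
    intensity over the scans where it occurs, its occurrence fraction,
    intra-sample RSD (NaN for single occurrences) and mean SNR.
    """
    params = params or WorkflowParams()
    report = label_scans(sample, params)
    selected = select_scans(report, params.extraction_method)
    by_index = {scan.index: scan for scan in sample}

    mzs, intens, snrs, sources = [], [], [], []
    for idx in selected:
        scan = by_index[idx]
        if scan.n_peaks == 0:
            continue
        snr = estimate_scan_snr(scan)
        mzs.append(scan.mz)
        intens.append(scan.intensity)
        snrs.append(snr)
        sources.append(np.full(scan.n_peaks, idx))
    if not mzs:
        raise EmptySelectionError(f"sample {sample.sample_id!r}: selected scans empty")

    mz = np.concatenate(mzs)
    inten = np.concatenate(intens)
    snr = np.concatenate(snrs)
    source = np.concatenate(sources)

    assignment, collisions = cluster_mz_peaks(mz, inten, source,
                                              ppm=params.mz_tolerance_ppm)
    n_sel = len(selected)
    rows = []
    for cluster in assignment:
        c_int = inten[cluster]
        c_mz = mz[cluster]
        c_snr = snr[cluster]
        centroid = float(np.average(c_mz, weights=c_int)) if c_int.sum() > 0 \
            else float(np.mean(c_mz))
        n_occ = len(cluster)
        rsd = float(100.0 * np.std(c_int, ddof=1) / np.mean(c_int)) if n_occ >= 2 else np.nan
        rows.append({
            "mz": centroid,
            "intensity": float(np.mean(c_int)),
            "occurrence": n_occ / n_sel,
            "rsd": rsd,
            "snr": float(np.mean(c_snr)),
        })
    table = pd.DataFrame(rows, columns=list(PeakList.COLUMNS))
    table = table.sort_values("mz", kind="stable").reset_index(drop=True)
    return PeakList(sample_id=sample.sample_id, table=table,
                    n_selected_scans=n_sel, collisions=collisions)


def optimize_off_tolerance(samples: list[SampleScanSet],
                           truth: dict[str, list[str]],
                           tolerances: list[int],
                           params: WorkflowParams | None = None,
                           criterion: str = "youden") -> tuple[pd.DataFrame, int]:
    """Evaluate candidate off-scan tolerances against ground-truth labels.

    Returns a (tolerance, sensitivity, specificity, youden_j) table and the
    selected tolerance: the one maximizing Youden's J = sens + spec - 1
    (ties broken toward the smaller tolerance). ``criterion`` may also be
    ``"balanced_accuracy"`` (equivalent ordering, reported for clarity).
    """
    if not truth:
        raise ValidationError("ground-truth labels are required")
    if not tolerances:
        raise ValidationError("at least one candidate tolerance is required")
    if criterion not in ("youden", "balanced_accuracy"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    params = params or WorkflowParams()

    rows = []
    for tol in sorted(tolerances):
        tp = fn = tn = fp = 0
        for sample in samples:
            true_labels = truth[sample.sample_id]
            report = label_scans(sample, params.with_(off_scan_tolerance=tol))
            for pred, true in zip(report.labels, true_labels):
                if true == "on":
                    tp += pred == "on"
                    fn += pred == "off"
                else:
                    tn += pred == "off"
                    fp += pred == "on"
        sens = tp / (tp + fn) if (tp + fn) else np.nan
        spec = tn / (tn + fp) if (tn + fp) else np.nan
        rows.append({"tolerance": tol, "sensitivity": sens, "specificity": spec,
                     "youden_j": sens + spec - 1.0})
    table = pd.DataFrame(rows)
    scores = table["youden_j"] if criterion == "youden" \
        else (table["sensitivity"] + table["specificity"]) / 2.0
    # idxmax returns the first (smallest-tolerance) row on ties
    selected = int(table.loc[scores.idxmax(), "tolerance"])
    return table, selected
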