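"""End-to-end workflow orchestration with a per-stage run manifest.

Stage order is fixed:

    read -> label_scans -> select_scans -> extract -> snr_filter ->
    replicate_filter -> assemble_matrix -> sample_filter ->
    missing_value_filter -> rsd_filter -> pqn_normalize -> batch_correct ->
    phenotype_filter -> stats

Stages without their inputs (no QC samples, no cell counts, or a
pre-assembled matrix instead of raw scans) are marked "skipped" in the
manifest rather than silently omitted. Outputs carry no timestamps, so a
re-run with identical inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io as pio
from .feature_filtering import (
    assemble_feature_matrix,
    missing_value_sample_filter,
    replicate_filter,
    rsd_filter,
    sample_filter,
    snr_filter,
)
from .normalization import batch_correct, pqn_normalize
from .phenotype import (
    anova_per_feature,
    apply_phenotype_filter,
    concentration_response,
    pca_scores,
    phenotype_threshold,
    sample_counts,
)
from .scan_processing import extract_sample_spectrum, label_scans, select_scans
from .types import (
    FeatureMatrix,
    PulsedMSError,
    ValidationError,
    WorkflowParams,
)

__all__ = ["STAGES", "load_config", "run_workflow"]

logger = logging.getLogger(__name__)

STAGES = (
    "read", "label_scans", "select_scans", "extract",
    "snr_filter", "replicate_filter", "assemble_matrix",
    "sample_filter", "missing_value_filter", "rsd_filter",
    "pqn_normalize", "batch_correct", "phenotype_filter", "stats",
)


def load_config(path: str | Path) -> dict:
    """Load a YAML workflow config."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValidationError(f"config {path} is not a mapping")
    return config


class _Manifest:
    def __init__(self, config: dict, params: WorkflowParams):
        self.record = {
            "version": __version__,
            "inputs": config.get("inputs", {}),
            "params": dataclasses.asdict(params),
            "seed": config.get("seed"),
            "stages": [],
        }

    def add(self, stage: str, status: str, n_in=None, n_out=None, note: str = ""):
        entry = {"stage": stage, "status": status, "n_in": n_in, "n_out": n_out}
        if note:
            entry["note"] = note
        self.record["stages"].append(entry)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.record, indent=1, default=str))


def run_workflow(config: dict | str | Path) -> tuple[dict, dict]:
    """Run the full workflow from a config mapping or YAML path.

    Returns (outputs, manifest record). ``outputs`` maps artifact names to
    in-memory objects; everything is also written under ``output_dir``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    params = WorkflowParams(**config.get("params", {}))
    inputs = config.get("inputs", {})
    outdir = Path(config.get("output_dir", "pulsedms_output"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, params)
    outputs: dict = {}

    meta_path = inputs.get("metadata")
    if meta_path is None:
        raise ValidationError("config inputs.metadata is required")
    meta_records = pio.read_metadata(meta_path)
    sample_meta = pd.DataFrame(
        {
            "plate_id": [m.plate_id for m in meta_records],
            "well": [m.well for m in meta_records],
            "role": [m.role for m in meta_records],
            "drug": [m.drug for m in meta_records],
            "concentration_M": [m.concentration for m in meta_records],
            "replicate": [m.replicate for m in meta_records],
        },
        index=pd.Index([m.sample_id for m in meta_records], name="sample_id"),
    )

    matrix: FeatureMatrix
    if inputs.get("mzml_dir"):
        mzml_dir = Path(inputs["mzml_dir"])
        paths = sorted(mzml_dir.glob("*.mzML")) + sorted(mzml_dir.glob("*.mzml"))
        if not paths:
            raise PulsedMSError(f"stage read: no mzML files in {mzml_dir}")
        samples = [pio.read_mzml(p) for p in paths]
        n_scans = sum(len(s) for s in samples)
        manifest.add("read", "run", len(paths), n_scans,
                     note="samples in, scans out")

        label_rows = []
        reports = {}
        for sample in samples:
            report = label_scans(sample, params)
            reports[sample.sample_id] = report
            tbl = report.table.copy()
            tbl.insert(0, "sample_id", sample.sample_id)
            label_rows.append(tbl)
        labels_table = pd.concat(label_rows, ignore_index=True)
        labels_table.to_csv(outdir / "scan_labels.csv", index=False)
        outputs["scan_labels"] = labels_table
        manifest.add("label_scans", "run", n_scans, n_scans)

        n_selected = 0
        for sample in samples:
            n_selected += len(select_scans(reports[sample.sample_id],
                                           params.extraction_method))
        manifest.add("select_scans", "run", n_scans, n_selected)

        peaklists = []
        for sample in samples:
            try:
                peaklists.append(extract_sample_spectrum(sample, params))
            except PulsedMSError as exc:
                raise PulsedMSError(f"stage extract, sample "
                                    f"{sample.sample_id!r}: {exc}") from exc
        n_peaks = sum(len(p) for p in peaklists)
        manifest.add("extract", "run", n_selected, n_peaks,
                     note="selected scans in, features out")

        filtered = [snr_filter(p, params) for p in peaklists]
        manifest.add("snr_filter", "run", n_peaks, sum(len(p) for p in filtered))
        n_in = sum(len(p) for p in filtered)
        filtered = [replicate_filter(p, params) for p in filtered]
        manifest.add("replicate_filter", "run", n_in,
                     sum(len(p) for p in filtered))

        missing = [p.sample_id for p in filtered
                   if p.sample_id not in sample_meta.index]
        if missing:
            raise ValidationError(f"stage assemble_matrix: samples without "
                                  f"metadata: {missing}")
        matrix = assemble_feature_matrix(filtered, sample_meta,
                                         ppm=params.mz_tolerance_ppm)
        manifest.add("assemble_matrix", "run", len(filtered), matrix.n_features,
                     note="samples in, aligned features out")
    elif inputs.get("feature_matrix"):
        matrix = pio.read_feature_matrix(inputs["feature_matrix"])
        for stage in ("read", "label_scans", "select_scans", "extract",
                      "snr_filter", "replicate_filter"):
            manifest.add(stage, "skipped", note="pre-assembled matrix supplied")
        manifest.add("assemble_matrix", "skipped",
                     n_out=matrix.n_features, note="pre-assembled matrix supplied")
    else:
        raise ValidationError("config needs inputs.mzml_dir or inputs.feature_matrix")

    pio.write_feature_matrix(matrix, outdir / "feature_matrix_raw.tsv")

    n_in = matrix.n_features
    matrix = sample_filter(matrix, params)
    manifest.add("sample_filter", "run", n_in, matrix.n_features)

    n_in = matrix.n_samples
    matrix, dropped = missing_value_sample_filter(matrix, params)
    manifest.add("missing_value_filter", "run", n_in, matrix.n_samples,
                 note=f"dropped {len(dropped)} sample(s)")
    outputs["dropped_samples"] = dropped

    qc_ids = list(matrix.sample_meta.index[matrix.sample_meta["role"] == "qc"])
    if len(qc_ids) >= 2:
        n_in = matrix.n_features
        matrix = rsd_filter(matrix, qc_ids, params)
        manifest.add("rsd_filter", "run", n_in, matrix.n_features)
    else:
        logger.warning("RSD filter skipped: no intrastudy QC samples")
        manifest.add("rsd_filter", "skipped",
                     note="fewer than 2 QC samples available")
    pio.write_feature_matrix(matrix, outdir / "feature_matrix_filtered.tsv")

    matrix, quotients = pqn_normalize(matrix)
    quotients.rename("quotient").to_csv(outdir / "pqn_quotients.csv",
                                        index_label="sample_id")
    manifest.add("pqn_normalize", "run", matrix.n_samples, matrix.n_samples)

    matrix, coefficients = batch_correct(matrix)
    coefficients.to_csv(outdir / "batch_coefficients.csv", index=False)
    manifest.add("batch_correct", "run", matrix.n_features, matrix.n_features)
    outputs["batch_coefficients"] = coefficients

    counts_path = inputs.get("cell_counts")
    if counts_path:
        counts = pio.read_cell_counts(counts_path)
        death_mask = matrix.sample_meta["role"] == "death_control"
        death_ids = list(matrix.sample_meta.index[death_mask])
        if len(death_ids) < 2:
            raise PulsedMSError("stage phenotype_filter: cell counts supplied "
                                "but fewer than 2 death-control samples present")
        death_counts = sample_counts(matrix.select_samples(death_ids), counts)
        threshold = phenotype_threshold(death_counts,
                                        params.phenotype_quantile)
        n_in = matrix.n_samples
        matrix, flags = apply_phenotype_filter(matrix, counts, threshold)
        flags.to_csv(outdir / "phenotype_flags.csv", index=False)
        outputs["phenotype_flags"] = flags
        outputs["phenotype_threshold"] = threshold
        manifest.add("phenotype_filter", "run", n_in, matrix.n_samples,
                     note=f"threshold {threshold:.6g} cells")
    else:
        manifest.add("phenotype_filter", "skipped", note="no cell counts supplied")
    pio.write_feature_matrix(matrix, outdir / "feature_matrix_final.tsv")
    outputs["matrix"] = matrix

    # --- stats ---------------------------------------------------------
    scores, loadings, evr = pca_scores(matrix)
    scores.to_csv(outdir / "pca_scores.csv", index_label="sample_id")
    loadings.to_csv(outdir / "pca_loadings.csv", index_label="feature_id")
    outputs["pca_scores"] = scores
    outputs["pca_explained_variance_ratio"] = evr

    treated = matrix.sample_meta[matrix.sample_meta["role"] == "treated"]
    anova_tables = []
    response_tables = []
    for drug in sorted(set(treated["drug"])):
        conc_levels = treated.loc[treated["drug"] == drug, "concentration_M"]
        if conc_levels.nunique() < 2:
            continue
        table = anova_per_feature(matrix, drug)
        table.insert(0, "drug", drug)
        anova_tables.append(table)
        top = list(table.head(3)["feature_id"])
        flagged = []
        if "phenotype_flags" in outputs:
            fl = outputs["phenotype_flags"]
            flagged = list(fl.loc[(fl["drug"] == drug) & fl["flagged"],
                                  "concentration_M"])
        resp = concentration_response(matrix, drug, top,
                                      flagged_concentrations=flagged)
        resp.insert(0, "drug", drug)
        response_tables.append(resp)
    if anova_tables:
        anova_all = pd.concat(anova_tables, ignore_index=True)
        anova_all.to_csv(outdir / "anova.csv", index=False)
        outputs["anova"] = anova_all
    if response_tables:
        responses = pd.concat(response_tables, ignore_index=True)
        responses.to_csv(outdir / "concentration_response.csv", index=False)
        outputs["concentration_response"] = responses
    manifest.add("stats", "run", matrix.n_samples, matrix.n_samples,
                 note=f"{len(anova_tables)} drug(s) analyzed")

    manifest.write(outdir / "manifest.json")
    return outputs, manifest.record
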