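# pulsedms

Signal processing and analysis for pulsed direct-infusion (acoustic mist
ionization) mass-spectrometry metabolomics screens, plus a synthetic-data
module that makes the entire workflow testable at desk scale.

A pulsed ion source alternates between a charging ("on") phase that delivers
analyte to the detector and a discharge ("off") phase that does not. The
package covers the full path from raw centroided mzML scan data to
dose–response statistics:

1. **scan processing** — per-peak SNR (median-noise estimate), on/off scan
   classification (count of peaks with SNR > 15 vs. a tolerance of 3),
   edge-aware scan selection (`all_scans` / `on_scans` / `on_scans_no_edge`),
   per-sample spectrum extraction, and ROC-based tolerance optimization;
2. **feature filtering** — ppm-based single-linkage m/z clustering and the
   five-stage cascade: SNR filter (> 3), replicate filter (≥ 50% of selected
   scans), sample filter (≥ 50% of samples), missing-value sample filter
   (> 50% missing dropped), QC-based RSD filter (≤ 40%);
3. **normalization** — plate-wise probabilistic quotient normalization
   against the plate mean spectrum, then per-feature batch correction by
   plate median / grand median;
4. **phenotype & toxicology** — cell-phenotype filtering at the 95th
   quantile of death-control imaging counts, per-feature one-way ANOVA with
   Benjamini–Hochberg adjustment, PCA/UMAP, concentration–response summaries;
5. **synthetic** — seeded generators for pulsed runs (ground-truth scan
   labels, edge attenuation, off-scan contamination), technical-replicate
   matrices (median technical RSD calibrated near 39%), and a full
   2772-sample toxicity study (16 drugs × 9 half-log concentrations × 18
   replicates + 180 controls on nine 384-well plates) with truth tables for
   every downstream stage.

## CLI

```sh
# synthetic fixtures
pulsedms simulate pulsed-run --out fixtures/ --seed 1 --samples 6
pulsedms simulate study --out study/ --seed 1

# scan labeling only
pulsedms labels --mzml fixtures/ --out labels.csv

# full workflow from a YAML config
pulsedms process --config config.yaml

# matrix-level filter audit
pulsedms qc --matrix study/feature_matrix.tsv --out audit.csv
```

A workflow config names the inputs, parameter overrides and output
directory:

```yaml
inputs:
  mzml_dir: fixtures/            # or feature_matrix: study/feature_matrix.tsv
  metadata: study/metadata.csv
  cell_counts: study/cell_counts.csv   # optional; phenotype stage skipped if absent
params:
  snr_label_threshold: 15
  off_scan_tolerance: 3
  extraction_method: on_scans_no_edge
  rsd_threshold: 40
output_dir: results/
```

`run_workflow` executes the 14 stages in a fixed order and writes a
`manifest.json` with per-stage in/out counts; re-runs on identical inputs
are bit-identical. Stages without inputs (no QC samples, no cell counts)
are marked "skipped".

## File formats

- mzML: centroided MS1, negative mode; base64 64-bit float arrays (a
  minimal stdlib reader/writer — profile-mode data are rejected with a
  pointer to centroid upstream);
- metadata CSV: `sample_id, plate_id, well, role, drug, concentration_M,
  replicate` with roles `treated | dmso_control | death_control | qc`;
- cell counts CSV: `plate_id, well, cell_count` (plate id optional for
  single-plate tables);
- feature matrix: TSV (missing values as empty fields, never 0) plus a JSON
  sidecar carrying feature m/z and sample metadata.
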