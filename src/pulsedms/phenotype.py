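"""Cell-phenotype filtering and dose-response statistics.

Treatment groups whose imaging cell counts fall below a quantile of the
death-control distribution are flagged as cytotoxic and removed before any
multivariate or univariate analysis; the remaining concentration range is
summarized per feature with one-way ANOVA, PCA and per-concentration
medians.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    CellCountTable,
    FeatureMatrix,
    PulsedMSError,
    ValidationError,
)

__all__ = [
    "phenotype_threshold",
    "treatment_groups",
    "apply_phenotype_filter",
    "anova_per_feature",
    "pca_scores",
    "umap_embedding",
    "concentration_response",
    "impute_half_minimum",
]

logger = logging.getLogger(__name__)


def phenotype_threshold(death_control_counts, q: float = 0.95) -> float:
    """q-quantile of the death-control cell counts (linear interpolation)."""
    counts = np.asarray(list(death_control_counts), dtype=float)
    if counts.size < 2:
        raise PulsedMSError(
            "phenotype threshold needs >= 2 death-control counts"
        )
    if not 0.0 < q < 1.0:
        raise ValidationError(f"quantile must lie in (0, 1), got {q}")
    return float(np.quantile(counts, q))


def _group_key(row: pd.Series) -> tuple:
    role = row["role"]
    if role == "treated":
        return ("treated", row["drug"], float(row["concentration_M"]))
    return (role, "", np.nan)


def treatment_groups(sample_meta: pd.DataFrame) -> pd.Series:
    """Map sample_id -> group key (role, drug, concentration)."""
    return sample_meta.apply(_group_key, axis=1)


def sample_counts(matrix: FeatureMatrix, counts: CellCountTable) -> pd.Series:
    """Per-sample cell counts looked up by (plate_id, well)."""
    out = {}
    for sid, row in matrix.sample_meta.iterrows():
        c = counts.get(str(row["plate_id"]), str(row["well"]))
        if c is None:
            raise ValidationError(f"sample {sid!r} has no cell count")
        out[sid] = c
    return pd.Series(out).loc[matrix.intensities.index]


def apply_phenotype_filter(matrix: FeatureMatrix, counts: CellCountTable,
                           threshold: float, mode: str = "group_median"
                           ) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Remove samples of groups whose cell counts indicate cytotoxicity.

    In the default ``group_median`` mode a (drug, concentration) group is
    flagged iff its median count is strictly below the threshold, and all
    its samples are removed; control groups are judged by the same rule.
    ``per_sample`` mode flags individual samples instead. Returns the
    filtered matrix and a flag report (drug, concentration_M,
    group_median_count, n_samples, flagged).
    """
    if mode not in ("group_median", "per_sample"):
        raise ValidationError(f"unknown phenotype filter mode {mode!r}")
    per_sample = sample_counts(matrix, counts)
    groups = treatment_groups(matrix.sample_meta)

    rows = []
    removed: set[str] = set()
    for key, sids in groups.groupby(groups).groups.items():
        sids = list(sids)
        group_counts = per_sample.loc[sids]
        median = float(group_counts.median())
        if mode == "group_median":
            flagged = median < threshold
            if flagged:
                removed.update(sids)
        else:
            flagged_samples = group_counts.index[group_counts < threshold]
            removed.update(flagged_samples)
            flagged = len(flagged_samples) > 0
        role, drug, conc = key
        rows.append({"role": role, "drug": drug, "concentration_M": conc,
                     "group_median_count": median, "n_samples": len(sids),
                     "flagged": bool(flagged)})
    kept = [s for s in matrix.intensities.index if s not in removed]
    if not kept:
        raise PulsedMSError("phenotype filter removed every sample")
    report = pd.DataFrame(rows).sort_values(
        ["role", "drug", "concentration_M"]).reset_index(drop=True)
    return matrix.select_samples(kept), report


def impute_half_minimum(values: pd.DataFrame) -> pd.DataFrame:
    """Fill missing cells with half the feature's observed minimum.

    A left-censoring heuristic used only for statistics; raw matrices are
    never imputed. Features with no observed value at all stay missing.
    """
    mins = values.min(axis=0, skipna=True)
    return values.fillna(mins / 2.0)


def anova_per_feature(matrix: FeatureMatrix, drug: str,
                      log_transform: bool = True) -> pd.DataFrame:
    """One-way ANOVA across concentration groups for every feature.

    Intensities are half-minimum imputed and (by default) log10-transformed.
    Features entirely missing in the drug's samples, or with any group left
    empty, are skipped and logged. P-values are Benjamini-Hochberg adjusted
    across features. Returns (feature_id, F, p, p_adj) sorted by p.
    """
    meta = matrix.sample_meta
    mask = (meta["role"] == "treated") & (meta["drug"] == drug)
    sids = list(meta.index[mask])
    if not sids:
        raise ValidationError(f"no treated samples for drug {drug!r}")
    sub = matrix.intensities.loc[sids]
    conc = meta.loc[sids, "concentration_M"].astype(float)
    levels = sorted(conc.unique())
    if len(levels) < 2:
        raise ValidationError(f"drug {drug!r} has < 2 concentration groups")

    data = impute_half_minimum(sub)
    if log_transform:
        data = np.log10(data)

    rows = []
    skipped = 0
    for fid in data.columns:
        col = data[fid]
        if col.isna().any():
            skipped += 1
            continue
        groups = [col[conc == level].to_numpy() for level in levels]
        if any(len(g) < 2 for g in groups):
            skipped += 1
            continue
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*groups)
            if np.isnan(f_stat):
                f_stat, p = 0.0, 1.0
        rows.append({"feature_id": fid, "F": float(f_stat), "p": float(p)})
    if skipped:
        logger.info("ANOVA (%s): %d feature(s) skipped", drug, skipped)
    table = pd.DataFrame(rows, columns=["feature_id", "F", "p"])
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["p_adj"] = pd.Series(dtype=float)
    return table.sort_values("p", kind="stable").reset_index(drop=True)


def pca_scores(matrix: FeatureMatrix, n_components: int = 2,
               scale: bool = False, log_transform: bool = True
               ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of the (imputed, log10) matrix.

    Data are mean-centered; with ``scale=True`` features are additionally
    unit-variance scaled and constant features dropped (logged). Returns
    (scores, loadings, explained variance ratio).
    """
    from sklearn.decomposition import PCA

    data = impute_half_minimum(matrix.intensities)
    data = data.dropna(axis=1, how="any")
    if log_transform:
        data = np.log10(data)
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValidationError("PCA needs >= 2 samples and >= 2 features")
    if scale:
        sd = data.std(axis=0, ddof=1)
        constant = sd.index[(sd == 0) | sd.isna()]
        if len(constant):
            logger.info("PCA: dropping %d constant feature(s) under scaling",
                        len(constant))
            data = data.drop(columns=list(constant))
        data = (data - data.mean(axis=0)) / data.std(axis=0, ddof=1)
    n_components = min(n_components, data.shape[0] - 1, data.shape[1])
    pca = PCA(n_components=n_components)  # centers internally
    scores = pca.fit_transform(data.to_numpy())
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=data.index, columns=pcs),
        pd.DataFrame(pca.components_.T, index=data.columns, columns=pcs),
        pca.explained_variance_ratio_,
    )


def umap_embedding(matrix: FeatureMatrix, n_neighbors: int = 15,
                   random_state: int = 0, log_transform: bool = True
                   ) -> pd.DataFrame:
    """2-D UMAP embedding (visualization aid; delegated to umap-learn)."""
    import umap  # deferred: heavy import, optional dependency

    data = impute_half_minimum(matrix.intensities).dropna(axis=1, how="any")
    if log_transform:
        data = np.log10(data)
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        random_state=random_state)
    emb = reducer.fit_transform(data.to_numpy())
    return pd.DataFrame(emb, index=data.index, columns=["UMAP1", "UMAP2"])


def concentration_response(matrix: FeatureMatrix, drug: str,
                           feature_ids: list[str],
                           flagged_concentrations: list[float] | None = None,
                           smooth_frac: float = 0.6) -> pd.DataFrame:
    """Per-concentration medians and IQRs for selected features, with a
    lowess smoothing line over log10 concentration (no dose-response model
    is fitted). Flagged (cytotoxic) concentrations are marked.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    meta = matrix.sample_meta
    mask = (meta["role"] == "treated") & (meta["drug"] == drug)
    sids = list(meta.index[mask])
    if not sids:
        raise ValidationError(f"no treated samples for drug {drug!r}")
    conc = meta.loc[sids, "concentration_M"].astype(float)
    flagged = set(flagged_concentrations or [])

    rows = []
    for fid in feature_ids:
        col = matrix.intensities.loc[sids, fid]
        summaries = []
        for level in sorted(conc.unique()):
            vals = col[conc == level].dropna()
            summaries.append({
                "feature_id": fid, "concentration_M": level,
                "median": float(vals.median()) if len(vals) else np.nan,
                "q1": float(vals.quantile(0.25)) if len(vals) else np.nan,
                "q3": float(vals.quantile(0.75)) if len(vals) else np.nan,
                "n": int(len(vals)),
                "cytotoxic": level in flagged,
            })
        observed = [s for s in summaries if np.isfinite(s["median"])]
        if len(observed) >= 3:
            x = np.log10([s["concentration_M"] for s in observed])
            y = [s["median"] for s in observed]
            sm = lowess(y, x, frac=smooth_frac, return_sorted=True)
            smooth = dict(zip(sm[:, 0], sm[:, 1]))
            for s in observed:
                s["smoothed"] = float(smooth.get(np.log10(s["concentration_M"]), np.nan))
        for s in summaries:
            s.setdefault("smoothed", np.nan)
        rows.extend(summaries)
    return pd.DataFrame(rows)
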