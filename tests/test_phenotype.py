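import numpy as np
import pandas as pd
import pytest

from pulsedms.phenotype import (
    anova_per_feature,
    apply_phenotype_filter,
    concentration_response,
    impute_half_minimum,
    pca_scores,
    phenotype_threshold,
    sample_counts,
)
from pulsedms.synthetic import StudySimConfig, simulate_toxicity_study
from pulsedms.types import CellCountTable, PulsedMSError, ValidationError

from conftest import make_matrix


class TestThreshold:
    def test_one_to_hundred(self):
        assert phenotype_threshold(range(1, 101), 0.95) == pytest.approx(95.05)

    def test_constant_counts(self):
        for q in (0.05, 0.5, 0.95):
            assert phenotype_threshold([7, 7, 7], q) == 7.0

    def test_two_counts(self):
        assert phenotype_threshold([0, 1000], 0.95) == pytest.approx(950.0)

    def test_needs_two_counts(self):
        with pytest.raises(PulsedMSError):
            phenotype_threshold([500], 0.95)

    def test_quantile_range(self):
        with pytest.raises(ValidationError):
            phenotype_threshold([1, 2], 1.0)


def toy_grouped_matrix(group_medians, n_per_group=3):
    """One treated group per median; cell counts equal the target median."""
    n = len(group_medians) * n_per_group
    sample_ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame({
        "plate_id": "P1",
        "well": [f"A{i + 1:02d}" for i in range(n)],
        "role": "treated",
        "drug": [f"drug{g}" for g in range(len(group_medians))
                 for _ in range(n_per_group)],
        "concentration_M": 1e-6,
        "replicate": list(range(1, n_per_group + 1)) * len(group_medians),
    }, index=sample_ids)
    matrix = make_matrix(np.ones((n, 2)), meta=meta, sample_ids=sample_ids)
    counts = CellCountTable({
        ("P1", meta.loc[s, "well"]): group_medians[i // n_per_group]
        for i, s in enumerate(sample_ids)
    })
    return matrix, counts


class TestPhenotypeFilter:
    def test_group_below_threshold_flagged(self):
        matrix, counts = toy_grouped_matrix([3000, 2500, 400])
        out, report = apply_phenotype_filter(matrix, counts, threshold=602)
        flagged = report[report["flagged"]]
        assert list(flagged["drug"]) == ["drug2"]
        assert out.n_samples == 6

    def test_zero_threshold_flags_nothing(self):
        matrix, counts = toy_grouped_matrix([3000, 2500, 400])
        out, report = apply_phenotype_filter(matrix, counts, threshold=0)
        assert not report["flagged"].any()
        assert out.n_samples == matrix.n_samples

    def test_never_removes_group_at_or_above_threshold(self):
        rng = np.random.default_rng(3)
        medians = list(rng.integers(100, 5000, size=8))
        matrix, counts = toy_grouped_matrix(medians)
        threshold = 1500
        _, report = apply_phenotype_filter(matrix, counts, threshold=threshold)
        for row in report.itertuples():
            assert row.flagged == (row.group_median_count < threshold)

    def test_per_sample_mode(self):
        matrix, counts = toy_grouped_matrix([3000, 400])
        out, _ = apply_phenotype_filter(matrix, counts, threshold=602,
                                        mode="per_sample")
        assert out.n_samples == 3

    def test_missing_count_is_error(self):
        matrix, _ = toy_grouped_matrix([3000])
        with pytest.raises(ValidationError):
            apply_phenotype_filter(matrix, CellCountTable({}), threshold=1)

    def test_default_study_retains_all_dmso(self, study):
        config, matrix, counts, _, _ = study
        death = matrix.sample_meta.index[
            matrix.sample_meta["role"] == "death_control"]
        dc = sample_counts(matrix.select_samples(list(death)), counts)
        threshold = phenotype_threshold(dc, 0.95)
        out, _ = apply_phenotype_filter(matrix, counts, threshold)
        n_dmso = (matrix.sample_meta["role"] == "dmso_control").sum()
        assert (out.sample_meta["role"] == "dmso_control").sum() == n_dmso
        treated_before = (matrix.sample_meta["role"] == "treated").sum()
        treated_after = (out.sample_meta["role"] == "treated").sum()
        assert treated_after / treated_before > 0.80

    def test_flags_match_generator_truth(self, study):
        _, matrix, counts, _, truth = study
        death = matrix.sample_meta.index[
            matrix.sample_meta["role"] == "death_control"]
        dc = sample_counts(matrix.select_samples(list(death)), counts)
        threshold = phenotype_threshold(dc, 0.95)
        _, report = apply_phenotype_filter(matrix, counts, threshold)
        flagged = report[report["flagged"] & (report["role"] == "treated")]
        got = {(r.drug, round(float(r.concentration_M), 12))
               for r in flagged.itertuples()}
        expected = {(r.drug, round(float(r.concentration_M), 12))
                    for r in truth["expected_flags"].itertuples()}
        assert got == expected


def anova_matrix(groups, drug="drugX"):
    """Single-feature matrix from {concentration: values} (plus a dummy)."""
    values, concs = [], []
    for conc, vals in groups.items():
        values.extend(vals)
        concs.extend([conc] * len(vals))
    n = len(values)
    sample_ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame({
        "plate_id": "P1", "well": [f"A{i + 1:02d}" for i in range(n)],
        "role": "treated", "drug": drug, "concentration_M": concs,
        "replicate": 1,
    }, index=sample_ids)
    data = np.column_stack([values, np.ones(n)])
    return make_matrix(data, meta=meta, sample_ids=sample_ids)


class TestAnova:
    def test_identical_groups(self):
        m = anova_matrix({1e-6: [1.0, 2.0, 3.0], 1e-5: [1.0, 2.0, 3.0]})
        table = anova_per_feature(m, "drugX", log_transform=False)
        row = table[table["feature_id"] == "F0000"].iloc[0]
        assert row["F"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_closed_form_f150(self):
        m = anova_matrix({1e-6: [1.0, 2.0, 3.0], 1e-5: [11.0, 12.0, 13.0]})
        table = anova_per_feature(m, "drugX", log_transform=False)
        row = table[table["feature_id"] == "F0000"].iloc[0]
        assert row["F"] == pytest.approx(150.0)
        assert row["p"] == pytest.approx(2.54e-4, rel=0.05)

    def test_bh_adjustment_step_up(self):
        from statsmodels.stats.multitest import multipletests

        def bh_oracle(pvals):
            # independent step-up implementation
            n = len(pvals)
            order = np.argsort(pvals)
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, pvals[i] * n / rank)
                adj[i] = running
            return adj

        np.testing.assert_allclose(bh_oracle([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = rng.random(rng.integers(1, 30))
            np.testing.assert_allclose(multipletests(p, method="fdr_bh")[1],
                                       bh_oracle(p), rtol=1e-12)

    def test_duplication_increases_f(self):
        groups = {1e-6: [1.0, 2.0, 3.0], 1e-5: [2.0, 3.0, 5.0]}
        f1 = anova_per_feature(anova_matrix(groups), "drugX",
                               log_transform=False)
        dup = {c: list(v) * 3 for c, v in groups.items()}
        f3 = anova_per_feature(anova_matrix(dup), "drugX", log_transform=False)
        v1 = f1[f1["feature_id"] == "F0000"]["F"].iloc[0]
        v3 = f3[f3["feature_id"] == "F0000"]["F"].iloc[0]
        assert v3 > v1

    def test_perturbed_features_rank_high(self, small_study):
        _, matrix, _, _, truth = small_study
        drug = "drug03"  # non-cytotoxic in the small design
        table = anova_per_feature(matrix, drug)
        perturbed = set(truth["effects"].loc[
            truth["effects"]["drug"] == drug, "feature_id"])
        top = set(table.head(len(perturbed))["feature_id"])
        assert len(top & perturbed) >= len(perturbed) // 2

    def test_requires_two_groups(self):
        m = anova_matrix({1e-6: [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError):
            anova_per_feature(m, "drugX")


class TestPca:
    def test_identical_samples_identical_scores(self):
        rng = np.random.default_rng(4)
        values = rng.lognormal(3, 1, size=(5, 6))
        values[3] = values[1]
        scores, _, _ = pca_scores(make_matrix(values))
        np.testing.assert_allclose(scores.iloc[3], scores.iloc[1], atol=1e-9)

    def test_rank_one_matrix(self):
        base = np.array([1.0, 2.0, 4.0])
        values = np.outer([1.0, 2.0, 3.0, 4.0], base)
        _, _, evr = pca_scores(make_matrix(values), log_transform=False)
        assert evr[0] == pytest.approx(1.0)

    def test_matches_independent_eigendecomposition(self):
        values = np.array([[1.0, 2.0, 3.0],
                           [2.0, 1.0, 5.0],
                           [4.0, 7.0, 1.0]])
        scores, _, evr = pca_scores(make_matrix(values), n_components=2,
                                    log_transform=False)
        # oracle: eigendecomposition of the sample covariance
        centered = values - values.mean(axis=0)
        cov = centered.T @ centered / (values.shape[0] - 1)
        eigval, eigvec = np.linalg.eigh(cov)
        order = np.argsort(eigval)[::-1]
        expected = centered @ eigvec[:, order[:2]]
        for k in range(2):
            got = scores.iloc[:, k].to_numpy()
            assert (np.allclose(got, expected[:, k], atol=1e-9)
                    or np.allclose(got, -expected[:, k], atol=1e-9))
        np.testing.assert_allclose(evr, eigval[order[:2]] / eigval.sum(),
                                   atol=1e-12)

    def test_variance_ratios_sorted(self, techrep):
        _, matrix, _ = techrep
        _, _, evr = pca_scores(matrix, n_components=5)
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() <= 1.0 + 1e-9

    def test_scale_drops_constant_feature(self):
        values = np.column_stack([np.ones(4), np.arange(1.0, 5.0),
                                  np.arange(2.0, 6.0)])
        scores, loadings, _ = pca_scores(make_matrix(values),
                                         log_transform=False, scale=True)
        assert "F0000" not in loadings.index


class TestImputation:
    def test_half_minimum(self):
        df = pd.DataFrame({"a": [2.0, np.nan, 8.0], "b": [1.0, 1.0, 1.0]})
        out = impute_half_minimum(df)
        assert out.loc[1, "a"] == 1.0
        assert not out.isna().any().any()

    def test_all_missing_column_stays_missing(self):
        df = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        out = impute_half_minimum(df)
        assert out["a"].isna().all()


class TestConcentrationResponse:
    def test_single_concentration(self):
        m = anova_matrix({1e-6: [1.0, 2.0, 3.0]})
        out = concentration_response(m, "drugX", ["F0000"])
        assert len(out) == 1
        assert out.iloc[0]["median"] == 2.0

    def test_two_concentration_medians(self):
        m = anova_matrix({1e-6: [1.0, 2.0, 3.0], 1e-5: [10.0, 20.0, 30.0]})
        out = concentration_response(m, "drugX", ["F0000"])
        assert list(out["median"]) == [2.0, 20.0]

    def test_cytotoxic_marking(self):
        m = anova_matrix({1e-6: [1.0], 1e-5: [2.0]})
        out = concentration_response(m, "drugX", ["F0000"],
                                     flagged_concentrations=[1e-5])
        assert list(out["cytotoxic"]) == [False, True]

    def test_monotone_hill_feature(self):
        # near-noiseless generator: a positively perturbed feature of a
        # non-cytotoxic drug has monotone per-concentration medians
        config = StudySimConfig(seed=3, n_drugs=4, n_concentrations=6,
                                replicates_per_group=8, n_dmso_groups=1,
                                n_death_groups=1, n_plates=2,
                                n_real_features=30, n_noise_features=0,
                                n_cytotoxic_drugs=0, n_perturbed_per_drug=3,
                                scan_rsd=0.02, dilution_sd=0.0,
                                plate_effect_sd=0.0, real_missing_rate=0.0)
        matrix, _, _, truth = simulate_toxicity_study(config)
        eff = truth["effects"]
        row = eff[(eff["drug"] == "drug01") & (eff["direction"] > 0)].iloc[0]
        out = concentration_response(matrix, "drug01", [row["feature_id"]])
        medians = out.sort_values("concentration_M")["median"].to_numpy()
        assert (np.diff(medians) > -1e-9).all()
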