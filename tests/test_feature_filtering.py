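import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsedms.feature_filtering import (
    assemble_feature_matrix,
    cluster_mz_peaks,
    feature_rsd,
    missing_value_sample_filter,
    replicate_filter,
    rsd_filter,
    sample_filter,
    snr_filter,
)
from pulsedms.types import EmptyInputError, PeakList, ValidationError, WorkflowParams

from conftest import make_matrix, random_matrix


def peaklist(snr=None, occurrence=None, n=None):
    n = n or len(snr if snr is not None else occurrence)
    table = pd.DataFrame({
        "mz": 100.0 + np.arange(n),
        "intensity": np.full(n, 50.0),
        "occurrence": occurrence if occurrence is not None else np.ones(n),
        "rsd": np.full(n, 10.0),
        "snr": snr if snr is not None else np.full(n, 100.0),
    })
    return PeakList(sample_id="s", table=table, n_selected_scans=6)


def brute_force_cluster(mz, ppm):
    """Independent oracle: pairwise single-linkage by repeated merging."""
    clusters = [[i] for i in range(len(mz))]
    changed = True
    while changed:
        changed = False
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                link = any(
                    abs(mz[i] - mz[j]) <= ppm * 1e-6 * (mz[i] + mz[j]) / 2
                    for i in clusters[a] for j in clusters[b]
                )
                if link:
                    clusters[a] += clusters.pop(b)
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(sorted(c)) for c in clusters)


class TestClustering:
    def test_four_ppm_apart_merges(self):
        clusters, _ = cluster_mz_peaks([100.0000, 100.0004], [1.0, 1.0],
                                       [0, 1], ppm=5)
        assert len(clusters) == 1

    def test_twenty_ppm_apart_splits(self):
        clusters, _ = cluster_mz_peaks([100.000, 100.002], [1.0, 1.0],
                                       [0, 1], ppm=5)
        assert len(clusters) == 2

    def test_single_peak(self):
        clusters, collisions = cluster_mz_peaks([150.5], [3.0], [0], ppm=5)
        assert len(clusters) == 1 and collisions == 0

    def test_same_source_collision_keeps_more_intense(self):
        clusters, collisions = cluster_mz_peaks(
            [100.0000, 100.0002], [1.0, 9.0], [0, 0], ppm=5)
        assert collisions == 1
        assert len(clusters) == 1
        assert list(clusters[0]) == [1]

    def test_against_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 25))
            mz = np.sort(rng.uniform(100, 100.01, size=n))
            clusters, _ = cluster_mz_peaks(mz, np.ones(n), np.arange(n), ppm=5)
            got = sorted(tuple(sorted(c)) for c in clusters)
            assert got == brute_force_cluster(list(mz), 5)

    def test_invalid_ppm(self):
        with pytest.raises(ValidationError):
            cluster_mz_peaks([100.0], [1.0], [0], ppm=0)


class TestSnrFilter:
    def test_strict_boundary(self):
        out = snr_filter(peaklist(snr=[2.9, 3.0, 3.1]))
        assert list(out.table["snr"]) == [3.1]

    def test_all_pass(self):
        out = snr_filter(peaklist(snr=[100.0] * 4))
        assert len(out) == 4

    def test_empty(self):
        out = snr_filter(peaklist(snr=[]))
        assert len(out) == 0


class TestReplicateFilter:
    def test_three_of_six_retained(self):
        out = replicate_filter(peaklist(occurrence=[3 / 6]))
        assert len(out) == 1

    def test_two_of_six_removed(self):
        out = replicate_filter(peaklist(occurrence=[2 / 6]))
        assert len(out) == 0

    def test_zero_threshold_keeps_everything(self):
        out = replicate_filter(peaklist(occurrence=[0.0, 0.1, 1.0]),
                               WorkflowParams(replicate_fraction=0.0))
        assert len(out) == 3


class TestSampleFilter:
    def test_half_retained(self):
        m = make_matrix([[1, 1], [1, np.nan], [np.nan, np.nan], [1, np.nan]])
        out = sample_filter(m)  # feature 0: 3/4, feature 1: 1/4
        assert list(out.intensities.columns) == ["F0000"]

    def test_two_of_four_at_half(self):
        m = make_matrix([[1.0], [1.0], [np.nan], [np.nan]])
        assert sample_filter(m).n_features == 1

    def test_full_feature_survives_any_threshold(self):
        m = make_matrix([[1.0], [2.0], [3.0]])
        out = sample_filter(m, WorkflowParams(sample_fraction=1.0))
        assert out.n_features == 1


class TestMissingValueFilter:
    def test_sixty_percent_dropped(self):
        values = np.ones((2, 5))
        values[0, :3] = np.nan  # 60% missing
        m = make_matrix(values)
        out, dropped = missing_value_sample_filter(m)
        assert dropped == ["s0"]

    def test_exactly_half_retained(self):
        values = np.ones((2, 4))
        values[0, :2] = np.nan  # exactly 50%
        out, dropped = missing_value_sample_filter(make_matrix(values))
        assert dropped == []

    def test_complete_sample_retained(self):
        out, dropped = missing_value_sample_filter(make_matrix(np.ones((3, 4))))
        assert dropped == []

    def test_all_dropped_is_error(self):
        values = np.full((2, 4), np.nan)
        values[:, 0] = 1.0  # 75% missing everywhere
        with pytest.raises(EmptyInputError):
            missing_value_sample_filter(make_matrix(values))


class TestRsdFilter:
    def test_worked_example_removed(self):
        # QC values [1,2,3]: mean 2, sd 1, RSD 50% > 40 -> removed
        m = make_matrix([[1.0], [2.0], [3.0]])
        out = rsd_filter(m, list(m.intensities.index))
        assert out.n_features == 0
        assert feature_rsd(m, list(m.intensities.index)).iloc[0] == pytest.approx(50.0)

    def test_constant_retained(self):
        m = make_matrix([[5.0], [5.0], [5.0]])
        assert rsd_filter(m, list(m.intensities.index)).n_features == 1

    def test_exactly_forty_retained(self):
        # construct values with RSD exactly 40%: mean 1, sd 0.4
        vals = np.array([1 - 0.4 / np.sqrt(2), 1 + 0.4 / np.sqrt(2)])
        m = make_matrix(vals.reshape(-1, 1))
        ids = list(m.intensities.index)
        assert feature_rsd(m, ids).iloc[0] == pytest.approx(40.0)
        assert rsd_filter(m, ids).n_features == 1

    def test_undefined_rsd_removed(self):
        m = make_matrix([[1.0, 1.0], [np.nan, 1.0], [np.nan, 1.0]])
        out = rsd_filter(m, list(m.intensities.index))
        assert list(out.intensities.columns) == ["F0001"]

    def test_skipped_without_qc(self, caplog):
        m = make_matrix([[1.0], [200.0], [3.0]])
        out = rsd_filter(m, ["s0"])  # single QC: skip
        assert out.n_features == m.n_features


def brute_force_filters(matrix, params):
    """Direct counting loops, independent of the pandas implementations."""
    vals = matrix.intensities.to_numpy()
    n, m = vals.shape
    kept_features = [
        j for j in range(m)
        if sum(not np.isnan(vals[i, j]) for i in range(n)) / n >= params.sample_fraction
    ]
    kept_samples = [
        i for i in range(n)
        if sum(np.isnan(vals[i, j]) for j in range(m)) / m <= params.missing_fraction
    ]
    rsd_kept = []
    for j in range(m):
        col = [vals[i, j] for i in range(n) if not np.isnan(vals[i, j])]
        if len(col) < 2:
            continue
        mean = sum(col) / len(col)
        sd = (sum((x - mean) ** 2 for x in col) / (len(col) - 1)) ** 0.5
        if 100 * sd / mean <= params.rsd_threshold:
            rsd_kept.append(j)
    return kept_features, kept_samples, rsd_kept


class TestFilterProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, n=20, m=30, missing=0.35)
        params = WorkflowParams()
        bf_features, bf_samples, bf_rsd = brute_force_filters(m, params)

        out = sample_filter(m, params)
        assert list(out.intensities.columns) == \
            [m.intensities.columns[j] for j in bf_features]

        out2, dropped = missing_value_sample_filter(m, params)
        assert list(out2.intensities.index) == \
            [m.intensities.index[i] for i in bf_samples]

        out3 = rsd_filter(m, list(m.intensities.index), params)
        assert list(out3.intensities.columns) == \
            [m.intensities.columns[j] for j in bf_rsd]

    def test_idempotence(self):
        rng = np.random.default_rng(11)
        m = random_matrix(rng)
        once = sample_filter(m)
        twice = sample_filter(once)
        pd.testing.assert_frame_equal(once.intensities, twice.intensities)
        qc = list(m.intensities.index)
        r1 = rsd_filter(m, qc)
        r2 = rsd_filter(r1, qc)
        pd.testing.assert_frame_equal(r1.intensities, r2.intensities)

    def test_commutes_with_reordering(self):
        rng = np.random.default_rng(13)
        m = random_matrix(rng)
        perm = rng.permutation(m.n_samples)
        shuffled = m.select_samples([m.intensities.index[i] for i in perm])
        a = sample_filter(m)
        b = sample_filter(shuffled)
        assert set(a.intensities.columns) == set(b.intensities.columns)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotonicity(self, t1, t2):
        lo, hi = sorted([t1, t2])
        rng = np.random.default_rng(17)
        m = random_matrix(rng)
        n_lo = sample_filter(m, WorkflowParams(sample_fraction=lo)).n_features
        n_hi = sample_filter(m, WorkflowParams(sample_fraction=hi)).n_features
        assert n_hi <= n_lo


class TestAssemble:
    def test_alignment_and_missingness(self):
        meta = pd.DataFrame({
            "plate_id": "P1", "well": ["A01", "A02"], "role": "qc",
            "drug": "", "concentration_M": np.nan, "replicate": 1,
        }, index=["a", "b"])
        pl_a = PeakList(sample_id="a", table=pd.DataFrame({
            "mz": [100.0, 200.0], "intensity": [10.0, 20.0],
            "occurrence": [1.0, 1.0], "rsd": [np.nan] * 2, "snr": [50.0] * 2}))
        pl_b = PeakList(sample_id="b", table=pd.DataFrame({
            "mz": [100.0002, 300.0], "intensity": [12.0, 30.0],
            "occurrence": [1.0, 1.0], "rsd": [np.nan] * 2, "snr": [50.0] * 2}))
        matrix = assemble_feature_matrix([pl_a, pl_b], meta, ppm=5)
        assert matrix.n_features == 3
        shared = matrix.intensities.iloc[:, 0]
        np.testing.assert_allclose(shared.to_numpy(), [10.0, 12.0])
        assert matrix.missing_mask.iloc[0, 2] and matrix.missing_mask.iloc[1, 1]
        mz = matrix.feature_mz.to_numpy()
        assert (np.diff(mz) > 0).all()

    def test_empty_input(self):
        with pytest.raises(EmptyInputError):
            assemble_feature_matrix([], pd.DataFrame())
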