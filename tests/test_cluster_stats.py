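"""Cluster formation, permutation nulls, correlation clustering."""

import numpy as np
import pytest
from scipy import stats

from tntdecode.cluster_stats import (
    corr_cluster_timecourse,
    form_clusters,
    independent_t,
    one_sample_t,
    perm_test_condition_diff,
    perm_test_group_diff,
    perm_test_paired_maps,
    perm_test_vs_chance,
    rho_to_t,
)
from tntdecode.decoding import DecodingResult


def brute_force_1d_clusters(values, threshold):
    """Independent oracle: scan contiguous supra-threshold runs."""
    clusters, current = [], []
    for i, v in enumerate(values):
        if v > threshold:
            current.append(i)
        elif current:
            clusters.append((current, sum(values[j] for j in current)))
            current = []
    if current:
        clusters.append((current, sum(values[j] for j in current)))
    return clusters


def fake_result(rng, n_units=60, n_times=40, accuracy_boost=None, n_classes=2):
    """DecodingResult with random records; optional boosted window."""
    true = rng.integers(0, n_classes, size=n_units)
    pred = rng.integers(0, n_classes, size=(n_times, n_units))
    if accuracy_boost is not None:
        lo, hi, p = accuracy_boost
        for t in range(lo, hi):
            flip = rng.random(n_units) < p
            pred[t, flip] = true[flip]
    times = np.arange(n_times) * 20.0
    acc = (pred == true[None, :]).mean(axis=1)
    return DecodingResult(
        times=times, accuracy=acc, true=true, pred=pred,
        unit_iteration=np.zeros(n_units, int), classes=np.arange(n_classes),
        mode="condition", chance=1.0 / n_classes,
    )


class TestFormClusters:
    def test_worked_example(self):
        clusters = form_clusters(np.array([1.0, 2.5, 2.6, 0.3]), 2.02, "1d")
        assert len(clusters) == 1
        idx, mass = clusters[0]
        assert idx.tolist() == [1, 2]
        assert mass == pytest.approx(5.1)

    def test_all_below_threshold(self):
        assert form_clusters(np.array([0.1, -3.0, 1.9]), 2.0, "1d") == []

    def test_two_disjoint_blobs_on_grid(self):
        grid = np.zeros((8, 10))
        grid[1:3, 1:4] = 3.0
        grid[5:7, 6:9] = 4.0
        clusters = form_clusters(grid, 2.0, "grid")
        masses = sorted(m for _, m in clusters)
        assert masses == [pytest.approx(6 * 3.0), pytest.approx(6 * 4.0)]

    def test_channel_graph_components(self):
        # path graph 0-1-2-3-4 with a break at node 2
        adj = np.zeros((5, 5), bool)
        for i in range(4):
            adj[i, i + 1] = adj[i + 1, i] = True
        stat = np.array([3.0, 3.0, 0.0, 3.0, 3.0])
        clusters = form_clusters(stat, 2.0, adj)
        members = sorted(tuple(sorted(c[0])) for c in clusters)
        assert members == [(0, 1), (3, 4)]

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            vals = rng.normal(size=rng.integers(5, 60))
            thr = rng.uniform(-1, 2)
            ours = form_clusters(vals, thr, "1d")
            oracle = brute_force_1d_clusters(vals, thr)
            assert len(ours) == len(oracle)
            for (idx, mass), (oidx, omass) in zip(ours, oracle):
                assert idx.tolist() == oidx
                assert mass == pytest.approx(omass)

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            form_clusters(np.zeros(3), np.nan, "1d")


class TestTStatistics:
    def test_vectorized_t_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 7))
        assert np.allclose(one_sample_t(x, 0.3),
                           stats.ttest_1samp(x, 0.3).statistic)
        a, b = rng.normal(size=(10, 5)), rng.normal(size=(8, 5))
        assert np.allclose(independent_t(a, b),
                           stats.ttest_ind(a, b).statistic)

    def test_rho_to_t_closed_form(self):
        assert rho_to_t(np.array([0.0]), 40)[0] == 0.0
        t = rho_to_t(np.array([0.31]), 40)[0]
        assert t == pytest.approx(0.31 * np.sqrt(38 / (1 - 0.31**2)), abs=1e-12)
        assert t == pytest.approx(2.01, abs=0.01)
        with pytest.warns(UserWarning, match="capped"):
            capped = rho_to_t(np.array([1.0]), 10)
        assert np.isfinite(capped).all()


class TestVsChance:
    def test_planted_effect_detected_in_planted_window(self):
        rng = np.random.default_rng(2)
        results = [fake_result(rng, accuracy_boost=(10, 25, 0.4)) for _ in range(10)]
        res = perm_test_vs_chance(results, chance=0.5, n_perm=200,
                                  window=(0.0, 800.0), seed=0)
        sig = res.significant()
        assert sig, "planted effect must produce a significant cluster"
        members = np.concatenate([c.indices for c in sig])
        assert set(members) & set(range(10, 25))

    def test_null_length_matches_permutation_count(self):
        rng = np.random.default_rng(3)
        results = [fake_result(rng) for _ in range(6)]
        res = perm_test_vs_chance(results, n_perm=150, window=(0.0, 800.0), seed=0)
        assert len(res.null_pos) == 150
        assert res.n_permutations == 150

    def test_p_monotone_in_mass(self):
        rng = np.random.default_rng(4)
        results = [fake_result(rng, accuracy_boost=(5, 12, 0.3)) for _ in range(8)]
        results += [fake_result(rng, accuracy_boost=(25, 38, 0.6)) for _ in range(0)]
        res = perm_test_vs_chance(results, chance=0.5, n_perm=200,
                                  window=(0.0, 800.0), seed=1)
        ordered = sorted(res.clusters, key=lambda c: -abs(c.mass))
        ps = [c.p for c in ordered]
        assert ps == sorted(ps)

    def test_missing_records_rejected(self):
        rng = np.random.default_rng(5)
        r = fake_result(rng)
        r.pred = None
        with pytest.raises(ValueError, match="records"):
            perm_test_vs_chance([r, r], n_perm=10)


class TestConditionDiff:
    def test_identical_inputs_no_significant_clusters(self):
        rng = np.random.default_rng(6)
        results = [fake_result(rng) for _ in range(8)]
        res = perm_test_condition_diff(results, results, n_perm=100,
                                       window=(0.0, 800.0), seed=0)
        assert not res.any_significant()

    def test_two_tailed_critical_values_and_signs(self):
        rng = np.random.default_rng(7)
        a = [fake_result(rng, accuracy_boost=(8, 20, 0.5)) for _ in range(9)]
        b = [fake_result(rng) for _ in range(9)]
        res = perm_test_condition_diff(a, b, n_perm=200, window=(0.0, 800.0), seed=0)
        assert res.tails == 2
        assert res.null_neg is not None
        sig = res.significant()
        assert any(c.sign == +1 for c in sig)

    def test_unpaired_inputs_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="paired"):
            perm_test_condition_diff([fake_result(rng)], [], n_perm=10)


class TestGroupDiff:
    def test_identical_participants_give_no_clusters(self):
        rng = np.random.default_rng(9)
        one = fake_result(rng)
        results = [one] * 10
        res = perm_test_group_diff(results, [0] * 5 + [1] * 5, n_perm=100,
                                   window=(0.0, 800.0), seed=0)
        assert res.clusters == []

    def test_group_sizes_preserved_and_detection(self):
        rng = np.random.default_rng(10)
        hi = [fake_result(rng, accuracy_boost=(5, 30, 0.5)) for _ in range(10)]
        lo = [fake_result(rng) for _ in range(10)]
        res = perm_test_group_diff(hi + lo, [1] * 10 + [0] * 10, n_perm=200,
                                   window=(0.0, 800.0), seed=0)
        assert res.any_significant()

    def test_small_group_rejected(self):
        rng = np.random.default_rng(11)
        results = [fake_result(rng) for _ in range(4)]
        with pytest.raises(ValueError, match="at least 2"):
            perm_test_group_diff(results, [0, 1, 1, 1], n_perm=10)


class TestCorrCluster:
    def test_coupled_window_detected(self):
        rng = np.random.default_rng(12)
        n, t = 24, 50
        y = rng.normal(size=n)
        x = rng.normal(size=(n, t))
        x[:, 15:30] += 1.5 * y[:, None]
        res = corr_cluster_timecourse(x, y, n_perm=200, seed=0)
        sig = res.significant()
        assert sig
        members = np.concatenate([c.indices for c in sig])
        assert set(members) <= set(range(10, 35))

    def test_too_few_participants(self):
        with pytest.raises(ValueError, match="at least 4"):
            corr_cluster_timecourse(np.zeros((3, 5)), np.zeros(3), n_perm=10)


class TestPairedMaps:
    def test_planted_channel_cluster_found(self):
        rng = np.random.default_rng(13)
        n_sub, n_ch = 12, 20
        adj = np.zeros((n_ch, n_ch), bool)
        for i in range(n_ch - 1):
            adj[i, i + 1] = adj[i + 1, i] = True
        diffs = rng.normal(scale=0.05, size=(n_sub, n_ch))
        diffs[:, 5:9] += 0.15
        res = perm_test_paired_maps(diffs, adj, n_perm=300, seed=0)
        sig = res.significant()
        assert sig
        members = set(np.concatenate([c.indices for c in sig]))
        assert members & {5, 6, 7, 8}

    def test_zero_differences_give_no_clusters(self):
        adj = np.ones((4, 4), bool) ^ np.eye(4, dtype=bool)
        rng = np.random.default_rng(14)
        diffs = rng.normal(scale=1e-3, size=(8, 4))
        res = perm_test_paired_maps(diffs - diffs.mean(0), adj, n_perm=100, seed=0)
        assert not res.any_significant()


class TestNullCalibrationSmall:
    def test_corrected_p_roughly_uniform_under_null(self):
        """Smallest-p distribution across null replicates is not anti-
        conservative: familywise rate compatible with alpha."""
        rng = np.random.default_rng(15)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            x = rng.normal(size=(12, 30))
            y = rng.normal(size=12)
            res = corr_cluster_timecourse(x, y, n_perm=100, seed=rng)
            if res.any_significant():
                hits += 1
        rate = hits / n_rep
        assert rate < 0.15  # binomial upper band around 0.05 for 60 reps
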