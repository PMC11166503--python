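"""Feature reduction, sub-ERP binning, cross-validated decoding."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import tntdecode as td
from tntdecode.decoding import (
    DecodeSpec,
    FeatureEpochs,
    bin_average,
    condition_spec,
    decode_resampled_items,
    decode_timecourse,
    estimate_chance,
    item_spec,
    pairwise_item_decode,
    pca_reduce,
    timepoint_centers,
)

from conftest import toy_epochs


def make_features(data, labels, sfreq=250.0, t0=0.0):
    """Feature container straight from an array (no PCA)."""
    n, d, nt = data.shape
    times = t0 + np.arange(nt) * 1000.0 / sfreq
    table = pd.DataFrame(
        {"condition": ["Think"] * n, "item_id": labels, "participant_id": 0}
    )
    return FeatureEpochs(
        data=data, times=times, sfreq=sfreq, trial_table=table,
        explained_variance_ratio=np.array([]),
    )


class TestPcaReduce:
    def test_variances_non_increasing_and_white_noise_capture(self, montage):
        rng = np.random.default_rng(0)
        epochs = toy_epochs(rng.normal(size=(40, 61, 200)), montage)
        feats = pca_reduce(epochs, 15)
        evr = feats.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        # white noise: top 15 of 61 components carry ~15/61 of the variance
        assert evr.sum() == pytest.approx(15 / 61, abs=0.05)

    def test_rank_deficient_input_names_achievable_rank(self, montage):
        rng = np.random.default_rng(1)
        mixing = rng.normal(size=(61, 3))
        sources = rng.normal(size=(10, 3, 100))
        epochs = toy_epochs(np.einsum("cs,tsn->tcn", mixing, sources), montage)
        with pytest.raises(ValueError, match="rank 3"):
            pca_reduce(epochs, 15)

    def test_full_rank_reconstruction_exact(self, montage):
        rng = np.random.default_rng(2)
        mixing = rng.normal(size=(61, 3))
        sources = rng.normal(size=(10, 3, 50))
        data = np.einsum("cs,tsn->tcn", mixing, sources)
        feats = pca_reduce(toy_epochs(data, montage), 3)
        x = data.transpose(0, 2, 1).reshape(-1, 61)
        recon = feats.pca.inverse_transform(
            feats.data.transpose(0, 2, 1).reshape(-1, 3)
        )
        assert np.allclose(recon, x, atol=1e-8)


class TestBinAverage:
    def test_56_trials_into_10_bins(self):
        x = np.random.default_rng(0).normal(size=(56, 4))
        _, groups = bin_average(x, 10, np.random.default_rng(1))
        sizes = sorted(len(g) for g in groups)
        assert sizes == [5, 5, 5, 5, 6, 6, 6, 6, 6, 6]

    def test_30_trials_into_3_equal_bins(self):
        x = np.zeros((30, 2))
        _, groups = bin_average(x, 3, np.random.default_rng(0))
        assert [len(g) for g in groups] == [10, 10, 10]

    def test_identical_trials_give_identical_sub_erps(self):
        x = np.tile(np.array([1.0, -2.0, 3.0]), (12, 1))
        subs, _ = bin_average(x, 3, np.random.default_rng(0))
        assert np.allclose(subs, x[0])

    def test_partition_is_a_partition(self):
        x = np.zeros((17, 1))
        _, groups = bin_average(x, 5, np.random.default_rng(3))
        all_idx = np.sort(np.concatenate(groups))
        assert np.array_equal(all_idx, np.arange(17))

    def test_too_few_trials_errors(self):
        with pytest.raises(ValueError, match="cannot split"):
            bin_average(np.zeros((2, 1)), 3, np.random.default_rng(0))


class TestTimepointGrid:
    def test_20ms_grid_from_epoch_start(self):
        times = np.arange(-1000.0, 3500.0, 4.0)
        centers = timepoint_centers(times, 20.0)
        assert centers[0] == -1000.0
        assert np.allclose(np.diff(centers), 20.0)

    def test_window_restriction_half_open(self):
        times = np.arange(-1000.0, 3500.0, 4.0)
        centers = timepoint_centers(times, 20.0, window=(-500.0, 0.0))
        assert centers[0] == -500.0 and centers[-1] == -20.0


class TestDecodeTimecourse:
    def test_null_binary_near_half_and_null_12_class_near_chance(self):
        rng = np.random.default_rng(4)
        accs2, accs12 = [], []
        for rep in range(3):
            data = rng.normal(size=(40, 8, 30))
            feats = make_features(data, labels=np.repeat([0, 1], 20))
            spec = DecodeSpec(mode="condition", n_bins=10, n_folds=10,
                              n_iterations=4, step_ms=40.0)
            accs2.append(
                decode_timecourse(feats, spec, labels=np.repeat([0, 1], 20),
                                  seed=rep).accuracy
            )
            data12 = rng.normal(size=(48, 8, 30))
            feats12 = make_features(data12, labels=np.repeat(np.arange(12), 4))
            spec12 = DecodeSpec(mode="item", n_bins=2, n_folds=2,
                                n_iterations=4, step_ms=40.0)
            accs12.append(decode_timecourse(feats12, spec12, seed=rep).accuracy)
        assert np.mean(accs2) == pytest.approx(0.5, abs=0.06)
        assert np.mean(accs12) == pytest.approx(1 / 12, abs=0.04)

    def test_separable_pattern_only_at_planted_timepoint(self):
        rng = np.random.default_rng(5)
        data = rng.normal(scale=0.5, size=(30, 6, 25))
        t_star = slice(10, 13)  # 400-520 ms at 40 ms grid... planted samples
        labels = np.repeat([0, 1], 15)
        pattern = 5.0 * np.array([1, -1, 2, 0.5, -2, 1])
        data[np.ix_(np.flatnonzero(labels == 1), np.arange(6),
                    np.arange(10, 13))] += pattern[None, :, None]
        feats = make_features(data, labels, sfreq=50.0)  # 20 ms samples
        spec = DecodeSpec(mode="condition", n_bins=5, n_folds=5,
                          n_iterations=4, step_ms=20.0, smooth_halfwidth_ms=10.0)
        res = decode_timecourse(feats, spec, labels=labels, seed=0)
        planted = res.accuracy[10:13]
        clean = np.r_[res.accuracy[:8], res.accuracy[15:]]
        assert planted.mean() > 0.95
        assert abs(clean.mean() - 0.5) < 0.1

    def test_records_reaggregate_exactly_and_confusion_rows_sum(self):
        rng = np.random.default_rng(6)
        feats = make_features(rng.normal(size=(24, 5, 10)),
                              labels=np.repeat(np.arange(6), 4))
        spec = item_spec(n_iterations=2, step_ms=40.0)
        res = decode_timecourse(feats, spec, seed=0)
        assert np.array_equal(res.recompute_accuracy(), res.accuracy)
        conf = res.confusion()
        per_class_units = res.n_units // 6
        assert np.all(conf.sum(axis=1) == per_class_units)

    def test_leakage_probe_keeps_null_at_chance(self):
        """Adding a huge constant to test folds only must not help on null
        data - proof that normalization uses training statistics alone."""
        rng = np.random.default_rng(7)
        accs = []
        for rep in range(3):
            feats = make_features(rng.normal(size=(40, 6, 20)),
                                  labels=np.repeat([0, 1], 20))
            spec = condition_spec(n_iterations=3, step_ms=40.0)
            res = decode_timecourse(feats, spec, labels=np.repeat([0, 1], 20),
                                    seed=rep, leakage_probe_offset=1e4)
            accs.append(res.accuracy.mean())
        assert np.mean(accs) == pytest.approx(0.5, abs=0.08)

    def test_iteration_count_stability(self):
        """Averaging over many iterations agrees with few iterations."""
        rng = np.random.default_rng(8)
        data = rng.normal(size=(36, 6, 12))
        data[18:, :, 5:8] += 1.0 * rng.normal(size=(6, 1))[None, :, :]
        feats = make_features(data, labels=np.repeat([0, 1], 18))
        spec_few = condition_spec(n_bins=6, n_folds=6, n_iterations=10, step_ms=40.0)
        spec_many = condition_spec(n_bins=6, n_folds=6, n_iterations=100, step_ms=40.0)
        labels = np.repeat([0, 1], 18)
        few = decode_timecourse(feats, spec_few, labels=labels, seed=0).accuracy
        many = decode_timecourse(feats, spec_many, labels=labels, seed=1).accuracy
        assert np.abs(few - many).mean() < 0.06

    def test_invariance_to_channel_relabeling(self, montage):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(24, 61, 12))
        data[12:, :10, 4:8] += 1.5
        labels = np.repeat([0, 1], 12)
        epochs = toy_epochs(data, montage, items=labels)
        perm = rng.permutation(61)
        shuffled = toy_epochs(data[:, perm, :], montage, items=labels)
        spec = condition_spec(n_bins=4, n_folds=4, n_iterations=3, step_ms=40.0)
        acc_a = decode_timecourse(pca_reduce(epochs, 10), spec,
                                  labels=labels, seed=0).accuracy
        acc_b = decode_timecourse(pca_reduce(shuffled, 10), spec,
                                  labels=labels, seed=0).accuracy
        assert np.abs(acc_a - acc_b).mean() < 0.05

    def test_class_with_too_few_trials_errors(self):
        feats = make_features(np.zeros((12, 3, 5)), labels=[0] * 10 + [1, 1])
        with pytest.raises(ValueError, match="fewer than n_bins"):
            decode_timecourse(feats, condition_spec(),
                              labels=np.array([0] * 10 + [1, 1]), seed=0)


class TestEstimateChance:
    def test_binary_chance_near_50(self):
        rng = np.random.default_rng(10)
        feats = make_features(rng.normal(size=(40, 8, 160)),
                              labels=np.repeat([0, 1], 20), t0=-600.0)
        spec = condition_spec(n_iterations=4)
        chance = estimate_chance(feats, spec, labels=np.repeat([0, 1], 20),
                                 baseline_window=(-500.0, 0.0), seed=0)
        assert chance == pytest.approx(0.5, abs=0.07)

    def test_empty_baseline_errors(self):
        feats = make_features(np.zeros((8, 3, 10)), labels=[0, 1] * 4, t0=0.0)
        with pytest.raises(ValueError, match="baseline"):
            estimate_chance(feats, condition_spec(), labels=np.array([0, 1] * 4),
                            baseline_window=(-500.0, 0.0))


class TestResampledItems:
    def test_degenerate_subset_equals_plain_item_decoding_chance(self):
        rng = np.random.default_rng(11)
        feats = make_features(rng.normal(size=(48, 6, 10)),
                              labels=np.repeat(np.arange(12), 4))
        spec = item_spec(n_iterations=2, step_ms=40.0)
        res = decode_resampled_items(feats, spec, subset_size=12,
                                     n_iterations=2, seed=0)
        assert res.chance == pytest.approx(1 / 12)
        assert res.accuracy.mean() == pytest.approx(1 / 12, abs=0.06)

    def test_null_6_of_12_items_near_one_sixth(self):
        rng = np.random.default_rng(12)
        feats = make_features(rng.normal(size=(48, 6, 10)),
                              labels=np.repeat(np.arange(12), 4))
        res = decode_resampled_items(
            feats, item_spec(n_iterations=2, step_ms=40.0),
            subset_size=6, n_iterations=6, seed=0,
        )
        assert res.chance == pytest.approx(1 / 6)
        assert res.accuracy.mean() == pytest.approx(1 / 6, abs=0.07)

    def test_subset_larger_than_item_count_errors(self):
        feats = make_features(np.zeros((12, 3, 5)), labels=np.repeat(np.arange(4), 3))
        with pytest.raises(ValueError, match="exceeds"):
            decode_resampled_items(feats, subset_size=6, seed=0)


class TestTimeFrequencyDecoding:
    def test_band_signal_confined_to_band_and_theta_summary_definition(self):
        """An item difference carried by a 10 Hz envelope appears in alpha
        bins, not theta bins."""
        rng = np.random.default_rng(13)
        sfreq = 100.0
        times = np.arange(0, 3000.0, 1000.0 / sfreq)
        n = len(times)
        data = rng.normal(scale=1.0, size=(24, 4, n))
        labels = np.repeat([0, 1], 12)
        carrier = np.sin(2 * np.pi * 10.0 * times / 1000.0)
        data[labels == 1] += 2.0 * carrier  # all 4 features
        feats = make_features(data, labels, sfreq=sfreq)
        spec = DecodeSpec(mode="item", n_bins=4, n_folds=4, n_iterations=2,
                          step_ms=100.0)
        freqs = np.array([4.0, 6.0, 10.0, 20.0])
        tf = td.decode_timefrequency(feats, spec, freqs=freqs, seed=0)
        assert tf.accuracy.shape[0] == 4
        mid = (tf.times >= 500) & (tf.times < 2500)  # avoid wavelet edges
        alpha_acc = tf.accuracy[2][mid].mean()
        theta_acc = tf.accuracy[:2][:, mid].mean()
        assert alpha_acc > 0.9
        assert theta_acc < alpha_acc - 0.2
        assert np.allclose(tf.band_summary((3.0, 7.0)), tf.accuracy[:2].mean(axis=0))


class TestPairwiseItemDecode:
    def test_null_rdm_structure(self):
        rng = np.random.default_rng(14)
        feats = make_features(rng.normal(size=(24, 4, 8)),
                              labels=np.repeat(np.arange(6), 4))
        series = pairwise_item_decode(feats, item_spec(n_iterations=2, step_ms=40.0),
                                      seed=0)
        t0 = series.rdm[0]
        assert np.allclose(t0, t0.T, equal_nan=True)
        assert np.all(np.isnan(np.diag(t0)))
        iu = np.triu_indices(6, k=1)
        assert len(t0[iu]) == 15
        assert np.nanmean(series.rdm) == pytest.approx(0.5, abs=0.08)

    def test_identical_items_less_separable_than_distinct(self):
        rng = np.random.default_rng(15)
        data = rng.normal(scale=0.5, size=(40, 5, 40))
        labels = np.repeat(np.arange(4), 10)
        patterns = {1: np.array([3, 0, -3, 1, 2.0]), 2: np.array([-2, 3, 1, -3, 0.0]),
                    3: np.array([-2, 3, 1, -3, 0.0])}  # items 2 and 3 identical
        for item, pat in patterns.items():
            data[labels == item] += pat[None, :, None]
        feats = make_features(data, labels)
        series = pairwise_item_decode(feats, item_spec(n_iterations=4, step_ms=40.0),
                                      seed=0)
        mean_rdm = np.nanmean(series.rdm, axis=0)
        twin = mean_rdm[2, 3]
        others = [mean_rdm[i, j] for i, j in [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]]
        assert twin == pytest.approx(0.5, abs=0.15)
        assert min(others) > twin + 0.2
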