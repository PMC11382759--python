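"""Noise models, bootstrap significance, peaks, Q scores and gated tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal, stats

from speechffr import inference as inf
from speechffr import synthdata as sd
from speechffr import trf
from speechffr.features import StimulusFeatures
from speechffr.neuralprep import NeuralRecording

LAGS = trf.LagAxis().lags_ms()


def _narrowband_features(n=6000, seed=0, fs=1000.0):
    rng = np.random.default_rng(seed)
    sos = signal.butter(2, [70, 120], btype="bandpass", fs=fs, output="sos")
    f = signal.sosfiltfilt(sos, rng.standard_normal(n)) * 0.003
    e = signal.sosfiltfilt(sos, rng.standard_normal(n)) * 0.003
    return StimulusFeatures(f, e, fs)


class TestNoiseModels:
    def test_double_reversal_restores_features(self):
        feats = _narrowband_features(500)
        twice = feats.reversed().reversed()
        assert np.array_equal(twice.fundamental, feats.fundamental)
        assert np.array_equal(twice.envelope_mod, feats.envelope_mod)

    def test_noise_sets_are_distinct_and_deterministic(self):
        feats = _narrowband_features(1000)
        sets_a = inf.noise_feature_sets(feats, 4)
        sets_b = inf.noise_feature_sets(feats, 4)
        assert len(sets_a) == 4
        for a, b in zip(sets_a, sets_b):
            assert np.array_equal(a.fundamental, b.fundamental)
        assert not np.array_equal(sets_a[0].fundamental, sets_a[1].fundamental)

    def test_noise_trf_much_weaker_than_genuine_on_clean_data(self):
        feats = _narrowband_features(20000, seed=2)
        truth = sd.make_ground_truth(noise_sd=0.0, seed=2)
        rec = sd.gen_neural_response(feats, truth, attended=True)
        analyzer = inf.TRFAnalyzer(feats, n_reversals=5)
        genuine_env = trf.model_envelopes(analyzer.genuine(rec))["fundamental"]
        noise_env = inf.noise_envelopes(analyzer.noise(rec))["fundamental"]
        assert noise_env.max() / genuine_env.max() < 0.2

    def test_zero_reversals_rejected(self):
        with pytest.raises(ValueError):
            inf.noise_feature_sets(_narrowband_features(100), 0)


class TestBootstrapSignificance:
    def test_observation_above_all_null_draws_hits_p_floor(self):
        noise = np.full((5, 10), 1.0)
        obs = np.full(10, 2.0)
        sig = inf.bootstrap_significance(obs, noise, n_permutations=999, seed=0)
        assert np.allclose(sig.p_per_lag, 1.0 / 1000.0)

    def test_observation_at_null_median_has_p_about_half(self):
        rng = np.random.default_rng(1)
        noise = rng.standard_normal((200, 1))
        obs = np.array([np.median(noise)])
        sig = inf.bootstrap_significance(obs, noise, n_permutations=5000, seed=1)
        assert sig.p_per_lag[0] == pytest.approx(0.5, abs=0.05)

    def test_p_values_in_unit_interval_and_bonferroni_monotone(self):
        rng = np.random.default_rng(2)
        noise = rng.standard_normal((10, 141)) ** 2
        obs = rng.standard_normal(141) ** 2
        sig = inf.bootstrap_significance(obs, noise, n_permutations=500, seed=2)
        assert np.all(sig.p_per_lag > 0)
        assert np.all(sig.p_per_lag <= 1)
        assert np.all(sig.p_corrected >= sig.p_per_lag)
        assert np.all(sig.significant_mask == (sig.p_corrected < 0.05))

    def test_empty_noise_set_rejected(self):
        with pytest.raises(ValueError):
            inf.bootstrap_significance(np.ones(5), np.empty((0, 5)), 100)

    def test_familywise_rate_controlled_under_global_null(self):
        # each repeat draws both the "genuine" and the noise envelopes from
        # the same null process; after Bonferroni the family-wise flag rate
        # must stay at or below alpha
        rng = np.random.default_rng(3)
        flags = 0
        repeats = 200
        for r in range(repeats):
            noise = rng.standard_normal((10, 141)) ** 2
            obs = rng.standard_normal(141) ** 2
            sig = inf.bootstrap_significance(obs, noise, n_permutations=1000,
                                             seed=r)
            flags += sig.any_significant
        assert flags / repeats <= 0.05


class TestFindPeak:
    def _sig(self, mask):
        mask = np.asarray(mask, dtype=bool)
        return inf.SignificanceProfile(
            p_per_lag=np.where(mask, 0.001, 0.5),
            p_corrected=np.where(mask, 0.01, 1.0),
            significant_mask=mask, n_permutations=100, alpha=0.05,
            noise_quantiles={})

    def test_unimodal_envelope_peak_found(self):
        env = np.exp(-0.5 * ((LAGS - 35.0) / 8.0) ** 2)
        peak = inf.find_peak(env, self._sig(np.ones(141)), LAGS)
        assert peak.latency_ms == 35.0
        assert peak.is_significant

    def test_empty_mask_reports_no_peak(self):
        env = np.ones(141)
        peak = inf.find_peak(env, self._sig(np.zeros(141)), LAGS)
        assert not peak.is_significant
        assert np.isnan(peak.latency_ms)

    def test_exact_tie_resolved_to_earliest_lag(self):
        env = np.zeros(141)
        env[LAGS == 30.0] = 1.0
        env[LAGS == 40.0] = 1.0
        peak = inf.find_peak(env, self._sig(np.ones(141)), LAGS)
        assert peak.latency_ms == 30.0

    def test_mask_restricts_the_search(self):
        env = np.exp(-0.5 * ((LAGS - 35.0) / 8.0) ** 2)
        mask = LAGS >= 60.0
        peak = inf.find_peak(env, self._sig(mask), LAGS)
        assert peak.latency_ms == 60.0


class TestIqrExclude:
    def test_tight_sample_keeps_everything(self):
        kept, excluded, _ = inf.iqr_exclude([10, 11, 12, 13, 14])
        assert excluded.size == 0
        assert kept.size == 5

    def test_hand_computed_fences_exclude_the_outlier(self):
        # values [10,11,12,13,100]: Q1=11, Q3=13, IQR=2 -> fences [8, 16]
        v = np.array([10.0, 11.0, 12.0, 13.0, 100.0])
        q1, q3 = np.percentile(v, [25, 75])
        assert (q1, q3) == (11.0, 13.0)
        kept, excluded, mask = inf.iqr_exclude(v)
        assert list(excluded) == [100.0]
        assert list(kept) == [10.0, 11.0, 12.0, 13.0]

    def test_degenerate_zero_iqr_keeps_common_value(self):
        kept, excluded, _ = inf.iqr_exclude([5.0, 5.0, 5.0, 5.0, 5.0])
        assert excluded.size == 0

    def test_fewer_than_four_values_warns_and_keeps_all(self):
        with pytest.warns(UserWarning):
            kept, excluded, _ = inf.iqr_exclude([1.0, 100.0])
        assert kept.size == 2 and excluded.size == 0


class TestAttentionScore:
    def test_equal_conditions_give_zero(self):
        assert inf.attention_score(2.0, 2.0).Q == 0.0

    def test_fully_suppressed_ignored_condition_gives_one(self):
        assert inf.attention_score(1.5, 0.0).Q == 1.0

    def test_direct_arithmetic(self):
        assert inf.attention_score(3.0, 1.0).Q == pytest.approx(0.5)

    def test_zero_sum_reported_missing(self):
        assert np.isnan(inf.attention_score(0.0, 0.0).Q)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            inf.attention_score(-1.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(0.0, 100.0), i=st.floats(0.0, 100.0))
    def test_swap_antisymmetry_and_bounds(self, a, i):
        if a + i == 0:
            return
        q = inf.attention_score(a, i).Q
        assert -1.0 <= q <= 1.0
        assert q == pytest.approx(-inf.attention_score(i, a).Q, abs=1e-12)


class TestGatedComparisons:
    def test_normal_samples_take_the_t_branch(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(30), rng.standard_normal(30) + 0.2
        # oracle: the gate must agree with reference Shapiro-Wilk decisions
        assert stats.shapiro(x).pvalue >= 0.05
        assert stats.shapiro(y).pvalue >= 0.05
        report = inf.compare_conditions(x, y)
        assert report["branch"] == "parametric"
        stat_ref, p_ref = stats.ttest_ind(x, y)
        assert report["statistic"] == pytest.approx(stat_ref, abs=1e-12)
        assert report["p"] == pytest.approx(p_ref, abs=1e-12)

    def test_skewed_sample_takes_the_mann_whitney_branch(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(40)
        y = np.exp(rng.standard_normal(40) * 2)  # heavily skewed
        assert stats.shapiro(y).pvalue < 0.05
        report = inf.compare_conditions(x, y)
        assert report["branch"] == "nonparametric"
        stat_ref, p_ref = stats.mannwhitneyu(x, y, alternative="two-sided")
        assert report["statistic"] == pytest.approx(stat_ref, abs=1e-12)
        assert report["p"] == pytest.approx(p_ref, abs=1e-12)

    def test_identical_samples_not_significant(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(25)
        report = inf.compare_conditions(x, x.copy())
        assert report["p"] > 0.9

    def test_paired_branch_uses_paired_tests(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(20)
        y = x + rng.normal(0.5, 0.1, 20)
        report = inf.compare_conditions(x, y, paired=True)
        assert "paired" in report["test"] or report["test"] == "Wilcoxon signed-rank"
        assert report["p"] < 0.01

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            inf.compare_conditions([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCompareVariances:
    def test_matches_median_centred_levene(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(40), 3 * rng.standard_normal(40)
        report = inf.compare_variances(x, y)
        stat_ref, p_ref = stats.levene(x, y, center="median")
        assert report["statistic"] == pytest.approx(stat_ref, abs=1e-12)
        assert report["p"] == pytest.approx(p_ref, abs=1e-12)

    def test_group_against_itself_has_zero_statistic(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        report = inf.compare_variances(x, x.copy())
        assert report["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_strongly_different_variances_detected(self):
        rng = np.random.default_rng(5)
        rejections = 0
        for r in range(20):
            x = rng.standard_normal(50)
            y = 5 * rng.standard_normal(50)
            if inf.compare_variances(x, y)["p"] < 0.01:
                rejections += 1
        assert rejections >= 19

    def test_rejection_rate_calibrated_under_null(self):
        rng = np.random.default_rng(6)
        rejections = sum(
            inf.compare_variances(rng.standard_normal(30),
                                  rng.standard_normal(30))["p"] < 0.05
            for _ in range(200))
        assert 0.01 <= rejections / 200 <= 0.10
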