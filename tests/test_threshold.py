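import numpy as np
import pytest

from mrsmeta.datasets import Metabolite, Region, RegionalCollection
from mrsmeta.quality import QualityMetric, QualityProfile, compute_profiles
from mrsmeta.simulate import SigmoidAttenuation, SyntheticCorpusConfig, generate_corpus
from mrsmeta.threshold import (
    InsufficientData,
    ThresholdScan,
    Window,
    compare_quality_subgroups,
    derive_threshold,
    fit_4pl_series,
    fit_logistic,
    moving_windows,
    quality_threshold_scan,
    rank_by_quality,
    window_size,
)
from mrsmeta.meta import pool_random_effects
from mrsmeta.effects import hedges_g
from conftest import make_dataset


def logistic(x, a, d, b, c):
    return d + (a - d) / (1 + np.exp(b * (x - c)))


def make_ranked(k, seed=0, **cfg):
    corpus = generate_corpus(SyntheticCorpusConfig(k=k, seed=seed, **cfg))
    profiles = compute_profiles(corpus, QualityMetric.COV)
    return rank_by_quality(corpus, profiles)


class TestWindowMechanics:
    @pytest.mark.parametrize("k,expected", [(48, 10), (7, 7), (23, 7), (35, 7), (36, 8), (100, 20)])
    def test_window_size_rule(self, k, expected):
        assert window_size(k) == expected

    @pytest.mark.parametrize("k,n_windows", [(48, 39), (7, 1), (23, 17)])
    def test_window_count(self, k, n_windows):
        ranked, profiles, _ = make_ranked(k)
        scan = moving_windows(ranked, profiles)
        assert scan.k_prime == window_size(k)
        assert scan.n_windows == n_windows
        # windows step by exactly one rank
        for i, w in enumerate(scan.windows, start=1):
            assert w.index == i
            assert w.study_ids == tuple(d.study_id for d in ranked[i - 1 : i - 1 + scan.k_prime])

    def test_too_few_datasets(self):
        ranked, profiles, _ = make_ranked(8)
        with pytest.raises(InsufficientData):
            moving_windows(ranked[:6], profiles[:6])

    def test_window_pool_matches_independent_pooling(self):
        ranked, profiles, _ = make_ranked(23, seed=4)
        scan = moving_windows(ranked, profiles)
        w = scan.windows[5]
        members = ranked[5 : 5 + scan.k_prime]
        independent = pool_random_effects([hedges_g(d) for d in members])
        assert w.pooled_g == pytest.approx(independent.pooled_g, abs=1e-12)


class TestRanking:
    def _profiles(self, metric, values):
        return [QualityProfile(f"s{i:02d}", metric, v) for i, v in enumerate(values)]

    def test_cov_worst_first(self):
        ds = [make_dataset(f"s{i:02d}") for i in range(3)]
        profiles = self._profiles(QualityMetric.COV, [12.0, 25.0, 19.0])
        ranked, rp, _ = rank_by_quality(ds, profiles)
        assert [p.value for p in rp] == [25.0, 19.0, 12.0]

    def test_snr_lowest_first(self):
        ds = [make_dataset(f"s{i:02d}") for i in range(3)]
        profiles = self._profiles(QualityMetric.SNR, [18.0, 10.0, 14.0])
        ranked, rp, _ = rank_by_quality(ds, profiles)
        assert [p.value for p in rp] == [10.0, 14.0, 18.0]

    def test_direction_flip_reverses_order(self):
        ds = [make_dataset(f"s{i:02d}") for i in range(5)]
        values = [3.0, 9.0, 5.0, 7.0, 1.0]
        _, low_rp, _ = rank_by_quality(ds, self._profiles(QualityMetric.FWHM, values))
        _, high_rp, _ = rank_by_quality(ds, self._profiles(QualityMetric.SNR, values))
        assert [p.value for p in low_rp] == [p.value for p in high_rp][::-1]

    def test_tie_breaks_on_study_id(self):
        ds = [make_dataset(s) for s in ("zz", "aa", "mm")]
        profiles = [QualityProfile(s, QualityMetric.COV, 20.0) for s in ("zz", "aa", "mm")]
        ranked, _, _ = rank_by_quality(ds, profiles)
        assert [d.study_id for d in ranked] == ["aa", "mm", "zz"]

    def test_missing_profile_excluded_with_log(self):
        ds = [make_dataset(f"s{i:02d}") for i in range(3)]
        profiles = self._profiles(QualityMetric.COV, [12.0, 25.0, None])
        ranked, _, excluded = rank_by_quality(ds, profiles)
        assert len(ranked) == 2
        assert excluded[0].study_id == "s02"


class TestLogisticFit:
    def test_noiseless_recovery(self):
        x = np.arange(1, 40, dtype=float)
        # generating curve starts at 0.35 and falls to -0.05 across x
        y = logistic(x, -0.05, 0.35, -0.8, 22.0)
        fit = fit_4pl_series(y)
        # canonical labeling: a is the left asymptote, b >= 0
        assert fit.a == pytest.approx(0.35, abs=1e-4)
        assert fit.d == pytest.approx(-0.05, abs=1e-4)
        assert fit.b == pytest.approx(0.8, abs=1e-3)
        assert fit.c == pytest.approx(22.0, abs=1e-3)
        assert fit.r2 > 1 - 1e-8
        assert fit.p_value < 1e-12

    def test_constant_series_not_significant(self):
        fit = fit_4pl_series(np.full(20, 0.3))
        assert fit.p_value == 1.0

    def test_noisy_sigmoid_inflection_recovered(self):
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            x = np.arange(1, 41, dtype=float)
            y = logistic(x, 0.0, 0.4, -1.5, 25.0) + rng.normal(0, 0.05, 40)
            fit = fit_4pl_series(y)
            hits += abs(fit.c - 25.0) <= 2.0
        assert hits >= 0.9 * n_rep

    def test_too_few_windows(self):
        with pytest.raises(InsufficientData):
            fit_4pl_series(np.array([0.1, 0.2, 0.3, 0.4]))


def synthetic_scan(values, c, p_value=0.001, k_prime=7, b=-2.0):
    """Scan skeleton with a prescribed fit, for threshold-mapping tests."""
    k = len(values)
    n_windows = k - k_prime + 1
    windows = [Window(i, tuple(f"s{j:02d}" for j in range(i, i + k_prime)), 0.0)
               for i in range(1, n_windows + 1)]
    scan = ThresholdScan(
        metric=QualityMetric.COV, k=k, k_prime=k_prime, windows=windows,
        ranked_ids=[f"s{i:02d}" for i in range(k)], ranked_values=list(values),
    )
    from mrsmeta.threshold import LogisticFit
    scan.fit = LogisticFit(a=0.0, d=0.3, b=b, c=c, sse=0.0, r2=0.9, p_value=p_value)
    return scan


class TestDeriveThreshold:
    def test_integer_inflection_hits_exact_rank(self):
        values = list(np.linspace(30, 10, 20))
        scan = derive_threshold(synthetic_scan(values, c=5.0))
        # r* = 5 + 7 - 1 = 11 -> the 11th ranked dataset's value
        assert scan.threshold_value == pytest.approx(values[10])

    def test_fractional_inflection_interpolates(self):
        values = list(np.linspace(30, 10, 20))
        scan = derive_threshold(synthetic_scan(values, c=5.5))
        expected = (values[10] + values[11]) / 2
        assert scan.threshold_value == pytest.approx(expected)

    def test_not_significant_no_threshold(self):
        values = list(np.linspace(30, 10, 20))
        scan = derive_threshold(synthetic_scan(values, c=5.0, p_value=0.2))
        assert scan.threshold_value is None

    def test_out_of_range_inflection_no_threshold(self):
        values = list(np.linspace(30, 10, 20))
        scan = derive_threshold(synthetic_scan(values, c=40.0))
        assert scan.threshold_value is None

    def test_boundary_value_joins_better_side(self):
        # dataset with COV exactly T belongs to the high-quality subgroup
        values = [25.0, 22.0, 20.0, 19.0, 19.0, 17.0, 15.0, 14.0, 13.0, 12.0,
                  11.5, 11.0, 10.5, 10.0]
        scan = derive_threshold(synthetic_scan(values, c=1.0))
        assert scan.threshold_value == pytest.approx(values[6])
        ds = [make_dataset(f"s{i:02d}") for i in range(len(values))]
        scan = compare_quality_subgroups(scan, ds)
        high_k = scan.subgroup_high.k
        assert high_k == sum(v <= values[6] for v in values)


class TestStratificationGate:
    def test_refuses_below_14_reporting_datasets(self):
        values = list(np.linspace(28, 12, 13))
        scan = synthetic_scan(values, c=2.0)
        ds = [make_dataset(f"s{i:02d}") for i in range(13)]
        with pytest.raises(InsufficientData, match="14"):
            compare_quality_subgroups(scan, ds)

    def test_runs_at_exactly_14(self):
        values = list(np.linspace(28, 12, 14))
        scan = derive_threshold(synthetic_scan(values, c=2.0))
        ds = [make_dataset(f"s{i:02d}", mean_pt=10.0 + 0.02 * i) for i in range(14)]
        scan = compare_quality_subgroups(scan, ds)
        assert scan.p_subgroup_diff is not None


class TestEndToEnd:
    def test_attenuated_corpus_shows_quality_moderation(self):
        # one seeded corpus with a sharp quality threshold: the scan fits a
        # significant sigmoid and the high-quality subgroup shows the larger
        # pooled effect
        corpus = generate_corpus(
            SyntheticCorpusConfig(seed=1, attenuation=SigmoidAttenuation(threshold=0.20))
        )
        coll = RegionalCollection(Region.MPFC, Metabolite.CHO, corpus)
        scan = quality_threshold_scan(coll, QualityMetric.COV)
        assert scan.fit.p_value < 0.05
        if scan.threshold_declared and scan.subgroup_high is not None:
            assert scan.subgroup_high.pooled_g > scan.subgroup_low.pooled_g
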