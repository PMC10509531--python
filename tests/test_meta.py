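import numpy as np
import pytest

from mrsmeta.datasets import RegionalCollection, Region, Metabolite
from mrsmeta.effects import EffectSize, hedges_g
from mrsmeta.meta import (
    egger_test,
    meta_regress,
    pool_random_effects,
    remove_small_study_bias,
    subgroup_compare,
)
from conftest import make_dataset


def reml_grid_oracle(y, v, step=1e-4, upper=2.0):
    """Brute-force grid maximizer of the intercept-only restricted likelihood."""
    y = np.asarray(y)
    v = np.asarray(v)
    grid = np.arange(0.0, upper + step, step)
    best_t, best_ll = 0.0, -np.inf
    for t in grid:
        w = 1.0 / (v + t)
        mu = np.sum(w * y) / np.sum(w)
        ll = -0.5 * (
            np.sum(np.log(v + t)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
        )
        if ll > best_ll:
            best_ll, best_t = ll, t
    return best_t


def random_effects_instance(rng, k, tau2=0.05):
    v = rng.uniform(0.01, 0.3, k)
    g = rng.normal(0.1, np.sqrt(v + tau2))
    return [EffectSize(float(gi), float(vi)) for gi, vi in zip(g, v)]


class TestPooling:
    def test_identical_effects_collapse(self):
        effects = [EffectSize(-0.4, v) for v in (0.02, 0.1, 0.3, 0.05)]
        res = pool_random_effects(effects)
        assert res.pooled_g == pytest.approx(-0.4, abs=1e-10)
        assert res.tau2 == pytest.approx(0.0, abs=1e-8)
        assert res.i2 == pytest.approx(0.0, abs=1e-5)
        assert res.qe == pytest.approx(0.0, abs=1e-12)

    def test_fixed_effect_limit_closed_form(self, rng):
        effects = random_effects_instance(rng, 8)
        res = pool_random_effects(effects, weights="fixed")
        w = 1.0 / np.array([e.var_g for e in effects])
        g = np.array([e.g for e in effects])
        assert res.pooled_g == pytest.approx(float(np.sum(w * g) / np.sum(w)), abs=1e-14)
        assert res.se_pooled == pytest.approx(float(np.sqrt(1 / np.sum(w))), abs=1e-14)
        assert res.tau2 == 0.0

    def test_variance_doubling_scales_se(self):
        effects = [EffectSize(0.2, v) for v in (0.05, 0.1, 0.2)]
        base = pool_random_effects(effects)          # identical g: tau2 = 0
        doubled = pool_random_effects([EffectSize(0.2, 2 * e.var_g) for e in effects])
        assert doubled.se_pooled == pytest.approx(base.se_pooled * np.sqrt(2), rel=1e-8)

    def test_reml_matches_grid_oracle(self, rng):
        for _ in range(12):
            k = int(rng.integers(3, 13))
            effects = random_effects_instance(rng, k, tau2=float(rng.uniform(0, 0.3)))
            res = pool_random_effects(effects)
            oracle = reml_grid_oracle([e.g for e in effects], [e.var_g for e in effects])
            assert res.tau2 == pytest.approx(oracle, abs=2e-4)

    def test_permutation_invariance(self, rng):
        effects = random_effects_instance(rng, 9)
        res1 = pool_random_effects(effects)
        perm = [effects[i] for i in rng.permutation(9)]
        res2 = pool_random_effects(perm)
        assert res2.pooled_g == pytest.approx(res1.pooled_g, abs=1e-10)
        assert res2.tau2 == pytest.approx(res1.tau2, abs=1e-8)

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            pool_random_effects([EffectSize(0.1, 0.1)])

    def test_i2_within_range(self, rng):
        for _ in range(5):
            res = pool_random_effects(random_effects_instance(rng, 15, tau2=0.2))
            assert 0.0 <= res.i2 <= 100.0


class TestMetaRegression:
    def test_constant_moderator_rejected(self, rng):
        effects = random_effects_instance(rng, 10)
        with pytest.raises(ValueError, match="constant"):
            meta_regress(effects, {"x": [1.0] * 10})

    def test_collinear_moderator_named(self, rng):
        effects = random_effects_instance(rng, 10)
        x = list(rng.normal(size=10))
        with pytest.raises(ValueError, match="x2"):
            meta_regress(effects, {"x1": x, "x2": [2 * xi for xi in x]})

    def test_recovers_subgroup_difference(self, rng):
        # two subgroups with true effects -0.4 and 0.0, tiny sampling noise
        k = 60
        labels = np.r_[np.zeros(k // 2), np.ones(k // 2)]
        truth = -0.4 * (1 - labels)
        v = np.full(k, 1e-4)
        effects = [
            EffectSize(float(rng.normal(t, np.sqrt(vi))), float(vi))
            for t, vi in zip(truth, v)
        ]
        res = meta_regress(effects, {"grp": labels})
        assert res.coef[1] == pytest.approx(0.4, abs=0.02)
        assert res.p_qm < 1e-6

    def test_orthogonal_moderator_is_null(self, rng):
        ps = []
        for _ in range(200):
            effects = random_effects_instance(rng, 20)
            ps.append(meta_regress(effects, {"noise": list(rng.normal(size=20))}).p_qm)
        assert 0.005 < np.mean(np.array(ps) < 0.05) < 0.12


class TestSubgroupCompare:
    def _collection(self, te_values):
        ds = [make_dataset(f"s{i:02d}", te_ms=te) for i, te in enumerate(te_values)]
        return RegionalCollection(Region.MPFC, Metabolite.NAA, ds)

    def test_te_split_labels(self):
        coll = self._collection([30.0] * 6 + [80.0] * 6)
        res = subgroup_compare(coll, lambda d: "short" if d.te_ms <= 35 else "long")
        assert set(res.subgroups) == {"short", "long"}
        assert res.subgroups["short"].k == 6

    def test_statistically_identical_subgroups(self, rng):
        k = 40
        effects = [EffectSize(0.25, 0.04) for _ in range(k)]
        ds = [make_dataset(f"s{i:02d}") for i in range(k)]
        labels = ["a"] * 20 + ["b"] * 20
        res = subgroup_compare(ds, labels, effects=effects)
        assert res.qm == pytest.approx(0.0, abs=1e-10)

    def test_empty_side_rejected(self):
        coll = self._collection([30.0] * 8)
        with pytest.raises(ValueError):
            subgroup_compare(coll, lambda d: "short" if d.te_ms <= 35 else "long")


class TestEgger:
    def test_too_few_studies(self):
        with pytest.raises(ValueError):
            egger_test([EffectSize(0.1, 0.1), EffectSize(0.2, 0.1)])

    def test_planted_asymmetry_detected(self, rng):
        # g inflated proportionally to its standard error
        detected = 0
        for _ in range(30):
            v = rng.uniform(0.01, 0.4, 30)
            g = rng.normal(2.0 * np.sqrt(v), np.sqrt(v))
            res = egger_test([EffectSize(float(a), float(b)) for a, b in zip(g, v)])
            detected += res.p < 0.05
        assert detected >= 24  # power > 0.8 under strong bias

    def test_influence_scores_one_per_study(self, rng):
        v = rng.uniform(0.01, 0.4, 12)
        g = rng.normal(0, np.sqrt(v))
        res = egger_test([EffectSize(float(a), float(b)) for a, b in zip(g, v)])
        assert res.influence.shape == (12,)


class TestSmallStudyRemoval:
    def _collection_with_outlier(self):
        ds = []
        rng = np.random.default_rng(7)
        for i in range(14):
            n = 60
            ds.append(
                make_dataset(f"big{i:02d}", n_pt=n, n_con=n,
                             mean_pt=10.0 + rng.normal(0, 0.05), mean_con=10.0)
            )
        # one small study with a huge apparent effect drives the asymmetry
        ds.append(make_dataset("tiny99", n_pt=9, n_con=9, mean_pt=13.0, mean_con=10.0))
        return RegionalCollection(Region.MPFC, Metabolite.NAA, ds)

    def test_unchanged_when_not_significant(self):
        rng = np.random.default_rng(1)
        ds = [make_dataset(f"s{i:02d}", mean_pt=10.0 + float(rng.normal(0, 0.3)),
                           n_pt=15 + 3 * i, n_con=15 + 2 * i) for i in range(10)]
        coll = RegionalCollection(Region.MPFC, Metabolite.NAA, ds)
        out, log, egger = remove_small_study_bias(coll)
        assert egger.p >= 0.05
        assert len(out) == len(coll)
        assert log == []

    def test_planted_small_study_removed(self):
        coll = self._collection_with_outlier()
        before = egger_test([hedges_g(d) for d in coll])
        assert before.p < 0.05
        out, log, after = remove_small_study_bias(coll)
        assert len(out) == len(coll) - 1
        assert log[0]["study_id"] == "tiny99"
        assert after.p > before.p

    def test_removal_restricted_to_small_studies(self):
        coll = self._collection_with_outlier()
        out, log, _ = remove_small_study_bias(coll)
        removed_n = next(d.total_n for d in coll if d.study_id == log[0]["study_id"])
        median_n = float(np.median([d.total_n for d in coll]))
        assert removed_n < median_n
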