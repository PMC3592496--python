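"""MDL discretization, symmetrical uncertainty, CFS merit, GA search, rankers."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mirvote.selection import (
    DEFAULT_SELECTED_FEATURES,
    CorrelationCache,
    GAConfig,
    cfs_merit,
    discretize,
    ga_search,
    info_gain,
    mdl_discretize,
    relieff,
    symmetrical_uncertainty,
)


class TestMdlDiscretize:
    def test_perfect_separation_yields_one_cut(self):
        cuts = mdl_discretize([1, 1, 2, 2], ["+", "+", "-", "-"])
        assert len(cuts) == 1
        assert 1 < cuts[0] < 2

    def test_constant_column_no_cuts(self):
        assert len(mdl_discretize([3, 3, 3, 3], ["+", "-", "+", "-"])) == 0

    def test_uninformative_interleaving_rejected(self):
        # alternating labels along the value axis carry no split information
        values = np.arange(20, dtype=float)
        labels = np.tile(["+", "-"], 10)
        assert len(mdl_discretize(values, labels)) == 0

    def test_separable_blocks_recovered(self):
        values = np.concatenate([np.zeros(30), np.ones(30), np.full(30, 2.0)])
        labels = ["a"] * 30 + ["b"] * 30 + ["a"] * 30
        cuts = mdl_discretize(values, labels)
        disc = discretize(values, cuts)
        assert len(np.unique(disc)) == 3


class TestSymmetricalUncertainty:
    def test_identical_columns(self):
        a = [0, 0, 1, 1, 2, 2]
        assert symmetrical_uncertainty(a, a) == pytest.approx(1.0)

    def test_independent_columns(self):
        a = [0, 0, 1, 1]
        b = [0, 1, 0, 1]
        assert symmetrical_uncertainty(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_joint(self):
        # joint counts: (0,0)=4, (0,1)=2, (1,0)=1, (1,1)=3 over n=10
        a = [0] * 6 + [1] * 4
        b = [0] * 4 + [1] * 2 + [0] * 1 + [1] * 3
        n = 10.0
        ha = -(0.6 * math.log2(0.6) + 0.4 * math.log2(0.4))
        hb = -(0.5 * math.log2(0.5) * 2)
        hab = -sum(c / n * math.log2(c / n) for c in (4, 2, 1, 3))
        expected = 2 * (ha + hb - hab) / (ha + hb)
        assert symmetrical_uncertainty(a, b) == pytest.approx(expected)

    def test_both_constant(self):
        assert symmetrical_uncertainty([1, 1], [2, 2]) == 0.0


def make_cache(r_cf, r_ff=None):
    d = len(r_cf)
    return CorrelationCache(
        feature_names=tuple(f"f{k}" for k in range(d)),
        r_cf=np.asarray(r_cf, float),
        r_ff=np.zeros((d, d)) if r_ff is None else np.asarray(r_ff, float),
    )


class TestCfsMerit:
    def test_singleton_reduces_to_rcf(self):
        cache = make_cache([0.3, 0.7])
        assert cfs_merit(["f1"], cache) == pytest.approx(0.7)

    def test_uncorrelated_quartet(self):
        cache = make_cache([0.5] * 4)
        assert cfs_merit(["f0", "f1", "f2", "f3"], cache) == pytest.approx(1.0)

    def test_zero_class_correlation(self):
        cache = make_cache([0.0, 0.0], r_ff=[[0, 0.5], [0.5, 0]])
        assert cfs_merit(["f0", "f1"], cache) == 0.0

    def test_empty_subset(self):
        assert cfs_merit([], make_cache([0.5])) == 0.0

    def test_redundancy_penalty(self):
        indep = make_cache([0.5, 0.5])
        redun = make_cache([0.5, 0.5], r_ff=[[0, 0.9], [0.9, 0]])
        assert cfs_merit(["f0", "f1"], redun) < cfs_merit(["f0", "f1"], indep)


def random_table(rng, n=60, d=10):
    y = rng.integers(0, 2, n)
    cols = {
        f"f{k}": rng.random(n) + y * rng.random() * rng.choice([0.0, 1.0, 2.0])
        for k in range(d)
    }
    return pd.DataFrame(cols), y


class TestGaSearch:
    def test_matches_exhaustive_on_random_tables(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            X, y = random_table(rng, d=int(rng.integers(8, 11)))
            cache = CorrelationCache.from_table(X, y)
            d = cache.n_features
            best = max(
                cfs_merit(list(sub), cache)
                for r in range(1, d + 1)
                for sub in itertools.combinations(range(d), r)
            )
            res = ga_search(cache, GAConfig(seed=trial))
            assert res.merit == pytest.approx(best)

    def test_single_informative_feature_selected(self):
        cache = make_cache([0.0, 1.0, 0.0, 0.0])
        res = ga_search(cache, GAConfig(seed=0))
        assert res.selected == ("f1",)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X, y = random_table(rng)
        cache = CorrelationCache.from_table(X, y)
        a = ga_search(cache, GAConfig(seed=5))
        b = ga_search(cache, GAConfig(seed=5))
        assert a.selected == b.selected and a.merit == b.merit


class TestRelieff:
    def test_constant_feature_gets_zero_weight(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"const": np.ones(40), "noise": rng.random(40)})
        y = rng.integers(0, 2, 40)
        res = relieff(X, y, seed=1)
        assert res.weights["const"] == 0.0

    def test_class_indicator_dominates(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 60)
        X = pd.DataFrame({
            "indicator": y.astype(float),
            "noise1": rng.random(60),
            "noise2": rng.random(60),
        })
        res = relieff(X, y, seed=2)
        assert res.selected[0] == "indicator"
        assert res.weights["indicator"] > max(
            res.weights["noise1"], res.weights["noise2"]
        )

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        X, y = random_table(rng, n=40, d=5)
        a = relieff(X, y, seed=9, m_samples=20)
        b = relieff(X, y, seed=9, m_samples=20)
        assert a.weights == b.weights

    def test_single_class_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ValueError):
            relieff(X, [1, 1])


class TestInfoGain:
    def test_class_copy_recovers_class_entropy(self):
        y = np.array([0] * 30 + [1] * 30)
        X = pd.DataFrame({"copy": y.astype(float)})
        res = info_gain(X, y)
        assert res.weights["copy"] == pytest.approx(1.0)  # H(y) = 1 bit

    def test_constant_feature_zero_gain(self):
        y = np.array([0, 1] * 20)
        X = pd.DataFrame({"const": np.ones(40)})
        assert info_gain(X, y).weights["const"] == 0.0

    def test_ranking_descends(self):
        rng = np.random.default_rng(2)
        X, y = random_table(rng)
        res = info_gain(X, y)
        w = [res.weights[f] for f in res.selected]
        assert w == sorted(w, reverse=True)


class TestDefaultSelection:
    def test_shipped_list_is_twenty_registry_features(self):
        from mirvote.features import FEATURE_NAMES
        assert len(DEFAULT_SELECTED_FEATURES) == 20
        assert len(set(DEFAULT_SELECTED_FEATURES)) == 20
        assert set(DEFAULT_SELECTED_FEATURES) <= set(FEATURE_NAMES)

    def test_selection_result_json_round_trips(self):
        import json
        cache = make_cache([0.2, 0.8])
        res = ga_search(cache, GAConfig(seed=0))
        payload = json.loads(res.to_json())
        assert payload["method"] == "cfs_ga"
        assert payload["selected"] == list(res.selected)
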