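"""Permutation inference on regional volumes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepcog import (bonferroni_threshold, percent_difference,
                      permutation_region_test, split_contrasts, summary_volume)
from sleepcog.errors import SleepcogError


class TestBonferroni:
    def test_published_configuration(self):
        assert bonferroni_threshold(0.05, 140) == 0.05 / 140

    def test_single_test_leaves_alpha(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_corrected_flags_subset_of_uncorrected(self, rng):
        V = rng.normal(size=(60, 30))
        labels = rng.random(60) < 0.5
        res_corr = permutation_region_test(V, labels, n_perm=300, seed=1,
                                           n_comparisons=30, method="sampling")
        res_raw = permutation_region_test(V, labels, n_perm=300, seed=1,
                                          n_comparisons=1, method="sampling")
        assert set(np.flatnonzero(res_corr.significant)) <= set(np.flatnonzero(res_raw.significant))


class TestPercentDifference:
    def test_equal_means_zero(self):
        assert percent_difference(5.0, 5.0) == 0.0

    def test_direct_formula(self):
        assert percent_difference(102.0, 98.0) == pytest.approx(4.0)

    @given(st.floats(-100, 100), st.floats(-100, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetry(self, a, b):
        f, r = percent_difference(a, b), percent_difference(b, a)
        if np.isnan(f):
            assert np.isnan(r)
        else:
            assert f == pytest.approx(-r, abs=1e-9)

    def test_zero_average_is_missing(self):
        assert np.isnan(percent_difference(1.0, -1.0))


class TestPermutationRegionTest:
    def test_exhaustive_enumeration_small_instance(self):
        # A = {1, 2}, B = {10, 11}: of the 6 arrangements only the observed
        # split and its mirror reach |t|, so the two-sided p is 2/6
        V = np.array([[1.0], [2.0], [10.0], [11.0]])
        labels = np.array([True, True, False, False])
        res = permutation_region_test(V, labels, method="exhaustive")
        assert res["p_perm"][0] == pytest.approx(2 / 6)
        assert res["n_perm"][0] == 6

    def test_sampling_agrees_with_enumeration(self, rng):
        V = rng.normal(size=(10, 5))
        V[:5] += 1.0
        labels = np.array([True] * 5 + [False] * 5)
        ex = permutation_region_test(V, labels, method="exhaustive")
        mc = permutation_region_test(V, labels, n_perm=5000, seed=0, method="sampling")
        sd = np.sqrt(ex["p_perm"] * (1 - ex["p_perm"]) / 5000)
        assert (np.abs(mc["p_perm"] - ex["p_perm"]) <= 3 * sd + 1e-3).all()

    def test_identical_group_distributions_give_t_zero_p_one(self, rng):
        # both groups hold the same multiset of values, so t = 0 exactly
        base = rng.normal(size=(200, 3))
        V = np.vstack([base, base])
        labels = np.array([True] * 200 + [False] * 200)
        res = permutation_region_test(V, labels, n_perm=300, seed=3, method="sampling")
        assert np.allclose(res["t_observed"], 0.0, atol=1e-10)
        assert (res["p_perm"] > 0.9).all()

    def test_same_seed_reproduces_pvalues(self, rng):
        V = rng.normal(size=(100, 10))
        labels = rng.random(100) < 0.4
        r1 = permutation_region_test(V, labels, n_perm=400, seed=9, method="sampling")
        r2 = permutation_region_test(V, labels, n_perm=400, seed=9, method="sampling")
        pd.testing.assert_frame_equal(r1, r2)

    def test_null_calibration_uncorrected(self, rng):
        n, m = 400, 150
        V = rng.normal(size=(n, m))
        labels = rng.random(n) < 0.7
        res = permutation_region_test(V, labels, n_perm=400, seed=5,
                                      n_comparisons=1, method="sampling")
        frac = (res["p_perm"] <= 0.05).mean()
        band = 3 * np.sqrt(0.05 * 0.95 / m)
        assert abs(frac - 0.05) <= band + 0.01

    def test_mean_offsets_shift_percent_diff_not_t(self, rng):
        V = rng.normal(size=(80, 2))
        labels = rng.random(80) < 0.5
        r0 = permutation_region_test(V, labels, n_perm=200, seed=1, method="sampling")
        r1 = permutation_region_test(V, labels, n_perm=200, seed=1, method="sampling",
                                     mean_offsets=np.array([100.0, 100.0]))
        assert np.allclose(r0["t_observed"], r1["t_observed"])
        assert (np.abs(r1["percent_diff"]) < np.abs(r0["percent_diff"])).all()

    def test_degenerate_groups_rejected(self, rng):
        V = rng.normal(size=(5, 2))
        with pytest.raises(SleepcogError):
            permutation_region_test(V, np.array([True, False, False, False, False]))


class TestSplitContrasts:
    def test_effect_classes_separate(self, rng):
        """Regions losing volume only beyond 8 h are flagged against long
        sleepers but not against short sleepers; inverted-U regions hit both."""
        n = 6000
        sleep = rng.choice(np.arange(1, 13), n,
                           p=np.array([1, 1, 2, 4, 10, 19, 30, 20, 6, 4, 2, 1]) / 100)
        q = (sleep - 7.0) ** 2
        h = np.maximum(0, sleep - 8.0)
        V = pd.DataFrame({
            "quad": -3.0 * q + rng.normal(0, 10, n),
            "long": -8.0 * h + rng.normal(0, 10, n),
            "null": rng.normal(0, 10, n),
        })
        out = split_contrasts(V, sleep, n_perm=2000, seed=2, n_comparisons=4)
        short, long_ = out["short"].set_index("region_id"), out["long"].set_index("region_id")
        assert short.loc["quad", "significant"] and long_.loc["quad", "significant"]
        assert long_.loc["long", "significant"] and not short.loc["long", "significant"]
        assert not short.loc["null", "significant"] and not long_.loc["null", "significant"]

    def test_empty_side_skipped(self, rng):
        sleep = rng.choice([6, 7, 8, 9, 10], 200)
        V = pd.DataFrame({"a": rng.normal(size=200)})
        out = split_contrasts(V, sleep, n_perm=200, seed=0)
        assert out["short"] is None and out["long"] is not None


class TestSummaryVolume:
    def test_single_region_equals_zscore(self, rng):
        V = pd.DataFrame({"a": rng.normal(10, 2, 300)})
        s = summary_volume(V, ["a"])
        z = (V["a"] - V["a"].mean()) / V["a"].std(ddof=0)
        assert np.allclose(s, z, atol=1e-12)

    def test_mean_zero_and_brute_force(self, rng):
        V = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        s = summary_volume(V, ["a", "c", "d"])
        assert abs(s.mean()) < 1e-10
        brute = np.mean([(V[c] - V[c].mean()) / V[c].std(ddof=0)
                         for c in ["a", "c", "d"]], axis=0)
        assert np.allclose(s, brute, atol=1e-12)

    def test_zero_variance_region_excluded(self, rng):
        V = pd.DataFrame({"a": rng.normal(size=100), "b": np.ones(100)})
        s = summary_volume(V, ["a", "b"])
        assert np.allclose(s, (V["a"] - V["a"].mean()) / V["a"].std(ddof=0), atol=1e-12)

    def test_no_regions_rejected(self, rng):
        V = pd.DataFrame({"a": rng.normal(size=100)})
        with pytest.raises(SleepcogError):
            summary_volume(V, [])
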