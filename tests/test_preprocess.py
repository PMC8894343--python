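"""Transforms, MAD outlier flagging and confound regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepcog import (log_wmh, mad_outlier_mask, regress_confounds,
                      transform_cognitive)
from sleepcog.errors import RankDeficiencyError, SleepcogError
from sleepcog.preprocess import CONFOUND_COLUMNS
from sleepcog.simulate import TASK_COLUMNS


def _pheno(n=6, **cols):
    base = {
        "participant_id": [f"P{i}" for i in range(n)],
        "task_pairs_errors": np.full(n, 8.0),
        "task_trail_diff": np.full(n, 20.0),
        "task_tower_accuracy": np.full(n, 7.0),
        "task_reaction_time": np.full(n, 500.0),
        "task_symbol_digit": np.full(n, 19.0),
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestTransformCognitive:
    def test_known_values(self):
        out = transform_cognitive(_pheno(
            task_pairs_errors=np.array([8.0] * 6),
            task_reaction_time=np.array([1.0] * 6)))
        assert np.allclose(out["task_pairs_errors"], 2.0)
        assert np.allclose(out["task_reaction_time"], 0.0)

    def test_matches_direct_formula_elementwise(self, rng):
        errors = rng.uniform(0, 30, 200)
        trail = rng.uniform(1, 120, 200)
        rt = rng.uniform(300, 1500, 200)
        out = transform_cognitive(_pheno(
            n=200, task_pairs_errors=errors, task_trail_diff=trail,
            task_reaction_time=rt))
        assert np.allclose(out["task_pairs_errors"], np.cbrt(errors), atol=1e-12)
        assert np.allclose(out["task_trail_diff"], np.log(trail), atol=1e-12)
        assert np.allclose(out["task_reaction_time"], np.log(rt), atol=1e-12)

    def test_missing_cells_stay_missing_and_others_untouched(self):
        df = _pheno()
        df.loc[0, "task_pairs_errors"] = np.nan
        out = transform_cognitive(df)
        assert np.isnan(out.loc[0, "task_pairs_errors"])
        assert (out["task_symbol_digit"] == df["task_symbol_digit"]).all()

    def test_nonpositive_trail_shift_policy(self):
        df = _pheno(task_trail_diff=np.array([-3.0, 1.0, 2.0, 5.0, 5.0, 5.0]))
        out = transform_cognitive(df)
        assert out.attrs["trail_shift"] == 4.0
        assert np.allclose(out["task_trail_diff"],
                           np.log(np.array([-3, 1, 2, 5, 5, 5]) + 4.0))

    def test_nonpositive_reaction_time_set_missing_with_count(self):
        df = _pheno(task_reaction_time=np.array([0.0, 500, 500, 500, 500, 500]))
        out = transform_cognitive(df)
        assert np.isnan(out.loc[0, "task_reaction_time"])
        assert out.attrs["transform_warnings"]["task_reaction_time_nonpositive"] == 1

    def test_double_application_rejected(self):
        out = transform_cognitive(_pheno())
        with pytest.raises(SleepcogError, match="already applied"):
            transform_cognitive(out)


class TestMadOutlierMask:
    def test_single_gross_outlier_flagged(self):
        mask = mad_outlier_mask([1, 1, 1, 1, 100], k=5)
        assert mask.tolist() == [False, False, False, False, True]

    def test_constant_vector_yields_no_flags(self):
        assert not mad_outlier_mask([3.0] * 10, k=5).any()

    def test_data_within_threshold_not_flagged(self):
        x = np.array([-2, -1, 0, 1, 2], dtype=float)
        assert not mad_outlier_mask(x, k=5).any()

    def test_missing_entries_never_flagged(self):
        x = np.array([1, 1, 1, 1, np.nan, 100.0])
        mask = mad_outlier_mask(x, k=5)
        assert not mask[4] and mask[5]

    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=40),
           st.floats(1, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mask_matches_definition(self, values, k):
        x = np.asarray(values)
        mask = mad_outlier_mask(x, k=k)
        med = np.median(x)
        mad = 1.4826 * np.median(np.abs(x - med))
        if mad > 0:
            assert np.array_equal(mask, np.abs(x - med) > k * mad)

    def test_too_few_values_rejected(self):
        with pytest.raises(SleepcogError):
            mad_outlier_mask([1.0, 2.0], k=5)


def _imaging(n, rng, volumes):
    df = pd.DataFrame({
        "participant_id": [f"P{i}" for i in range(n)],
        "conf_age": rng.integers(45, 80, n).astype(float),
        "conf_head_size": rng.normal(1, 0.1, n),
        "conf_table_position": rng.normal(0, 4, n),
        "conf_scan_date": rng.integers(0, 2000, n).astype(float),
    })
    for name, v in volumes.items():
        df[name] = v
    df["wmh_volume"] = np.exp(rng.normal(8, 0.4, n))
    return df


class TestRegressConfounds:
    def test_exact_linear_confound_functions_give_zero_residuals(self, rng):
        n = 200
        df = _imaging(n, rng, {})
        age = df["conf_age"] - df["conf_age"].mean()
        df["vol_a"] = 3.0 + 2 * age + 0.5 * age**2 - 1.2 * df["conf_head_size"]
        df["vol_b"] = 7.0 + 0.3 * df["conf_table_position"] + 0.01 * df["conf_scan_date"]
        out = regress_confounds(df)
        assert np.allclose(out["vol_a"], 0, atol=1e-8)
        assert np.allclose(out["vol_b"], 0, atol=1e-8)

    def test_residuals_orthogonal_to_each_confound(self, rng):
        n = 500
        df = _imaging(n, rng, {"vol": rng.normal(5000, 100, n)})
        out = regress_confounds(df)
        resid = out["vol"].to_numpy()
        for col in CONFOUND_COLUMNS:
            x = df[col].to_numpy(dtype=float)
            assert abs(resid @ (x - x.mean())) / (np.linalg.norm(resid) * np.linalg.norm(x - x.mean()) + 1e-30) < 1e-8

    def test_effect_orthogonal_to_confounds_survives_deconfounding(self, rng):
        n = 20_000
        df = _imaging(n, rng, {})
        group = rng.random(n) < 0.5  # independent of confounds
        effect = 10.0
        df["vol"] = (5000 + effect * group + 0.5 * (df["conf_age"] - 60)
                     + rng.normal(0, 5, n))
        before = df.loc[group, "vol"].mean() - df.loc[~group, "vol"].mean()
        out = regress_confounds(df)
        after = out.loc[group, "vol"].mean() - out.loc[~group, "vol"].mean()
        assert abs(after - effect) / effect < 0.02

    def test_row_count_unchanged_and_means_recorded(self, rng):
        df = _imaging(100, rng, {"vol": rng.normal(5000, 100, 100)})
        out = regress_confounds(df)
        assert len(out) == 100
        assert abs(out.attrs["volume_column_means"]["vol"] - df["vol"].mean()) < 1e-9

    def test_collinear_confounds_raise_with_names(self, rng):
        df = _imaging(50, rng, {"vol": rng.normal(0, 1, 50)})
        df["conf_table_position"] = 2.0 * df["conf_head_size"]
        with pytest.raises(RankDeficiencyError) as err:
            regress_confounds(df)
        assert "head_size" in str(err.value) or "table_position" in str(err.value)

    def test_missing_confound_rows_dropped_and_counted(self, rng):
        df = _imaging(60, rng, {"vol": rng.normal(0, 1, 60)})
        df.loc[0, "conf_head_size"] = np.nan
        out = regress_confounds(df)
        assert len(out) == 59
        assert out.attrs["confound_exclusions"] == 1


class TestLogWmh:
    def test_known_values(self, rng):
        df = _imaging(4, np.random.default_rng(0), {})
        df["wmh_volume"] = [1.0, np.e**2, 10.0, 100.0]
        out = log_wmh(df)
        assert out["wmh_volume"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["wmh_volume"].iloc[1] == pytest.approx(2.0, abs=1e-12)

    def test_lognormal_sample_becomes_symmetric(self, rng):
        from scipy import stats
        df = _imaging(20_000, rng, {})
        raw_skew = stats.skew(df["wmh_volume"])
        out = log_wmh(df)
        assert raw_skew > 1.0
        assert abs(stats.skew(out["wmh_volume"])) < 0.1

    def test_nonpositive_excluded_with_count(self, rng):
        df = _imaging(5, np.random.default_rng(0), {})
        df["wmh_volume"] = [-1.0, 0.0, 1.0, 2.0, 3.0]
        out = log_wmh(df)
        assert out.attrs["wmh_exclusions"] == 2
        assert out["wmh_volume"].isna().sum() == 2
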