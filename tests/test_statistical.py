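import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitalrep import (
    base_stats,
    correlation_filter,
    extract_features,
    feature_matrix,
    feature_names,
    first_difference,
)

from conftest import make_record


def brute_force_stats(x):
    """Independent direct-summation oracle for the nine statistics."""
    x = list(map(float, x))
    T = len(x)
    mu = sum(x) / T
    var = sum((v - mu) ** 2 for v in x) / T
    sigma = var**0.5
    s = sorted(x)

    def q(p):
        rank = min(max((T + 1) * p, 1.0), float(T))
        lo, hi = int(rank) - 1, min(int(rank), T - 1) if rank != int(rank) else int(rank) - 1
        frac = rank - int(rank)
        return s[lo] + frac * (s[hi] - s[lo])

    skew = sum((v - mu) ** 3 for v in x) / T / sigma**3 if sigma else 0.0
    kurt = sum((v - mu) ** 4 for v in x) / T / sigma**4 if sigma else 0.0
    return {
        "mean": mu, "std": sigma, "min": s[0], "perc25": q(0.25),
        "perc50": q(0.50), "perc75": q(0.75), "max": s[-1],
        "skew": skew, "kurt": kurt,
    }


class TestBaseStats:
    def test_symmetric_input_has_zero_skew(self):
        st_ = base_stats([1, 2, 3])
        assert st_["mean"] == 2.0
        assert st_["skew"] == pytest.approx(0.0, abs=1e-12)

    def test_quantile_rank_convention(self):
        # 25% quantile of 7 sorted points sits at rank (7+1)/4 = 2
        st_ = base_stats([1, 2, 3, 4, 5, 6, 7])
        assert st_["perc25"] == 2.0
        assert st_["perc50"] == 4.0
        assert st_["perc75"] == 6.0

    def test_quantile_interpolates_between_ranks(self):
        # n=4: rank (5)/4 = 1.25 -> 1 + 0.25*(2-1)
        assert base_stats([1, 2, 3, 4])["perc25"] == 1.25

    def test_kurtosis_is_not_excess(self):
        st_ = base_stats([-1, 1, -1, 1])
        assert st_["mean"] == 0.0 and st_["std"] == 1.0 and st_["kurt"] == 1.0

    def test_kurtosis_of_normal_sample_near_three(self):
        x = np.random.default_rng(0).normal(size=100_000)
        assert abs(base_stats(x)["kurt"] - 3.0) < 0.1

    def test_degenerate_series_policy(self):
        st_ = base_stats([5.0, 5.0, 5.0])
        assert st_.degenerate
        assert st_["skew"] == 0.0 and st_["kurt"] == 0.0 and st_["std"] == 0.0

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            base_stats([])

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            x = rng.normal(rng.uniform(-50, 50), rng.uniform(0.1, 20), rng.integers(2, 60))
            got = base_stats(x)
            want = brute_force_stats(x)
            for k, v in want.items():
                assert got[k] == pytest.approx(v, abs=1e-12), k


class TestFirstDifference:
    def test_definition(self):
        assert list(first_difference([1, 3, 6])) == [2.0, 3.0]

    def test_constant_is_zero(self):
        assert list(first_difference([4, 4, 4])) == [0.0, 0.0]

    def test_single_application(self):
        # diff([1,2,4,8]) = [1,2,4]; diff of that = [1,2] -- pipeline applies once
        once = first_difference([1, 2, 4, 8])
        assert list(once) == [1.0, 2.0, 4.0]
        assert list(first_difference(once)) == [1.0, 2.0]

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            first_difference([1.0])


class TestExtractFeatures:
    def test_ninety_named_features(self, complete_record):
        fv = extract_features(complete_record)
        assert len(fv) == 90
        assert list(fv.features) == feature_names()

    def test_names_follow_table_convention(self):
        names = feature_names()
        assert "mean_hr" in names
        assert "min_diff_hr" in names
        assert "perc25_nisysbp" in names
        assert "diff-skew_diff_hr" in names
        assert "diff-kurt_diff_pp" in names
        # diastolic channel uses the trailing-'e' spelling throughout
        assert "mean_nidiasbpe" in names and "mean_nidiasbp" not in names
        assert len(set(names)) == 90

    def test_missing_indicator_named_in_error(self, complete_record):
        del complete_record.series["spo2"]
        with pytest.raises(ValueError, match="spo2"):
            extract_features(complete_record)

    def test_constant_record_flags_degenerate(self):
        rec = make_record(
            {ind: [50.0] * 10 for ind in ("hr", "nisysbp", "nidiasbp", "pp")}
            | {"spo2": [98.0] * 10}
        )
        fv = extract_features(rec)
        assert set(fv.degenerate_channels) == {"hr", "nisysbp", "nidiasbp", "spo2", "pp"}
        assert fv["std_hr"] == 0.0 and fv["kurt_hr"] == 0.0

    def test_mean_hr_matches_recomputation(self, small_cohort):
        for rec in small_cohort.records[:5]:
            fv = extract_features(rec)
            assert fv["mean_hr"] == pytest.approx(rec.series["hr"].values.mean(), rel=1e-12)
            assert fv["mean_diff_spo2"] == pytest.approx(
                np.diff(rec.series["spo2"].values).mean(), abs=1e-12
            )

    def test_order_free_stats_but_order_sensitive_diffs(self, complete_record):
        fv = extract_features(complete_record)
        shuffled = make_record({})
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(complete_record.series["hr"]))
        for ind, s in complete_record.series.items():
            shuffled.series[ind] = type(s)(ind, s.times, s.values[perm])
        fv2 = extract_features(shuffled)
        # distributional stats of the raw series are permutation invariant
        for stat in ("mean", "std", "min", "perc25", "perc50", "perc75", "max", "skew", "kurt"):
            assert fv2[f"{stat}_hr"] == pytest.approx(fv[f"{stat}_hr"], rel=1e-12)
        # difference features are not
        assert fv2["std_diff_hr"] != pytest.approx(fv["std_diff_hr"], rel=1e-6)


class TestCorrelationFilter:
    def test_constant_column_removed(self, small_cohort):
        df = feature_matrix(small_cohort)
        df["flat"] = 1.0
        out, report = correlation_filter(df)
        assert "flat" not in out.columns
        assert report["dropped"]["flat"] == "zero variance"

    def test_duplicate_column_drops_exactly_one(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=40)})
        df["b"] = df["a"]
        df["c"] = rng.normal(size=40)
        out, report = correlation_filter(df)
        assert list(out.columns) == ["a", "c"]
        assert "b" in report["dropped"]

    def test_independent_columns_survive(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(200, 10)), columns=[f"f{i}" for i in range(10)])
        out, report = correlation_filter(df)
        assert out.shape == df.shape and not report["dropped"]

    def test_single_row_is_error(self):
        with pytest.raises(ValueError):
            correlation_filter(pd.DataFrame({"a": [1.0]}))


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=10, deadline=None)
def test_feature_count_invariant_on_random_records(seed):
    """Every complete record yields exactly 90 features, whatever its data."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 50))
    vals = {
        "hr": rng.normal(75, 10, n),
        "nisysbp": rng.normal(120, 10, n),
        "nidiasbp": rng.normal(70, 8, n),
        "spo2": np.clip(rng.normal(97, 1, n), 0, 100),
    }
    vals["pp"] = vals["nisysbp"] - vals["nidiasbp"]
    assert len(extract_features(make_record(vals))) == 90
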