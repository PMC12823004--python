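"""Tests for imputation, scaling, splitting and leakage-safe lag features."""
import numpy as np
import pandas as pd
import pytest

from aquadiag.preprocess import (MeanImputer, RobustScaler, SplitSpec,
                                 ZScoreScaler, chronological_split,
                                 handle_outliers, impute_mean,
                                 make_lag_features, read_timeseries_csv,
                                 resample_daily, robust_standardize,
                                 write_timeseries_csv, zscore_standardize)


def ts_frame(values, freq="D", **cols):
    n = len(values) if not cols else len(next(iter(cols.values())))
    idx = pd.date_range("2024-01-01", periods=n, freq=freq)
    if cols:
        return pd.DataFrame(cols, index=idx)
    return pd.DataFrame({"x": values}, index=idx)


class TestImputeMean:
    def test_missing_filled_with_observed_mean(self):
        out = impute_mean(np.array([1.0, np.nan, 3.0]))
        np.testing.assert_allclose(out, [1.0, 2.0, 3.0])

    def test_complete_column_unchanged(self):
        x = np.array([4.0, 5.0, 6.0])
        np.testing.assert_array_equal(impute_mean(x), x)

    def test_single_observed_value_propagates(self):
        np.testing.assert_allclose(impute_mean(np.array([5.0, np.nan, np.nan])),
                                   [5.0, 5.0, 5.0])

    def test_all_missing_names_column(self):
        df = pd.DataFrame({"good": [1.0, 2.0], "empty": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="empty"):
            impute_mean(df)

    def test_imputer_uses_train_means_only(self):
        train = pd.DataFrame({"a": [1.0, 3.0]})
        test = pd.DataFrame({"a": [np.nan, 100.0]})
        imp = MeanImputer().fit(train)
        out = imp.transform(test)
        assert out["a"].iloc[0] == 2.0  # train mean, not test mean


class TestRobustScaling:
    def test_median_iqr_example(self):
        scaled, scaler = robust_standardize(np.array([1.0, 2, 3, 4, 5]).reshape(-1, 1))
        np.testing.assert_allclose(scaled.to_numpy().ravel(),
                                   [-1.0, -0.5, 0.0, 0.5, 1.0])
        assert scaler.medians_.iloc[0] == 3.0 and scaler.iqrs_.iloc[0] == 2.0

    def test_constant_column_names_offender(self):
        df = pd.DataFrame({"ok": [1.0, 2, 3, 4], "flat": [7.0, 7, 7, 7]})
        with pytest.raises(ValueError, match="flat"):
            robust_standardize(df)

    def test_refit_of_scaled_data_is_identity(self):
        scaled, _ = robust_standardize(np.arange(9.0).reshape(-1, 1))
        rescaled, s2 = robust_standardize(scaled)
        assert s2.medians_.iloc[0] == pytest.approx(0.0)
        assert s2.iqrs_.iloc[0] == pytest.approx(1.0)
        np.testing.assert_allclose(rescaled.to_numpy(), scaled.to_numpy())

    def test_transform_uses_train_statistics(self):
        train = pd.DataFrame({"a": [1.0, 2, 3, 4, 5]})
        scaler = RobustScaler().fit(train)
        out = scaler.transform(pd.DataFrame({"a": [7.0]}))
        assert out["a"].iloc[0] == pytest.approx(2.0)

    def test_inverse_round_trip(self):
        df = pd.DataFrame({"a": [1.0, 5, 2, 8, 4]})
        scaler = RobustScaler().fit(df)
        back = scaler.inverse_transform(scaler.transform(df))
        np.testing.assert_allclose(back.to_numpy(), df.to_numpy())


class TestZScore:
    def test_already_standardized_unchanged(self):
        scaled, _ = zscore_standardize(np.array([-1.0, 1.0]).reshape(-1, 1))
        np.testing.assert_allclose(scaled.to_numpy().ravel(), [-1.0, 1.0])

    def test_population_sd_convention(self):
        scaled, _ = zscore_standardize(np.array([0.0, 2.0]).reshape(-1, 1))
        np.testing.assert_allclose(scaled.to_numpy().ravel(), [-1.0, 1.0])

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            ZScoreScaler().fit(pd.DataFrame({"a": [3.0, 3.0]}))


class TestChronologicalSplit:
    def test_reference_1080_split(self):
        df = ts_frame(np.arange(1080.0))
        tr, va, te = chronological_split(df)
        assert (len(tr), len(va), len(te)) == (756, 216, 108)

    def test_exact_ratio_on_ten_rows(self):
        tr, va, te = chronological_split(ts_frame(np.arange(10.0)))
        assert (len(tr), len(va), len(te)) == (7, 2, 1)

    def test_blocks_are_disjoint_exhaustive_and_ordered(self):
        df = ts_frame(np.arange(100.0))
        tr, va, te = chronological_split(df)
        recombined = pd.concat([tr, va, te])
        pd.testing.assert_frame_equal(recombined, df)
        assert tr.index.max() < va.index.min() < te.index.min()

    def test_unsorted_rejected_unless_auto_sort(self):
        df = ts_frame(np.arange(20.0)).iloc[::-1]
        with pytest.raises(ValueError, match="sort"):
            chronological_split(df)
        tr, _, _ = chronological_split(df, auto_sort=True)
        assert tr.index.is_monotonic_increasing

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            chronological_split(ts_frame(np.arange(9.0)))


class TestLagFeatures:
    def test_single_lag_enumeration(self):
        df = ts_frame([1.0, 2.0, 3.0, 4.0])
        out = make_lag_features(df, [1], "x", horizon=1)
        np.testing.assert_allclose(out["x_lag1"], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(out["target"], [2.0, 3.0, 4.0])

    def test_first_valid_row_at_max_lag(self):
        df = ts_frame([1.0, 2.0, 3.0, 4.0])
        out = make_lag_features(df, [1, 2], "x")
        assert len(out) == 2
        np.testing.assert_allclose(out.iloc[0][["x_lag1", "x_lag2"]], [2.0, 1.0])

    def test_horizon_two_shifts_target(self):
        df = ts_frame([1.0, 2.0, 3.0, 4.0])
        out = make_lag_features(df, [1], "x", horizon=2)
        np.testing.assert_allclose(out["x_lag1"], [1.0, 2.0])
        np.testing.assert_allclose(out["target"], [3.0, 4.0])

    def test_lag_zero_rejected_as_leakage(self):
        with pytest.raises(ValueError, match="leak"):
            make_lag_features(ts_frame([1.0, 2.0, 3.0]), [0, 1], "x")

    def test_future_mutation_leaves_features_unchanged(self):
        """No feature may depend on data at or after its target boundary."""
        base = ts_frame(np.arange(30.0), y=np.arange(30.0) * 2,
                        x=np.arange(30.0))
        out = make_lag_features(base, [1, 3], "x")
        mutated = base.copy()
        mutated.iloc[20:] += 999.0
        out_m = make_lag_features(mutated, [1, 3], "x")
        feat_cols = [c for c in out.columns if c != "target"]
        # rows whose lags reach only pre-mutation data (t < 20) are identical
        pd.testing.assert_frame_equal(out[feat_cols].iloc[:17],
                                      out_m[feat_cols].iloc[:17])


class TestAlignmentAndOutliers:
    def test_daily_resample_forward_fills_sparse_series(self):
        idx = pd.to_datetime(["2024-01-01", "2024-01-04"])
        df = pd.DataFrame({"x": [1.0, 4.0]}, index=idx)
        out = resample_daily(df)
        np.testing.assert_allclose(out["x"], [1.0, 1.0, 1.0, 4.0])

    def test_tukey_fence_actions(self):
        df = ts_frame([1.0, 2, 3, 2, 1, 2, 3, 2, 100.0])
        dropped, flags = handle_outliers(df, "drop")
        assert flags["x"].iloc[-1] and len(dropped) == len(df) - 1
        wins, _ = handle_outliers(df, "winsorize")
        assert wins["x"].iloc[-1] < 100.0
        kept, _ = handle_outliers(df, "keep")
        assert kept["x"].iloc[-1] == 100.0
        with pytest.raises(ValueError):
            handle_outliers(df, "delete")


class TestCsvDialect:
    def test_round_trip(self, tmp_path):
        df = ts_frame(np.array([1.5, np.nan, 3.0]))
        path = tmp_path / "t.csv"
        write_timeseries_csv(df, path)
        back = read_timeseries_csv(path)
        assert isinstance(back.index, pd.DatetimeIndex)
        np.testing.assert_allclose(back["x"], df["x"])


def test_split_spec_normalizes_ratios():
    spec = SplitSpec(ratios=(7, 2, 1))
    assert sum(spec.ratios) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        SplitSpec(ratios=(1, 0, 0))
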