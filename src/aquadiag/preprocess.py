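"""Data hygiene and leakage-safe featurization for water-quality tables.

Conventions: tables are pandas DataFrames indexed by timestamp (first CSV
column, ISO-8601), numeric parameter columns, missing values as empty
cells / NaN.  Scalers and imputers follow the fit-on-train contract: fit
statistics on the training block only, then apply unchanged to
validation and test data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MeanImputer",
    "RobustScaler",
    "ZScoreScaler",
    "SplitSpec",
    "impute_mean",
    "robust_standardize",
    "zscore_standardize",
    "chronological_split",
    "make_lag_features",
    "resample_daily",
    "handle_outliers",
    "read_timeseries_csv",
    "write_timeseries_csv",
]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    if isinstance(X, pd.Series):
        return X.to_frame()
    return pd.DataFrame(np.asarray(X, dtype=float))


def impute_mean(column):
    """Replace missing entries by the mean of the observed entries.

    Accepts a vector or a DataFrame (column-wise).  An all-missing column
    is an error naming the column.
    """
    X = _as_frame(column)
    out = X.copy()
    for c in X.columns:
        col = X[c].astype(float)
        if col.isna().all():
            raise ValueError(f"column {c!r} has no observed values to impute from")
        out[c] = col.fillna(col.mean())
    if isinstance(column, pd.DataFrame):
        return out
    if isinstance(column, pd.Series):
        return out.iloc[:, 0]
    return out.iloc[:, 0].to_numpy() if np.ndim(column) == 1 else out.to_numpy()


class MeanImputer:
    """Train-fitted mean imputation (means computed on the training block)."""

    def __init__(self):
        self.means_: pd.Series | None = None

    def fit(self, X: pd.DataFrame) -> "MeanImputer":
        X = _as_frame(X)
        bad = [c for c in X.columns if X[c].isna().all()]
        if bad:
            raise ValueError(f"columns {bad} have no observed values to impute from")
        self.means_ = X.mean()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.means_ is None:
            raise RuntimeError("imputer is not fitted")
        return _as_frame(X).fillna(self.means_)

    def fit_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).transform(X)


class RobustScaler:
    """Median/IQR standardization: ``(x - median) / IQR`` per column.

    Quantiles use linear interpolation between order statistics.  A
    zero-IQR (effectively constant) column is an error naming the column;
    constant columns must be dropped upstream.
    """

    def __init__(self):
        self.medians_: pd.Series | None = None
        self.iqrs_: pd.Series | None = None

    def fit(self, X) -> "RobustScaler":
        X = _as_frame(X)
        q1 = X.quantile(0.25, interpolation="linear")
        q3 = X.quantile(0.75, interpolation="linear")
        iqr = q3 - q1
        bad = [c for c in X.columns if not iqr[c] > 0]
        if bad:
            raise ValueError(f"zero interquartile range in columns {bad}")
        self.medians_ = X.median()
        self.iqrs_ = iqr
        return self

    def transform(self, X) -> pd.DataFrame:
        if self.medians_ is None:
            raise RuntimeError("scaler is not fitted")
        return (_as_frame(X) - self.medians_) / self.iqrs_

    def inverse_transform(self, X) -> pd.DataFrame:
        return _as_frame(X) * self.iqrs_ + self.medians_


class ZScoreScaler:
    """Mean-0 / SD-1 standardization (population SD, ``ddof=0``)."""

    def __init__(self):
        self.means_: pd.Series | None = None
        self.sds_: pd.Series | None = None

    def fit(self, X) -> "ZScoreScaler":
        X = _as_frame(X)
        sd = X.std(ddof=0)
        bad = [c for c in X.columns if not sd[c] > 0]
        if bad:
            raise ValueError(f"zero variance in columns {bad}")
        self.means_ = X.mean()
        self.sds_ = sd
        return self

    def transform(self, X) -> pd.DataFrame:
        if self.means_ is None:
            raise RuntimeError("scaler is not fitted")
        return (_as_frame(X) - self.means_) / self.sds_

    def inverse_transform(self, X) -> pd.DataFrame:
        return _as_frame(X) * self.sds_ + self.means_


def robust_standardize(X):
    """Fit-and-transform convenience; returns ``(scaled, fitted scaler)``."""
    scaler = RobustScaler().fit(X)
    return scaler.transform(X), scaler


def zscore_standardize(X):
    scaler = ZScoreScaler().fit(X)
    return scaler.transform(X), scaler


@dataclass(frozen=True)
class SplitSpec:
    """Chronological train/validation/test ratios (normalized to sum 1)."""

    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    chronological: bool = True

    def __post_init__(self):
        if len(self.ratios) != 3 or any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be three positive numbers")
        total = sum(self.ratios)
        object.__setattr__(self, "ratios", tuple(r / total for r in self.ratios))


def chronological_split(dataset: pd.DataFrame, spec: SplitSpec | None = None,
                        auto_sort: bool = False):
    """Split a timestamp-indexed table into contiguous time-ordered blocks.

    Block sizes are ``floor(r_train * n)`` / ``floor(r_valid * n)`` /
    remainder, so the default 7:2:1 on 1080 rows gives 756/216/108.
    Every training timestamp is strictly earlier than every test timestamp.
    """
    spec = spec or SplitSpec()
    n = len(dataset)
    if n < 10:
        raise ValueError(f"need at least 10 rows to honour the split ratio, got {n}")
    idx = dataset.index
    if not idx.is_monotonic_increasing:
        if auto_sort:
            dataset = dataset.sort_index()
        else:
            raise ValueError("dataset is not sorted by timestamp (pass auto_sort=True)")
    r_train, r_valid, _ = spec.ratios
    n_train = int(np.floor(r_train * n))
    n_valid = int(np.floor(r_valid * n))
    return (dataset.iloc[:n_train],
            dataset.iloc[n_train:n_train + n_valid],
            dataset.iloc[n_train + n_valid:])


def make_lag_features(series: pd.DataFrame, lags: list[int], target_column: str,
                      horizon: int = 1) -> pd.DataFrame:
    """Build a supervised table from lagged columns, leaking no future data.

    The row anchored at time ``t`` carries features ``x_c(t - lag)`` for
    every column ``c`` and ``lag >= 1``, and the target
    ``y(t + horizon - 1)``.  Rows whose lags reach before the series
    start are dropped.  Requesting lag 0 is rejected: with ``horizon=1``
    it would hand the model the value it is asked to predict.
    """
    series = _as_frame(series)
    if target_column not in series.columns:
        raise KeyError(f"target column {target_column!r} not in series")
    lags = sorted(set(int(l) for l in lags))
    if not lags:
        raise ValueError("need at least one lag")
    if lags[0] < 1:
        raise ValueError("lags must be >= 1 (lag 0 leaks the target)")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if max(lags) + horizon > len(series):
        raise ValueError("series too short for requested lags and horizon")
    cols = {}
    for c in series.columns:
        for lag in lags:
            cols[f"{c}_lag{lag}"] = series[c].shift(lag)
    out = pd.DataFrame(cols, index=series.index)
    out["target"] = series[target_column].shift(-(horizon - 1))
    return out.iloc[max(lags):len(series) - (horizon - 1)]


def resample_daily(df: pd.DataFrame) -> pd.DataFrame:
    """Align mixed-frequency parameter series onto a common daily grid.

    Forward-fills each column, matching how a sparsely sampled laboratory
    parameter (e.g. monthly total phosphorus) is carried between
    measurements.
    """
    return df.resample("D").mean().ffill()


def handle_outliers(df: pd.DataFrame, action: str = "drop", k: float = 1.5):
    """Tukey-fence screening: flag entries beyond ``[Q1 - k*IQR, Q3 + k*IQR]``.

    ``action``: ``"drop"`` removes rows containing any flagged entry,
    ``"winsorize"`` clips flagged entries to the fence, ``"keep"`` only
    reports.  Returns ``(table, flags)`` with a boolean flag frame.
    """
    if action not in ("drop", "winsorize", "keep"):
        raise ValueError(f"unknown outlier action {action!r}")
    df = _as_frame(df)
    q1, q3 = df.quantile(0.25), df.quantile(0.75)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    flags = (df < lo) | (df > hi)
    if action == "drop":
        return df.loc[~flags.any(axis=1)], flags
    if action == "winsorize":
        return df.clip(lower=lo, upper=hi, axis=1), flags
    return df, flags


def read_timeseries_csv(path) -> pd.DataFrame:
    """Read the package CSV dialect: first column ISO-8601 timestamp index."""
    return pd.read_csv(path, index_col=0, parse_dates=True)


def write_timeseries_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="timestamp")
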