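"""Error metrics and the robustness ratios used by the evaluation suite."""
from __future__ import annotations

import numpy as np

__all__ = [
    "rmse", "mae", "r2",
    "outlier_sensitivity", "noise_resistance", "overfitting_tendency",
]


def _pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0 or y.size != yhat.size:
        raise ValueError(f"length mismatch or empty input: {y.size} vs {yhat.size}")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean squared error ``sqrt(sum((y - yhat)^2) / n)``."""
    y, yhat = _pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(y, yhat) -> float:
    y, yhat = _pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def r2(y, yhat) -> float:
    """Coefficient of determination; errors on a constant target with
    imperfect predictions, where R^2 is undefined."""
    y, yhat = _pair(y, yhat)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        if ss_res == 0.0:
            return 1.0
        raise ValueError("R^2 undefined: constant target with imperfect predictions")
    return 1.0 - ss_res / ss_tot


def outlier_sensitivity(rmse_clean: float, rmse_outlier: float) -> float:
    """Relative RMSE degradation when training data carries injected outliers."""
    if rmse_clean <= 0:
        raise ValueError("rmse_clean must be positive")
    return (rmse_outlier - rmse_clean) / rmse_clean


def noise_resistance(rmse_clean: float, rmse_noise: float) -> float:
    """1 minus the relative RMSE degradation under injected noise, floored at 0."""
    if rmse_clean <= 0:
        raise ValueError("rmse_clean must be positive")
    return max(0.0, 1.0 - (rmse_noise - rmse_clean) / rmse_clean)


def overfitting_tendency(rmse_train: float, rmse_test: float) -> float:
    """Train/test RMSE gap as a fraction of test RMSE, floored at 0."""
    if rmse_test <= 0:
        raise ValueError("rmse_test must be positive")
    return max(0.0, (rmse_test - rmse_train) / rmse_test)
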