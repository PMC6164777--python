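"""Forecast evaluation: error metrics, AQI class accuracy, the
Diebold–Mariano test, the improvement rate, and correlation.

Error metrics are the usual SSE / MAE / MAPE / RMSE over the evaluation
window.  The mean mode accuracy (MMA) scores a forecast by health-warning
class rather than by magnitude: it is the fraction of days on which the
forecast falls in the same AQI class as the observation, using the six-class
national breakpoint scheme on half-open intervals.  The Diebold–Mariano test
compares two forecasts under squared loss via the mean loss differential and
its long-run variance; one-sided, with a negative statistic favouring the
target model.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .io import AQIClassScheme, CHINA_AQI_SCHEME, DMResult, MetricsReport

__all__ = [
    "error_metrics",
    "aqi_class",
    "mma",
    "dm_test",
    "improvement_rate",
    "correlation",
    "metrics_report",
]


def _aligned(actual: np.ndarray, forecast: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(actual, dtype=float)
    f = np.asarray(forecast, dtype=float)
    if x.shape != f.shape or x.ndim != 1:
        raise ValueError("actual and forecast must be 1-D and equal length")
    return x, f


def error_metrics(
    actual: np.ndarray, forecast: np.ndarray
) -> tuple[float, float, float, float]:
    """Return ``(SSE, MAE, MAPE, RMSE)``; ``RMSE = sqrt(SSE / N)``.

    MAPE divides by the actuals, so any zero actual is an error.
    """
    x, f = _aligned(actual, forecast)
    if np.any(x == 0):
        raise ValueError("MAPE undefined: actual contains zeros")
    err = x - f
    sse = float(np.sum(err**2))
    mae = float(np.mean(np.abs(err)))
    mape = float(np.mean(np.abs(err) / np.abs(x)))
    rmse = float(np.sqrt(sse / x.size))
    return sse, mae, mape, rmse


def aqi_class(
    value: float | np.ndarray, scheme: AQIClassScheme = CHINA_AQI_SCHEME
) -> int | np.ndarray:
    """Class index 1..6 of a positive AQI value (forecasts included: real
    values are classified on the same intervals)."""
    return scheme.classify(value)


def mma(
    actual: np.ndarray,
    forecast: np.ndarray,
    scheme: AQIClassScheme = CHINA_AQI_SCHEME,
) -> float:
    """Mean mode accuracy: fraction of time points whose forecast class
    matches the observed class."""
    x, f = _aligned(actual, forecast)
    return float(np.mean(scheme.classify(x) == scheme.classify(f)))


def dm_test(
    actual: np.ndarray,
    forecast_a: np.ndarray,
    forecast_b: np.ndarray,
    lag_truncation: int = 0,
) -> DMResult:
    """Diebold–Mariano test of equal predictive accuracy under squared loss.

    The loss differential is ``g_t = (x_t - x_At)^2 - (x_t - x_Bt)^2``; its
    long-run variance is estimated as ``gamma_0 + 2 * sum_{k<=lag} gamma_k``
    from sample autocovariances (truncation lag 0 — the plain variance — is
    the default for one-step forecasts, with no small-sample correction).
    The p-value is the lower tail of the standard normal: small p means the
    target model A beats the benchmark B.
    """
    x, fa = _aligned(actual, forecast_a)
    _, fb = _aligned(actual, forecast_b)
    n = x.size
    if n < 10:
        raise ValueError("DM test needs at least 10 observations")
    g = (x - fa) ** 2 - (x - fb) ** 2
    if np.ptp(g) == 0.0:
        raise ValueError(
            "degenerate loss differential (constant g_t): zero variance"
        )
    g_bar = float(np.mean(g))
    dev = g - g_bar
    v = float(np.mean(dev**2))  # gamma_0
    for k in range(1, lag_truncation + 1):
        gamma_k = float(np.mean(dev[k:] * dev[:-k]))
        v += 2.0 * gamma_k
    if v <= 0:
        raise ValueError("degenerate long-run variance (V_hat <= 0)")
    statistic = g_bar / np.sqrt(v / n)
    p = float(stats.norm.cdf(statistic))
    return DMResult(
        statistic=float(statistic),
        p_value=p,
        lag_truncation=lag_truncation,
        n_obs=n,
        mean_loss_diff=g_bar,
    )


def improvement_rate(rmse_proposed: float, rmse_benchmark: float) -> float:
    """Relative RMSE reduction of the proposed model over a benchmark:
    ``(RMSE_benchmark - RMSE_proposed) / RMSE_benchmark``; positive means
    the proposed model improves."""
    if rmse_proposed <= 0 or rmse_benchmark <= 0:
        raise ValueError("RMSE values must be positive")
    return (rmse_benchmark - rmse_proposed) / rmse_benchmark


def correlation(actual: np.ndarray, forecast: np.ndarray) -> float:
    """Pearson product-moment correlation between the series."""
    x, f = _aligned(actual, forecast)
    if np.std(x) == 0 or np.std(f) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(x, f).statistic)


def metrics_report(
    actual: np.ndarray,
    forecast: np.ndarray,
    scheme: AQIClassScheme | None = CHINA_AQI_SCHEME,
) -> MetricsReport:
    """All scalar metrics for one forecast in a single report.

    MMA requires positive actuals *and* forecasts; correlation requires
    non-constant series.  Either is reported as ``None`` when undefined.
    """
    x, f = _aligned(actual, forecast)
    sse, mae, mape, rmse = error_metrics(x, f)
    mma_val = None
    if scheme is not None and np.all(x > 0) and np.all(f > 0):
        mma_val = mma(x, f, scheme)
    r_val = None
    if np.std(x) > 0 and np.std(f) > 0:
        r_val = correlation(x, f)
    return MetricsReport(
        sse=sse, mae=mae, mape=mape, rmse=rmse, mma=mma_val, r=r_val, n_obs=x.size
    )
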