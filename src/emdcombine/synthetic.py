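"""Synthetic AQI-like series and controlled forecast panels.

Daily air-quality-index records mix a slow level/trend, annual and weekly
seasonal oscillations, and autocorrelated high-frequency noise, all bounded
below by a small positive floor.  :func:`gen_series` emulates exactly that
structure — trend + sinusoidal seasonals with seeded phases + AR(1) noise —
so every stage of the decomposition-forecast-combination pipeline can be
exercised offline with known ground truth.  :func:`gen_panel` builds
forecast panels whose error distributions (variances, cross-correlations)
are chosen by the caller, which is what the combination-weight recovery and
test-calibration checks need.

All generators are pure functions of their spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ForecastPanel, SeriesSample

__all__ = ["SynthSpec", "gen_series", "gen_panel"]


@dataclass
class SynthSpec:
    """Recipe for an AQI-like series.

    Defaults give ~2.5 years of daily data on the realistic urban AQI range
    (roughly 20–280): level 100 with a slight improving trend, an annual
    cycle of amplitude 40, a weekly cycle of amplitude 6, and AR(1) noise
    (coefficient 0.5, innovation scale 10).  The AR(1) fast component — not
    white noise — gives the decomposition several meaningful high-frequency
    modes.
    """

    n: int = 896
    level: float = 100.0
    slope: float = -0.01
    seasonal: list[tuple[float, float]] = field(
        default_factory=lambda: [(365.25, 40.0), (7.0, 6.0)]
    )  # (period, amplitude) pairs
    ar_coef: float = 0.5
    innovation_scale: float = 10.0
    floor: float = 1.0
    seed: int = 0


def gen_series(spec: SynthSpec) -> SeriesSample:
    """Generate ``value_t = level + slope*t + sum_j amp_j sin(2πt/P_j + φ_j)
    + AR(1) noise``, clipped at the floor; phases are drawn from the seed."""
    if spec.n < 64:
        raise ValueError("need n >= 64")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n, dtype=float)
    values = spec.level + spec.slope * t
    for period, amp in spec.seasonal:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        values = values + amp * np.sin(2.0 * np.pi * t / period + phase)
    if spec.innovation_scale > 0:
        phi = spec.ar_coef
        innov = rng.normal(0.0, spec.innovation_scale, size=spec.n)
        noise = np.empty(spec.n)
        noise[0] = innov[0] / np.sqrt(max(1.0 - phi**2, 1e-12))
        for i in range(1, spec.n):
            noise[i] = phi * noise[i - 1] + innov[i]
        values = values + noise
    clipped = values < spec.floor
    if clipped.all():
        raise ValueError("spec produces an all-clipped (constant-floor) series")
    values = np.maximum(values, spec.floor)
    return SeriesSample(times=np.arange(spec.n), values=values, name="synthetic_aqi")


def gen_panel(
    n: int,
    m: int,
    error_sds: np.ndarray | float = 0.1,
    error_corr: np.ndarray | None = None,
    truth: np.ndarray | None = None,
    seed: int = 0,
    model_labels: list[str] | None = None,
) -> ForecastPanel:
    """Ground-truth series plus ``m`` forecast columns with controlled errors.

    Errors are jointly Gaussian with per-model standard deviations
    ``error_sds`` and cross-correlation matrix ``error_corr`` (identity by
    default); forecasts are ``truth - error`` so the panel's error matrix
    reproduces the draws exactly.  The default truth is a smooth positive
    unit-scale series (level 1 with a mild oscillation), suitable for
    relative-error scales like the 10% default.
    """
    if m < 1:
        raise ValueError("need m >= 1 models")
    rng = np.random.default_rng(seed)
    if truth is None:
        t = np.arange(n, dtype=float)
        truth = 1.0 + 0.2 * np.sin(2.0 * np.pi * t / 50.0)
    truth = np.asarray(truth, dtype=float)
    if truth.size != n:
        raise ValueError("truth length must equal n")

    sds = np.broadcast_to(np.asarray(error_sds, dtype=float), (m,)).copy()
    corr = np.eye(m) if error_corr is None else np.asarray(error_corr, dtype=float)
    if corr.shape != (m, m) or not np.allclose(corr, corr.T):
        raise ValueError("error_corr must be a symmetric (m, m) matrix")
    cov = corr * np.outer(sds, sds)
    # Cholesky with a graceful path for singular but PSD matrices (rho = ±1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals.min() < -1e-10 * max(eigvals.max(), 1.0):
        raise ValueError("infeasible (non-PSD) error correlation matrix")
    root = eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0.0, None)))
    errors = rng.standard_normal((n, m)) @ root.T
    return ForecastPanel(
        actual=truth,
        forecasts=truth[:, None] - errors,
        model_labels=model_labels or [f"model{i + 1}" for i in range(m)],
    )
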