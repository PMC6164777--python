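"""One-step-ahead forecasters applied to each IMF and the residue.

Three individual models are provided:

* **ES** — simple exponential smoothing, ``x̂_{t+1} = α x_t + (1-α) x̂_t``,
  with the smoothing parameter picked by in-sample one-step SSE over a grid.
* **GRNN** — general regression neural network: a Gaussian-kernel weighted
  average (Nadaraya–Watson regression) of training targets over a lag
  embedding of the series, with the bandwidth chosen by leave-one-out SSE.
* **NARNN** — nonlinear autoregressive network: a single-hidden-layer
  feedforward map (tanh hidden units, linear output) from ``d`` lagged values
  to the next value, trained by L-BFGS with early stopping on a chronological
  tail validation split.

All three are strictly causal: the forecast at time ``t`` uses only values
before ``t``, and forecasts over a held-out window are open loop (true lags
fed in).  GRNN and NARNN inputs are standardized with training-window
statistics because kernel bandwidths and network training are
scale-sensitive; predictions are mapped back to the original scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "ESModel",
    "GRNNModel",
    "NARNNModel",
    "es_forecast",
    "es_select_alpha",
    "grnn_fit",
    "grnn_predict",
    "grnn_forecast",
    "narnn_fit",
    "narnn_forecast",
    "narnn_fit_forecast",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_SIGMA_GRID",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)
DEFAULT_SIGMA_GRID = np.array([0.05, 0.1, 0.2, 0.3, 0.5, 0.8, 1.2, 2.0, 3.0, 5.0])


# ---------------------------------------------------------------------------
# exponential smoothing


@dataclass
class ESModel:
    """Simple exponential smoothing with smoothing parameter ``alpha`` in
    (0, 1] and initial forecast ``x̂_1`` (defaults to the first observation)."""

    alpha: float
    initial_forecast: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")


def es_forecast(series: np.ndarray, model: ESModel) -> np.ndarray:
    """Recursive one-step forecasts ``x̂_2 .. x̂_{N+1}`` (length N).

    ``out[k]`` is the forecast of the observation at 0-based position
    ``k + 1``; the last element forecasts one step beyond the series end.
    With ``alpha = 1`` this reduces exactly to the naive forecast
    ``x̂_{t+1} = x_t``.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be nonempty")
    a = model.alpha
    prev = x[0] if model.initial_forecast is None else float(model.initial_forecast)
    out = np.empty(x.size, dtype=float)
    for t in range(x.size):
        prev = a * x[t] + (1.0 - a) * prev
        out[t] = prev
    return out


def es_select_alpha(
    train: np.ndarray, grid: np.ndarray | None = None
) -> ESModel:
    """Pick ``alpha`` minimizing in-sample one-step SSE; ties go to the
    smallest grid value.  Stable series favour small alpha, random walks
    large alpha."""
    x = np.asarray(train, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 training points to select alpha")
    grid = DEFAULT_ALPHA_GRID if grid is None else np.asarray(grid, dtype=float)
    sses = np.empty(grid.size)
    for i, a in enumerate(grid):
        fc = es_forecast(x, ESModel(alpha=float(a)))
        sses[i] = np.sum((x[1:] - fc[:-1]) ** 2)
    return ESModel(alpha=float(grid[int(np.argmin(sses))]))


# ---------------------------------------------------------------------------
# general regression neural network


@dataclass
class GRNNModel:
    """Gaussian-kernel regression over a lag embedding.

    ``patterns`` holds the standardized lag vectors, ``targets`` the
    standardized next-step values; ``sigma`` is the kernel bandwidth on the
    standardized scale.
    """

    patterns: np.ndarray  # (n, lag), standardized
    targets: np.ndarray  # (n,), standardized
    sigma: float
    lag: int
    x_mean: float
    x_std: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.patterns.shape[0] != self.targets.shape[0]:
            raise ValueError("patterns and targets must have equal count")


def _embed(z: np.ndarray, lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Lag embedding: rows ``(z_{t-lag}, ..., z_{t-1})`` with target ``z_t``."""
    n = z.size - lag
    X = np.lib.stride_tricks.sliding_window_view(z, lag)[:n]
    y = z[lag:]
    return np.ascontiguousarray(X, dtype=float), np.asarray(y, dtype=float)


def _kernel_weights(sq_dists: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian pattern-layer activations, shifted by the minimum squared
    distance so that the nearest pattern always keeps weight 1.  The shift
    cancels in the normalized output and realizes the nearest-neighbour
    limit as sigma -> 0 instead of a total underflow."""
    shifted = sq_dists - sq_dists.min(axis=-1, keepdims=True)
    return np.exp(-shifted / (2.0 * sigma**2))


def grnn_predict(
    model: GRNNModel, query: np.ndarray, printed_ratio: bool = False
) -> float | np.ndarray:
    """Kernel-weighted mean of training targets for one or many queries.

    The output is the weighted summation over the simple summation,
    ``S_w / S_s`` — a convex combination of the targets.  The transposed
    ratio ``S_s / S_w`` is available via ``printed_ratio`` for comparison
    only.  Queries are given on the original data scale.
    """
    q = np.atleast_2d(np.asarray(query, dtype=float))
    if q.shape[1] != model.lag:
        raise ValueError(f"query dimension must equal lag={model.lag}")
    qz = (q - model.x_mean) / model.x_std
    d2 = ((qz[:, None, :] - model.patterns[None, :, :]) ** 2).sum(axis=2)
    p = _kernel_weights(d2, model.sigma)
    s_s = p.sum(axis=1)
    s_w = p @ model.targets
    dead = ~np.isfinite(s_s) | (s_s == 0)
    if np.any(dead):
        logger.warning("kernel weights degenerate; using nearest pattern target")
        nearest = model.targets[np.argmin(d2, axis=1)]
        s_s = np.where(dead, 1.0, s_s)
        s_w = np.where(dead, nearest, s_w)
    out_z = s_s / s_w if printed_ratio else s_w / s_s
    out = model.x_mean + model.x_std * out_z
    return float(out[0]) if np.asarray(query).ndim == 1 else out


def grnn_fit(
    train: np.ndarray,
    lag: int = 5,
    sigma_grid: np.ndarray | None = None,
) -> GRNNModel:
    """Build the embedding and choose sigma by leave-one-out one-step SSE.

    A constant training series yields a degenerate (zero-variance) embedding
    whose predictions are exactly the constant.
    """
    x = np.asarray(train, dtype=float)
    if x.size <= lag + 2:
        raise ValueError(f"need more than lag + 2 = {lag + 2} training points")
    sigma_grid = DEFAULT_SIGMA_GRID if sigma_grid is None else np.asarray(
        sigma_grid, dtype=float
    )
    mean = float(np.mean(x))
    std = float(np.std(x))
    if std == 0.0:
        std = 1.0  # constant series: z is all zeros, prediction = mean
    z = (x - mean) / std
    X, y = _embed(z, lag)

    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)  # leave-one-out: a pattern never votes for itself
    best_sigma, best_sse = float(sigma_grid[0]), np.inf
    for s in sigma_grid:
        p = _kernel_weights(d2, float(s))
        pred = (p @ y) / p.sum(axis=1)
        sse = float(np.sum((pred - y) ** 2))
        if sse < best_sse - 1e-15:
            best_sigma, best_sse = float(s), sse
    return GRNNModel(
        patterns=X, targets=y, sigma=best_sigma, lag=lag, x_mean=mean, x_std=std
    )


def grnn_forecast(model: GRNNModel, series: np.ndarray) -> np.ndarray:
    """Open-loop one-step forecasts at positions ``lag .. N-1`` of ``series``
    (true lagged values fed in); length ``N - lag``."""
    x = np.asarray(series, dtype=float)
    queries = np.lib.stride_tricks.sliding_window_view(x, model.lag)[
        : x.size - model.lag
    ]
    return np.asarray(grnn_predict(model, np.ascontiguousarray(queries)))


# ---------------------------------------------------------------------------
# nonlinear autoregressive neural network


@dataclass
class NARNNModel:
    """Single-hidden-layer autoregressive network ``y_t = f(y_{t-1..t-d})``
    with tanh hidden units and a linear output."""

    d: int
    hidden_units: int
    W1: np.ndarray  # (hidden, d)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    x_mean: float
    x_std: float
    seed: int = 0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("delay d must be >= 1")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")


def _narnn_unpack(theta: np.ndarray, d: int, h: int):
    i = 0
    W1 = theta[i : i + h * d].reshape(h, d)
    i += h * d
    b1 = theta[i : i + h]
    i += h
    w2 = theta[i : i + h]
    i += h
    b2 = theta[i]
    return W1, b1, w2, b2


def _narnn_loss_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray, d: int, h: int,
                     ridge: float = 1e-6) -> tuple[float, np.ndarray]:
    W1, b1, w2, b2 = _narnn_unpack(theta, d, h)
    H = np.tanh(X @ W1.T + b1)  # (n, h)
    pred = H @ w2 + b2
    resid = pred - y
    n = y.size
    loss = float(np.mean(resid**2) + ridge * np.sum(theta**2))
    dpred = 2.0 * resid / n
    g_w2 = H.T @ dpred
    g_b2 = float(dpred.sum())
    dH = np.outer(dpred, w2) * (1.0 - H**2)
    g_W1 = dH.T @ X
    g_b1 = dH.sum(axis=0)
    grad = np.concatenate([g_W1.ravel(), g_b1, g_w2, [g_b2]]) + 2.0 * ridge * theta
    return loss, grad


def narnn_fit(
    train: np.ndarray,
    d: int = 5,
    hidden_units: int = 10,
    seed: int = 0,
    max_iter: int = 300,
    val_frac: float = 0.15,
) -> NARNNModel:
    """Train the network on the lag embedding of ``train``.

    The embedding rows are split chronologically: the head trains the
    weights (L-BFGS on mean squared error with a tiny ridge term for
    conditioning), the final ``val_frac`` validates; the parameters kept are
    those with the lowest validation error along the optimization path
    (early stopping).  Fully deterministic given ``seed``.
    """
    if d < 1:
        raise ValueError("delay d must be >= 1")
    x = np.asarray(train, dtype=float)
    if x.size <= d + hidden_units:
        raise ValueError(
            f"need more than d + hidden = {d + hidden_units} training points"
        )
    mean = float(np.mean(x))
    std = float(np.std(x))
    if std == 0.0:
        std = 1.0
    z = (x - mean) / std
    X, y = _embed(z, d)
    n_val = max(1, int(round(val_frac * X.shape[0])))
    X_fit, y_fit = X[:-n_val], y[:-n_val]
    X_val, y_val = X[-n_val:], y[-n_val:]

    rng = np.random.default_rng(seed)
    h = hidden_units
    theta0 = np.concatenate([
        rng.normal(0.0, 1.0 / np.sqrt(d), h * d),
        np.zeros(h),
        rng.normal(0.0, 1.0 / np.sqrt(h), h),
        [0.0],
    ])

    best = {"theta": theta0.copy(), "val": np.inf, "iters": 0}

    def track(theta: np.ndarray) -> None:
        W1, b1, w2, b2 = _narnn_unpack(theta, d, h)
        v = float(np.mean((np.tanh(X_val @ W1.T + b1) @ w2 + b2 - y_val) ** 2))
        best["iters"] += 1
        if v < best["val"]:
            best["val"] = v
            best["theta"] = theta.copy()

    track(theta0)
    res = minimize(
        _narnn_loss_grad,
        theta0,
        args=(X_fit, y_fit, d, h),
        jac=True,
        method="L-BFGS-B",
        callback=track,
        options={"maxiter": max_iter},
    )
    if not np.isfinite(res.fun):
        raise FloatingPointError("NARNN training diverged (non-finite loss)")
    W1, b1, w2, b2 = _narnn_unpack(best["theta"], d, h)
    train_loss, _ = _narnn_loss_grad(best["theta"], X_fit, y_fit, d, h, ridge=0.0)
    return NARNNModel(
        d=d,
        hidden_units=h,
        W1=W1,
        b1=b1,
        w2=w2,
        b2=float(b2),
        x_mean=mean,
        x_std=std,
        seed=seed,
        diagnostics={
            "train_mse": train_loss,
            "val_mse": best["val"],
            "n_iterations": best["iters"],
            "optimizer_status": int(res.status),
        },
    )


def narnn_forecast(model: NARNNModel, series: np.ndarray) -> np.ndarray:
    """Open-loop one-step forecasts at positions ``d .. N-1``; length
    ``N - d``."""
    x = np.asarray(series, dtype=float)
    z = (x - model.x_mean) / model.x_std
    X = np.lib.stride_tricks.sliding_window_view(z, model.d)[: z.size - model.d]
    pred_z = np.tanh(X @ model.W1.T + model.b1) @ model.w2 + model.b2
    return model.x_mean + model.x_std * pred_z


def narnn_fit_forecast(
    train: np.ndarray,
    test: np.ndarray | None = None,
    d: int = 5,
    hidden_units: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[NARNNModel, np.ndarray]:
    """Fit on ``train`` and return open-loop one-step forecasts over the
    concatenated train + test window (positions ``d`` onward)."""
    model = narnn_fit(train, d=d, hidden_units=hidden_units, seed=seed, **fit_kwargs)
    full = (
        np.asarray(train, float)
        if test is None
        else np.concatenate([np.asarray(train, float), np.asarray(test, float)])
    )
    return model, narnn_forecast(model, full)
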