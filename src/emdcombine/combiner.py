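"""Forecast combination: equal weights, fixed optimal weights, and the
induced-ordered-weighted-averaging (IOWA) optimal combination.

The fixed-weight combined forecasting model chooses one convex weight vector
``w`` per model by minimizing the combination's sum of squared errors

    min_w  sum_t (sum_i w_i e_it)^2   s.t.  sum_i w_i = 1,  w_i >= 0,

a small convex quadratic program over the probability simplex.  The IOWA
variant first rearranges, at every time point, the model forecasts by their
realized forecasting accuracy and then solves the same program on the
rank-ordered error columns, so the weights attach to accuracy ranks rather
than to models.  Because the accuracy index at a fixed time is a decreasing
function of the absolute error alone, the rank ordering extends naturally to
series that are not strictly positive (IMFs oscillate around zero) by
sorting on ascending absolute error.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import minimize

from .io import CombWeights, ForecastPanel

__all__ = [
    "sam_combine",
    "accuracy_index",
    "iowa_reorder",
    "optimal_weights_fixed",
    "optimal_weights_iowa",
    "combine",
    "solve_simplex_qp",
    "grid_search_simplex",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# elementary combinations


def sam_combine(panel: ForecastPanel) -> np.ndarray:
    """Simple arithmetic mean: equal weight 1/m for every model."""
    if panel.n_models < 1:
        raise ValueError("need at least one model")
    return panel.forecasts.mean(axis=1)


def accuracy_index(actual: np.ndarray, forecast: np.ndarray) -> np.ndarray:
    """Relative forecasting accuracy ``a_t = 1 - |x_t - x̂_t| / x_t``,
    clipped to 0 whenever the relative error reaches 1.  Defined only for
    strictly positive actuals."""
    x = np.asarray(actual, dtype=float)
    f = np.asarray(forecast, dtype=float)
    if np.any(x <= 0):
        raise ValueError("accuracy index requires strictly positive actuals")
    rel = np.abs(x - f) / x
    return np.where(rel < 1.0, 1.0 - rel, 0.0)


def _ordering_keys(panel: ForecastPanel) -> np.ndarray:
    """Per-time sort keys: ascending key = best model first.

    Uses ``-accuracy`` when all actuals are positive (the accuracy-index
    ordering, ties within the zero-accuracy group by model index), otherwise
    ascending absolute error — the same ordering wherever both exist.
    """
    if np.all(panel.actual > 0):
        return -panel.accuracies
    return np.abs(panel.errors)


def iowa_reorder(
    panel: ForecastPanel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rearrange forecast columns at each time point by descending accuracy.

    Returns ``(forecasts_ordered, errors_ordered, permutation)`` where column
    ``j`` of the ordered arrays holds, for every ``t``, the rank-``j+1``
    (j-th most accurate) model's value, and ``permutation[t, j]`` is the
    original model index occupying that rank.  Ties are broken by ascending
    model index (stable sort).
    """
    keys = _ordering_keys(panel)
    perm = np.argsort(keys, axis=1, kind="stable")
    rows = np.arange(panel.n_obs)[:, None]
    return panel.forecasts[rows, perm], panel.errors[rows, perm], perm


# ---------------------------------------------------------------------------
# the simplex-constrained quadratic program


def _active_set_qp(Q: np.ndarray, max_cycles: int = 200) -> np.ndarray | None:
    """Exact minimizer of ``w' Q w`` on the simplex via an active-set method.

    Free weights solve the equality-constrained KKT system; the most
    negative weight is fixed to zero until feasibility, then zero weights
    with negative reduced cost are released.  Returns ``None`` when cycling
    is detected (degenerate Q), signalling the caller to fall back.
    """
    m = Q.shape[0]
    free = np.ones(m, dtype=bool)
    tol = 1e-10
    for _ in range(max_cycles):
        f = np.flatnonzero(free)
        k = f.size
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = 2.0 * Q[np.ix_(f, f)]
        kkt[:k, k] = 1.0
        kkt[k, :k] = 1.0
        rhs = np.zeros(k + 1)
        rhs[k] = 1.0
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        w_f, lam = sol[:k], sol[k]
        if w_f.min() < -tol:
            free[f[np.argmin(w_f)]] = False
            if not free.any():
                return None
            continue
        w = np.zeros(m)
        w[f] = np.clip(w_f, 0.0, None)
        # reduced costs of the fixed (zero) weights
        g = 2.0 * Q @ w
        mu = g - lam
        fixed = np.flatnonzero(~free)
        if fixed.size and mu[fixed].min() < -1e-8:
            free[fixed[np.argmin(mu[fixed])]] = True
            continue
        return w
    return None


def solve_simplex_qp(errors: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimize ``sum_t (sum_i w_i e_it)^2`` over the simplex.

    ``errors`` has shape (N, m).  The active-set solution is polished against
    an SLSQP fallback whenever the active-set method stalls on a degenerate
    Gram matrix.  The returned weights satisfy the constraints exactly
    (clipped at 0, renormalized) and the achieved objective is reported.
    """
    E = np.asarray(errors, dtype=float)
    if not np.all(np.isfinite(E)):
        raise ValueError("errors must be finite")
    m = E.shape[1]
    Q = E.T @ E

    w = _active_set_qp(Q)
    if w is None:
        logger.warning("active-set QP stalled; falling back to SLSQP")
        res = minimize(
            lambda v: v @ Q @ v,
            np.full(m, 1.0 / m),
            jac=lambda v: 2.0 * Q @ v,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * m,
            constraints=[{"type": "eq", "fun": lambda v: v.sum() - 1.0}],
            options={"ftol": 1e-14, "maxiter": 500},
        )
        w = res.x
    w = np.clip(w, 0.0, None)
    w = w / w.sum()
    return w, float(w @ Q @ w)


def grid_search_simplex(
    errors: np.ndarray, step: float = 0.01
) -> tuple[np.ndarray, float]:
    """Brute-force minimization over the simplex lattice with the given step.

    Independent oracle for :func:`solve_simplex_qp`; practical for m <= 4.
    """
    E = np.asarray(errors, dtype=float)
    m = E.shape[1]
    n_steps = int(round(1.0 / step))

    def lattice(levels: int, dims: int):
        if dims == 1:
            yield (levels,)
            return
        for first in range(levels + 1):
            for rest in lattice(levels - first, dims - 1):
                yield (first, *rest)

    pts = np.array(list(lattice(n_steps, m)), dtype=float) * step
    obj = np.einsum("ki,ij,kj->k", pts, E.T @ E, pts)
    best = int(np.argmin(obj))
    return pts[best], float(obj[best])


def optimal_weights_fixed(panel: ForecastPanel) -> CombWeights:
    """Optimal fixed (model-attached) combination weights."""
    if panel.n_obs < panel.n_models:
        raise ValueError("need at least as many observations as models")
    w, obj = solve_simplex_qp(panel.errors)
    return CombWeights(weights=w, ordering="fixed", objective=obj)


def optimal_weights_iowa(panel: ForecastPanel) -> CombWeights:
    """Optimal weights on accuracy ranks: the same program as the fixed case
    but on the per-time accuracy-ordered error columns."""
    if panel.n_obs < panel.n_models:
        raise ValueError("need at least as many observations as models")
    _, errors_ordered, _ = iowa_reorder(panel)
    w, obj = solve_simplex_qp(errors_ordered)
    return CombWeights(weights=w, ordering="accuracy_ordered", objective=obj)


# ---------------------------------------------------------------------------
# applying weights


def combine(
    panel: ForecastPanel,
    weights: CombWeights,
    mode: str = "ex_post",
    model_order: np.ndarray | None = None,
) -> np.ndarray:
    """Apply combination weights to a panel.

    For ``fixed`` weights the mode is irrelevant: the combination is the
    weighted sum of model columns.  For accuracy-ordered weights:

    * ``ex_post`` rearranges the columns at each time point by the realized
      accuracies (requires actuals over the window) — this replicates the
      in-sample evaluation of the rank-weighted combination;
    * ``ex_ante`` applies one fixed model ordering at every time point
      (``model_order``, best model first, e.g. the mean training-window
      accuracy ranking), which is deployable without future actuals.
    """
    w = weights.weights
    if w.size != panel.n_models:
        raise ValueError("weight count must match the number of models")
    if weights.ordering == "fixed":
        return panel.forecasts @ w
    if mode == "ex_post":
        if not np.all(np.isfinite(panel.actual)):
            raise ValueError("ex_post combination requires realized actuals")
        ordered, _, _ = iowa_reorder(panel)
        return ordered @ w
    if mode == "ex_ante":
        if model_order is None:
            if not np.all(np.isfinite(panel.actual)):
                raise ValueError(
                    "ex_ante combination needs a model_order when actuals "
                    "are unavailable"
                )
            mean_acc = (
                panel.accuracies.mean(axis=0)
                if np.all(panel.actual > 0)
                else -np.abs(panel.errors).mean(axis=0)
            )
            model_order = np.argsort(-mean_acc, kind="stable")
        return panel.forecasts[:, np.asarray(model_order, int)] @ w
    raise ValueError(f"unknown mode {mode!r}")
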