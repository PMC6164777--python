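"""Empirical mode decomposition with the mirror endpoint condition.

The sifting procedure follows the classical Huang scheme: interpolate the
local maxima and minima with natural cubic splines, subtract the mean
envelope, and repeat until the candidate satisfies the two IMF conditions
(zero-crossing and extrema counts differ by at most one; the mean envelope is
negligible relative to the local amplitude).  Envelope splines are anchored
beyond both series ends by *mirrored* extrema: at the series start a boundary
minimum is added by reflecting the first interior minimum about the first
interior maximum (with the roles swapped when the first extremum is a
minimum), and symmetrically at the end.  This supplies boundary knots for the
splines and suppresses the end-effect divergence of the envelopes.

The ensemble variant (EEMD) decomposes ``NE`` white-noise-perturbed copies of
the signal and averages the k-th IMF across members, which cancels the added
noise at rate ``1/sqrt(NE)`` and alleviates mode mixing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .io import Decomposition, EnvelopePair, ExtremaSet, SeriesSample

__all__ = [
    "SiftConfig",
    "InsufficientExtremaError",
    "find_local_extrema",
    "mirror_extend",
    "clamp_extend",
    "envelope_mean",
    "zero_crossings",
    "is_imf",
    "sift_imf",
    "emd",
    "eemd",
]

logger = logging.getLogger(__name__)


class InsufficientExtremaError(ValueError):
    """Raised when a candidate has too few extrema to build envelopes — the
    operational signal that the remainder is a constant or trend residue."""


@dataclass
class SiftConfig:
    """Decomposition settings.

    Parameters
    ----------
    ensemble_size : int
        Number NE of noise-perturbed ensemble members (1 = plain EMD).
    noise_scale : float
        Standard deviation of the added white noise.  With
        ``noise_mode='relative'`` (default, the usual EEMD convention) the
        actual noise std is ``noise_scale * std(series)``; with
        ``'absolute'`` it is used as-is.
    max_sifts : int
        Hard cap on sifting iterations per IMF.
    s_number : int
        Consecutive sifts for which the IMF conditions must hold before the
        candidate is accepted; a candidate that already satisfies the
        conditions on entry is returned unsifted.
    envelope_tolerance : float
        Mean-envelope threshold as a fraction of the candidate's half
        peak-to-peak amplitude.
    extension : str
        Boundary rule for envelope knots: ``'mirror'`` (default) or
        ``'clamp'`` (series endpoints used as extrema — the naive baseline).
    """

    ensemble_size: int = 100
    noise_scale: float = 0.05
    noise_mode: str = "relative"  # "relative" | "absolute"
    max_sifts: int = 10
    s_number: int = 2
    envelope_tolerance: float = 0.05
    extension: str = "mirror"  # "mirror" | "clamp"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.max_sifts < 1:
            raise ValueError("max_sifts must be >= 1")
        if self.noise_mode not in ("relative", "absolute"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")
        if self.extension not in ("mirror", "clamp"):
            raise ValueError(f"unknown extension {self.extension!r}")


# ---------------------------------------------------------------------------
# extrema


def find_local_extrema(values: np.ndarray) -> ExtremaSet:
    """Interior strict local extrema; a plateau counts once, at its midpoint
    sample (left-biased for even runs)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples to define interior extrema")

    # compress runs of equal values; representative index = floor(mean(run))
    change = np.flatnonzero(np.diff(x) != 0.0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [n - 1]))
    reps = (starts + ends) // 2
    rv = x[starts]

    max_p, max_v, min_p, min_v = [], [], [], []
    for k in range(1, len(starts) - 1):
        left, mid, right = rv[k - 1], rv[k], rv[k + 1]
        if mid > left and mid > right:
            max_p.append(reps[k])
            max_v.append(mid)
        elif mid < left and mid < right:
            min_p.append(reps[k])
            min_v.append(mid)
    return ExtremaSet(
        np.array(max_p, dtype=float),
        np.array(max_v, dtype=float),
        np.array(min_p, dtype=float),
        np.array(min_v, dtype=float),
    )


def _merged(e: ExtremaSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All extrema merged in position order: (positions, values, is_max)."""
    pos = np.concatenate((e.max_positions, e.min_positions))
    val = np.concatenate((e.max_values, e.min_values))
    kind = np.concatenate((np.ones(e.n_max, bool), np.zeros(e.n_min, bool)))
    order = np.argsort(pos)
    return pos[order], val[order], kind[order]


def clamp_extend(values: np.ndarray, e: ExtremaSet) -> ExtremaSet:
    """Naive endpoint condition: both series endpoints join both extrema
    lists.  Kept as the baseline the mirror method is measured against."""
    if e.extended:
        return e
    x = np.asarray(values, dtype=float)
    n = x.size

    def pad(pos: np.ndarray, val: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p, v = list(pos), list(val)
        if not p or p[0] > 0:
            p.insert(0, 0.0)
            v.insert(0, x[0])
        if p[-1] < n - 1:
            p.append(float(n - 1))
            v.append(x[-1])
        return np.array(p), np.array(v)

    mp, mv = pad(e.max_positions, e.max_values)
    np_, nv = pad(e.min_positions, e.min_values)
    return ExtremaSet(mp, mv, np_, nv, extended=True)


def mirror_extend(values: np.ndarray, e: ExtremaSet) -> ExtremaSet:
    """Add one reflected extremum beyond each series end.

    At the start: if the first interior extremum is a maximum at position
    ``p_M`` followed by a minimum ``(p_m, v_m)``, prepend a minimum at
    ``2*p_M - p_m`` with value ``v_m`` (roles swap when the first extremum is
    a minimum).  The symmetric construction is applied at the end.  With
    fewer than one maximum or one minimum the clamped-endpoint extension is
    used instead, with a logged warning.  Idempotent: an already-extended set
    is returned unchanged.
    """
    if e.extended:
        return e
    if e.n_max < 1 or e.n_min < 1:
        logger.warning(
            "mirror extension needs at least one maximum and one minimum; "
            "falling back to endpoint-as-extremum extension"
        )
        return clamp_extend(values, e)

    pos, val, kind = _merged(e)
    if len(pos) < 2:
        return clamp_extend(values, e)

    max_p, max_v = list(e.max_positions), list(e.max_values)
    min_p, min_v = list(e.min_positions), list(e.min_values)

    # start: reflect the second extremum about the first
    p0 = 2 * pos[0] - pos[1]
    if kind[1]:  # second is a maximum -> prepend a maximum
        max_p.insert(0, p0)
        max_v.insert(0, val[1])
    else:
        min_p.insert(0, p0)
        min_v.insert(0, val[1])

    # end: reflect the second-to-last extremum about the last
    p1 = 2 * pos[-1] - pos[-2]
    if kind[-2]:
        max_p.append(p1)
        max_v.append(val[-2])
    else:
        min_p.append(p1)
        min_v.append(val[-2])

    return ExtremaSet(
        np.array(max_p), np.array(max_v), np.array(min_p), np.array(min_v),
        extended=True,
    )


def _extend(values: np.ndarray, e: ExtremaSet, extension: str) -> ExtremaSet:
    if extension == "mirror":
        return mirror_extend(values, e)
    return clamp_extend(values, e)


# ---------------------------------------------------------------------------
# envelopes and IMF conditions


def envelope_mean(values: np.ndarray, extended: ExtremaSet) -> EnvelopePair:
    """Natural-cubic-spline upper/lower envelopes through the extended
    extrema, evaluated at every original sample position."""
    x = np.asarray(values, dtype=float)
    if extended.n_max < 2 or extended.n_min < 2:
        raise InsufficientExtremaError(
            "need >= 2 maxima and >= 2 minima (after extension) for envelopes; "
            "remainder qualifies as residue"
        )
    t = np.arange(x.size, dtype=float)
    upper = CubicSpline(
        extended.max_positions, extended.max_values, bc_type="natural"
    )(t)
    lower = CubicSpline(
        extended.min_positions, extended.min_values, bc_type="natural"
    )(t)
    return EnvelopePair(upper=upper, lower=lower)


def zero_crossings(values: np.ndarray) -> int:
    """Count sign changes, ignoring exact zeros."""
    s = np.sign(np.asarray(values, dtype=float))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s) != 0))


def is_imf(
    values: np.ndarray,
    tolerance: float = 0.05,
    extension: str = "mirror",
    boundary_frac: float = 0.0,
) -> tuple[bool, dict]:
    """Test the two IMF conditions.

    Condition 1: the number of zero crossings and the number of extrema
    differ by at most one (counted on the interior ``1 - 2*boundary_frac``
    of samples when ``boundary_frac`` > 0).  Condition 2: the absolute mean
    envelope never exceeds ``tolerance`` times the half peak-to-peak
    amplitude.  Degenerate inputs simply return ``False``.
    """
    x = np.asarray(values, dtype=float)
    diag: dict = {}
    if x.size < 3 or np.ptp(x) == 0:
        return False, {"reason": "degenerate"}

    lo = int(math.floor(boundary_frac * x.size))
    hi = x.size - lo
    interior = x[lo:hi]
    try:
        ext_interior = find_local_extrema(interior)
    except ValueError:
        return False, {"reason": "too short"}
    n_ext = ext_interior.n_max + ext_interior.n_min
    n_zc = zero_crossings(interior)
    diag["n_extrema"] = n_ext
    diag["n_zero_crossings"] = n_zc
    count_ok = abs(n_zc - n_ext) <= 1 and n_ext >= 1

    try:
        full_ext = find_local_extrema(x)
        env = envelope_mean(x, _extend(x, full_ext, extension))
    except (ValueError, InsufficientExtremaError):
        return False, {**diag, "reason": "no envelopes"}
    amp = 0.5 * np.ptp(x)
    env_ratio = float(np.max(np.abs(env.mean)) / amp)
    diag["envelope_ratio"] = env_ratio
    envelope_ok = env_ratio <= tolerance
    diag["count_ok"] = count_ok
    diag["envelope_ok"] = envelope_ok
    return bool(count_ok and envelope_ok), diag


# ---------------------------------------------------------------------------
# sifting


def sift_imf(values: np.ndarray, cfg: SiftConfig) -> tuple[np.ndarray, np.ndarray]:
    """Extract one IMF by iterative mean-envelope subtraction.

    The loop checks the IMF conditions *before* each sift, so a candidate
    that already qualifies is returned untouched; otherwise it halts once the
    conditions have held for ``cfg.s_number`` consecutive checks, or at
    ``cfg.max_sifts`` with a logged warning.  ``imf + remainder`` equals the
    input to the last bit by construction.
    """
    x = np.asarray(values, dtype=float)
    h = x.copy()
    consec = cfg.s_number - 1  # an immediate pass needs no sifts
    converged = False
    for _ in range(cfg.max_sifts + 1):
        ok, _diag = is_imf(h, cfg.envelope_tolerance, cfg.extension)
        consec = consec + 1 if ok else 0
        if consec >= cfg.s_number:
            converged = True
            break
        ext = find_local_extrema(h)
        env = envelope_mean(h, _extend(h, ext, cfg.extension))
        h = h - env.mean
    if not converged:
        # hitting the cap is the routine exit path inside noisy ensemble
        # members, so this is not worth a stderr line per sift
        logger.debug("sift did not converge within %d sifts", cfg.max_sifts)
    return h, x - h


def emd(
    series: SeriesSample | np.ndarray, cfg: SiftConfig | None = None
) -> Decomposition:
    """Plain EMD: sift successive remainders until the remainder has fewer
    than two maxima or two minima (a constant or trend residue)."""
    cfg = cfg or SiftConfig(ensemble_size=1, noise_scale=0.0)
    x = series.values if isinstance(series, SeriesSample) else np.asarray(series, float)
    if x.size < 8:
        raise ValueError("series too short to decompose (need >= 8 samples)")
    max_imfs = int(np.log2(x.size)) + 1  # theoretical dyadic bound

    imfs: list[np.ndarray] = []
    r = x.astype(float).copy()
    while len(imfs) < max_imfs:
        try:
            ext = find_local_extrema(r)
        except ValueError:
            break
        if ext.n_max < 2 or ext.n_min < 2:
            break
        try:
            imf, r = sift_imf(r, cfg)
        except InsufficientExtremaError:
            break
        imfs.append(imf)
    return Decomposition(
        imfs=imfs,
        residue=r,
        ensemble_size=1,
        noise_scale=0.0,
        seed=cfg.seed,
    )


def eemd(
    series: SeriesSample | np.ndarray, cfg: SiftConfig | None = None
) -> Decomposition:
    """Ensemble EMD: average each IMF over ``NE`` noise-perturbed members.

    Member ``l`` draws its noise from an independent stream spawned from the
    master seed, so results are reproducible and independent of execution
    order.  Members with fewer IMFs than the ensemble maximum are padded with
    zero components before averaging, which preserves reconstruction of the
    ensemble mean signal.
    """
    cfg = cfg or SiftConfig()
    x = series.values if isinstance(series, SeriesSample) else np.asarray(series, float)
    sigma = cfg.noise_scale * (np.std(x) if cfg.noise_mode == "relative" else 1.0)

    member_cfg = replace(cfg, ensemble_size=1, noise_scale=0.0)
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.ensemble_size)
    members: list[Decomposition] = []
    for child in streams:
        rng = np.random.default_rng(child)
        noise = rng.normal(0.0, sigma, size=x.size) if sigma > 0 else 0.0
        members.append(emd(x + noise, member_cfg))

    k_max = max(m.n_imfs for m in members)
    zeros = np.zeros_like(x, dtype=float)
    imfs = []
    for k in range(k_max):
        stack = [m.imfs[k] if k < m.n_imfs else zeros for m in members]
        imfs.append(np.mean(stack, axis=0))
    residue = np.mean([m.residue for m in members], axis=0)
    return Decomposition(
        imfs=imfs,
        residue=residue,
        ensemble_size=cfg.ensemble_size,
        noise_scale=cfg.noise_scale,
        seed=cfg.seed,
    )
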