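"""Wiener first-passage-time machinery for the two-boundary diffusion model.

The density at each boundary is evaluated with the standard
small-time/large-time series, switching to whichever representation needs
fewer terms for a target truncation error (default 1e-8).  Across-trial
Gaussian drift variability (``sv``) is marginalized analytically; uniform
start-point variability (``sz``) is marginalized by fixed-order
Gauss-Legendre quadrature (order 11).  The simulator is an independent
route to the same distribution: Euler-Maruyama with an exact
diffusion-bridge correction for within-step boundary crossings, which is
used as a cross-check against the series density in the test-suite.

Boundary coding: ``upper`` corresponds to a "same" response in the
reference-back application; drift is signed toward the upper boundary.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit
from scipy.integrate import cumulative_trapezoid

from .params import DDMParams, ParameterError

#: target absolute truncation error of the density series
SERIES_EPS = 1e-8
#: density floor applied before taking logs in the likelihood
DENSITY_FLOOR = 1e-10

# Gauss-Legendre nodes/weights on [-1, 1] for the sz marginal (order 11)
_GL_X, _GL_W = np.polynomial.legendre.leggauss(11)
# Gauss-Hermite rule for the sv marginal of absorption probabilities
_GH_X, _GH_W = np.polynomial.hermite.hermgauss(41)


@njit(cache=True, fastmath=True)
def _f0(tt: float, w: float, eps: float) -> float:
    """Zero-drift FPT density at the lower boundary, a=1, time tt=t/a^2."""
    if tt <= 0.0:
        return 0.0
    # number of terms needed by each series representation
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * tt)))
        if ks < math.sqrt(tt) + 1.0:
            ks = math.sqrt(tt) + 1.0
    else:
        ks = 2.0
    if math.pi * tt * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * eps) / (math.pi * math.pi * tt))
        if kl < 1.0 / (math.pi * math.sqrt(tt)):
            kl = 1.0 / (math.pi * math.sqrt(tt))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))

    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        total = 0.0
        for k in range(-K, K + 1):
            u = w + 2.0 * k
            total += u * math.exp(-u * u / (2.0 * tt))
        return total / math.sqrt(2.0 * math.pi * tt * tt * tt)
    # large-time expansion
    K = int(math.ceil(kl))
    total = 0.0
    for k in range(1, K + 1):
        total += k * math.exp(-k * k * math.pi * math.pi * tt / 2.0) * math.sin(k * math.pi * w)
    return total * math.pi


@njit(cache=True, fastmath=True)
def _dens_lower(td: float, v: float, a: float, w: float, sv: float, eps: float) -> float:
    """FPT density at the lower boundary at decision time td, drift v, start w*a."""
    if td <= 0.0:
        return 0.0
    if sv > 0.0:
        s2t = 1.0 + sv * sv * td
        m = math.exp(
            (a * a * w * w * sv * sv - 2.0 * v * a * w - v * v * td) / (2.0 * s2t)
        ) / math.sqrt(s2t)
    else:
        m = math.exp(-v * a * w - v * v * td / 2.0)
    return m * _f0(td / (a * a), w, eps) / (a * a)


@njit(cache=True, fastmath=True)
def _dens(
    td: float, upper: bool, v: float, a: float, z: float, sz: float, sv: float, eps: float
) -> float:
    """Full density with sz quadrature; v signed toward the upper boundary."""
    if upper:
        vv = -v
        wb = 1.0 - z
    else:
        vv = v
        wb = z
    if sz <= 0.0:
        return _dens_lower(td, vv, a, wb, sv, eps)
    total = 0.0
    for i in range(_GL_X.size):
        total += _GL_W[i] * _dens_lower(td, vv, a, wb + 0.5 * sz * _GL_X[i], sv, eps)
    return 0.5 * total


@njit(cache=True, fastmath=True)
def _dens_array(t, upper, v, a, z, sz, sv, t0, eps):
    out = np.empty(t.size)
    for i in range(t.size):
        out[i] = _dens(t[i] - t0, upper[i], v, a, z, sz, sv, eps)
    return out


@njit(cache=True, fastmath=True)
def _loglik_cells(rt, upper, cell, v_signed, a_cell, t0_cell, z, sz, sv, eps, floor):
    """Summed log density over trials grouped by design cell (0-based index)."""
    total = 0.0
    for i in range(rt.size):
        c = cell[i]
        d = _dens(rt[i] - t0_cell[c], upper[i], v_signed[c], a_cell[c], z, sz, sv, eps)
        if d < floor:
            d = floor
        total += math.log(d)
    return total


@njit(cache=True)
def _sim_kernel(n, v, a, z, sz, sv, t0, dt, seed):
    """Euler-Maruyama simulation with diffusion-bridge crossing correction."""
    np.random.seed(seed)
    rts = np.empty(n)
    ups = np.empty(n, np.bool_)
    sq = math.sqrt(dt)
    for i in range(n):
        vi = v + sv * np.random.randn() if sv > 0.0 else v
        zi = z + sz * (np.random.random() - 0.5) if sz > 0.0 else z
        x = zi * a
        t = 0.0
        while True:
            xn = x + vi * dt + sq * np.random.randn()
            t += dt
            if xn >= a:
                rts[i] = t0 + t - dt + dt * (a - x) / (xn - x)
                ups[i] = True
                break
            if xn <= 0.0:
                rts[i] = t0 + t - dt + dt * x / (x - xn)
                ups[i] = False
                break
            # exact bridge probability of an unobserved within-step crossing;
            # skipped when it is below ~1e-9 (exponent < -20)
            if (a - x) * (a - xn) < 10.0 * dt and np.random.random() < math.exp(
                -2.0 * (a - x) * (a - xn) / dt
            ):
                rts[i] = t0 + t - 0.5 * dt
                ups[i] = True
                break
            if x * xn < 10.0 * dt and np.random.random() < math.exp(-2.0 * x * xn / dt):
                rts[i] = t0 + t - 0.5 * dt
                ups[i] = False
                break
            x = xn
    return ups, rts


def _check_boundary(boundary: str) -> bool:
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    return boundary == "upper"


def fpt_density(t, boundary: str, p: DDMParams, eps: float = SERIES_EPS):
    """First-passage-time density at boundary ``boundary`` evaluated at ``t``.

    Returns a scalar for scalar ``t`` or an ndarray for array input; the
    density is zero for ``t <= t0``.
    """
    up = _check_boundary(boundary)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    upper = np.full(t_arr.size, up)
    out = _dens_array(t_arr, upper, p.v, p.a, p.z, p.sz, p.sv, p.t0, eps)
    return out[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else out


def _p_upper_closed(v: float, a: float, w: float) -> float:
    """Absorption probability at the upper boundary, no parameter variability."""
    x = 2.0 * v * a
    if abs(x) < 1e-9:
        return w
    # (1 - exp(-2 v a w)) / (1 - exp(-2 v a)), computed stably
    return math.expm1(-x * w) / math.expm1(-x)


def boundary_probability(boundary: str, p: DDMParams) -> float:
    """Probability of absorption at the given boundary (marginal over sv, sz)."""
    up = _check_boundary(boundary)
    if p.sz > 0:
        ws = p.z + 0.5 * p.sz * _GL_X
        wts = 0.5 * _GL_W
    else:
        ws = np.array([p.z])
        wts = np.array([1.0])
    if p.sv > 0:
        vs = p.v + math.sqrt(2.0) * p.sv * _GH_X
        vwts = _GH_W / math.sqrt(math.pi)
    else:
        vs = np.array([p.v])
        vwts = np.array([1.0])
    prob = 0.0
    for w, ww in zip(ws, wts):
        for v, vw in zip(vs, vwts):
            prob += ww * vw * _p_upper_closed(v, p.a, w)
    return prob if up else 1.0 - prob


def _time_horizon(p: DDMParams) -> float:
    """Upper integration limit holding all but a negligible tail of mass."""
    # large-time decay rate of the slowest series mode is pi^2/(2 a^2);
    # pad for drift variability which fattens the tail
    rate = math.pi**2 / (2.0 * p.a**2) + 0.5 * min(abs(p.v), 5.0) ** 2 / (1.0 + p.sv**2)
    horizon = p.t0 + max(5.0, 40.0 / rate)
    return min(horizon, 240.0)


def _cdf_grid(p: DDMParams, boundary: str, n: int = 4096, t_max: float | None = None):
    """Time grid and cumulative defective CDF at one boundary."""
    up = _check_boundary(boundary)
    if t_max is None:
        t_max = _time_horizon(p)
    grid = np.linspace(p.t0, t_max, n)
    upper = np.full(n, up)
    dens = _dens_array(grid, upper, p.v, p.a, p.z, p.sz, p.sv, p.t0, SERIES_EPS)
    cdf = np.concatenate([[0.0], cumulative_trapezoid(dens, grid)])
    return grid, cdf


def defective_cdf(t, boundary: str, p: DDMParams):
    """Defective CDF: P(absorbed at ``boundary`` and RT <= t).

    Tends to ``boundary_probability`` as t -> infinity.
    """
    grid, cdf = _cdf_grid(p, boundary)
    t_arr = np.asarray(t, dtype=float)
    out = np.interp(t_arr, grid, cdf, left=0.0, right=cdf[-1])
    return float(out) if t_arr.ndim == 0 else out


def conditional_quantiles(qs, boundary: str, p: DDMParams):
    """RT quantiles conditional on absorption at ``boundary``."""
    grid, cdf = _cdf_grid(p, boundary)
    total = cdf[-1]
    if total <= 0:
        return np.full(len(np.atleast_1d(qs)), np.nan)
    return np.interp(np.asarray(qs, dtype=float) * total, cdf, grid)


def simulate_choice_rt(p: DDMParams, n: int, seed: int, dt: float = 1e-4):
    """Simulate ``n`` choice-RT pairs by Euler-Maruyama with bridge correction.

    Returns ``(upper, rt)``: a boolean array marking upper-boundary
    absorptions and the response times in seconds.  This path is
    deliberately independent of the series density.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return _sim_kernel(int(n), p.v, p.a, p.z, p.sz, p.sv, p.t0, dt, int(seed) % 2**32)


def log_likelihood(trials, cell_params: dict, floor: float = DENSITY_FLOOR) -> float:
    """Dataset log-likelihood under per-cell diffusion parameters.

    ``trials`` is a DataFrame with columns ``rt`` (seconds), ``response``
    ('same'/'different'; 'same' maps to the upper boundary) and ``cell``
    (design-cell index, keys of ``cell_params``).
    """
    rts = np.asarray(trials["rt"], dtype=float)
    if np.any(rts <= 0):
        raise ValueError("all RTs must be positive")
    upper = np.asarray(trials["response"] == "same")
    cells = np.asarray(trials["cell"])
    missing = set(np.unique(cells)) - set(cell_params)
    if missing:
        raise KeyError(f"no parameters supplied for cells {sorted(missing)}")
    total = 0.0
    for c, p in cell_params.items():
        m = cells == c
        if not m.any():
            continue
        d = _dens_array(rts[m], upper[m], p.v, p.a, p.z, p.sz, p.sv, p.t0, SERIES_EPS)
        total += float(np.log(np.maximum(d, floor)).sum())
    return total
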