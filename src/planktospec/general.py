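"""Steady state and growth eigenproblem for sloppy size control.

Cells may divide anywhere above the threshold fraction xth at rate
K = w*^(-xi) k(x), producing daughters of relative size drawn from q.  The
steady profile factorises as p(w, w*) = p(w_+, w*) psi(w/w*) with

    psi(x) = g(x_+)/g(x) * e(x) * Theta(x),        x_+ = (1+delta)/2,

where e is the survival factor through division and death hazards,

    e(x) = exp( - int_{x_+}^x (k(y) + m(y)) / g(y) dy ),

h the renewal (daughter-production) density

    h(x) = 2 int_xth^1 k(y) e(y) / g(y) * q(x/y) / y dy,

and Theta the cumulative renewal fraction int_0^x h/e dy (1 above x_+).  The
nutrient level is fixed by the renewal condition int_0^{x_+} h/e dx = 1 (each
cell leaves exactly one descendant at steady state); in a nutrient-rich
culture with no death the same condition, with the population growth rate
Lambda in place of mortality, becomes an eigenvalue problem for Lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid, quad
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from ._quad import cumulative_gauss, pole_clustered_nodes
from .errors import ExtinctionOnlyError, InfeasibleGrowthError
from .params import (DivisionSpec, GrowthParams, MortalitySpec, monod_uptake,
                     nutrient_for_uptake, relative_growth)

__all__ = [
    "GeneralProfile",
    "EigenResult",
    "survival_factor_e",
    "renewal_density_h",
    "renewal_integral",
    "solve_nutrient_general",
    "build_general_profile",
    "psi_profile",
    "solve_growth_eigenvalue",
]

_GL_X, _GL_W = np.polynomial.legendre.leggauss(32)


@dataclass
class GeneralProfile:
    """Tabulated steady profile for sloppy size control."""

    x_grid: np.ndarray
    psi: np.ndarray
    e_vals: np.ndarray
    h_vals: np.ndarray
    theta_vals: np.ndarray
    N_star: Optional[float]
    a_val: float
    renewal: float              # int_0^{x_+} h/e dx at a_val
    norm: float = 1.0           # overall abundance scale p(w_+, w*)
    alpha_eff: Optional[float] = None
    _psi_interp: PchipInterpolator = field(default=None, repr=False)

    @property
    def x_support(self) -> float:
        return float(self.x_grid[0])

    def __call__(self, x):
        x = np.asarray(x, float)
        out = np.where((x > self.x_grid[0]) & (x < 1.0),
                       self._psi_interp(np.clip(x, self.x_grid[0], self.x_grid[-1])),
                       0.0)
        out = np.maximum(out, 0.0)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class EigenResult:
    """Population growth rate Lambda and its scale-free form ell = Lambda w*^xi."""
    Lambda: float
    ell: float
    w_star: float
    residual: float


def _alpha(gp: GrowthParams, alpha: Optional[float]) -> float:
    return gp.alpha if alpha is None else alpha


# ---------------------------------------------------------------------------
# pointwise (adaptive quadrature) evaluations — oracle-grade, not fast
# ---------------------------------------------------------------------------

def survival_factor_e(x, ds: DivisionSpec, m_shape: Callable, a_val: float,
                      gp: GrowthParams, alpha: Optional[float] = None):
    """Survival factor e(x); equals 1 at x_+ = (1+delta)/2, 0 at x = 1.

    For x < x_+ the hazard integral runs backwards, so e(x) > 1 whenever
    mortality is positive."""
    al = _alpha(gp, alpha)
    if a_val <= gp.b:
        raise InfeasibleGrowthError("survival factor requires a_val > b")
    xp = ds.x_plus

    def one(xv: float) -> float:
        if xv >= 1.0:
            return 0.0
        pts = [ds.xth] if min(xv, xp) < ds.xth < max(xv, xp) else None
        val, _ = quad(lambda y: (ds.k(y) + m_shape(y)) /
                      relative_growth(y, a_val, gp, al),
                      xp, xv, epsabs=1e-13, epsrel=1e-11, limit=400, points=pts)
        return float(np.exp(-val))

    xs = np.asarray(x, float)
    if xs.ndim == 0:
        return one(float(xs))
    return np.array([one(v) for v in xs])


def renewal_density_h(x, ds: DivisionSpec, m_shape: Callable, a_val: float,
                      gp: GrowthParams, alpha: Optional[float] = None,
                      e_func: Optional[Callable] = None):
    """Renewal density h(x): rate density of daughters appearing at relative
    size x, per cell reaching x_+.  Zero outside (xth(1-delta)/2, (1+delta)/2)."""
    al = _alpha(gp, alpha)
    if e_func is None:
        def e_func(y):
            return survival_factor_e(y, ds, m_shape, a_val, gp, alpha)

    def one(xv: float) -> float:
        ylo = max(ds.xth, xv / ((1 + ds.delta) / 2))
        yhi = min(1.0, xv / ((1 - ds.delta) / 2))
        if ylo >= yhi:
            return 0.0
        val, _ = quad(lambda y: 2.0 * ds.k(y) * e_func(y) /
                      relative_growth(y, a_val, gp, al) * ds.q(xv / y) / y,
                      ylo, yhi, epsabs=1e-12, epsrel=1e-10, limit=400)
        return float(val)

    xs = np.asarray(x, float)
    if xs.ndim == 0:
        return one(float(xs))
    return np.array([one(v) for v in xs])


# ---------------------------------------------------------------------------
# fast grid machinery
# ---------------------------------------------------------------------------

def _hazard_cumulative(ds: DivisionSpec, m_shape: Callable, a_val: float,
                       gp: GrowthParams, alpha: Optional[float],
                       n_pole: int = 256):
    """Survival factor e as a callable built from a cumulative hazard table.

    The hazard is integrated exactly on panels: smooth below xth, and on
    pole-clustered nodes (x = 1 - e^{-u} map) above, where k ~ 1/(1-x)."""
    al = _alpha(gp, alpha)
    xp = ds.x_plus

    def hazard(y):
        return (ds.k(y) + m_shape(y)) / relative_growth(y, a_val, gp, al)

    lo_nodes = np.linspace(ds.x_lo * 0.5, xp, 129)
    mid_nodes = np.linspace(xp, ds.xth, 65)
    hi_nodes = pole_clustered_nodes(ds.xth, n_pole, tiny=1e-13)

    A_lo = cumulative_gauss(hazard, lo_nodes)          # from x_lo/2 up to xp
    A_mid = cumulative_gauss(hazard, mid_nodes)        # from xp up
    A_hi = A_mid[-1] + cumulative_gauss(hazard, hi_nodes)

    nodes = np.concatenate([lo_nodes[:-1], mid_nodes[:-1], hi_nodes])
    A = np.concatenate([A_lo[:-1] - A_lo[-1], A_mid[:-1], A_hi])
    interp = PchipInterpolator(nodes, A, extrapolate=False)

    def e(y):
        y = np.asarray(y, float)
        a_v = interp(np.clip(y, nodes[0], nodes[-1]))
        out = np.where(y >= 1.0, np.inf, a_v)
        out = np.exp(-np.minimum(out, 700.0))
        out = np.where(y >= 1.0, 0.0, out)
        return out if out.ndim else float(out)

    return e


def _renewal_grid(ds: DivisionSpec, a_val: float, gp: GrowthParams,
                  alpha: Optional[float], e) -> Callable:
    """h as a callable via Gauss quadrature in u = x/y over the q support."""
    al = _alpha(gp, alpha)
    qlo, qhi = (1 - ds.delta) / 2, (1 + ds.delta) / 2

    def h(x):
        x = np.atleast_1d(np.asarray(x, float))
        # integrate over u in (max(qlo, x/1), min(qhi, x/xth)) with y = x/u
        ulo = np.maximum(qlo, x)          # y <= 1
        uhi = np.minimum(qhi, x / ds.xth)  # y >= xth
        bad = ulo >= uhi
        ulo_s, uhi_s = np.where(bad, 0.4, ulo), np.where(bad, 0.6, uhi)
        u = 0.5 * (uhi_s - ulo_s)[:, None] * _GL_X[None, :] + 0.5 * (uhi_s + ulo_s)[:, None]
        wq = 0.5 * (uhi_s - ulo_s)[:, None] * _GL_W[None, :]
        y = x[:, None] / u
        # k e -> 0 as y -> 1 (survival beats the rate pole); mask the 0*inf
        safe = y < 1.0
        ys = np.where(safe, y, 0.5)
        integ = np.where(safe, 2.0 * ds.k(ys) * e(ys)
                         / relative_growth(ys, a_val, gp, al) * ds.q(u) / u, 0.0)
        out = np.sum(wq * integ, axis=1)
        out[bad] = 0.0
        return out

    return h


def renewal_integral(a_val: float, ds: DivisionSpec, m_shape: Callable,
                     gp: GrowthParams, alpha: Optional[float] = None,
                     n_outer: int = 96) -> float:
    """int_0^{x_+} h(x)/e(x) dx at uptake a_val (order-swapped double
    Gauss quadrature).  Equals 2 when mortality vanishes; equals 1 at the
    steady-state nutrient level."""
    al = _alpha(gp, alpha)
    e = _hazard_cumulative(ds, m_shape, a_val, gp, alpha)
    qlo, qhi = (1 - ds.delta) / 2, (1 + ds.delta) / 2

    # R = 2 int_xth^1 dy k e / (g) * [ int_qlo^qhi q(u)/e(u y) du ] dy
    y_nodes = pole_clustered_nodes(ds.xth, n_outer, tiny=1e-13)

    def outer(y):
        u = 0.5 * (qhi - qlo) * _GL_X + 0.5 * (qhi + qlo)
        wq = 0.5 * (qhi - qlo) * _GL_W
        inner = np.sum(wq[None, :] * ds.q(u)[None, :] /
                       e(y[..., None] * u[None, :]), axis=-1)
        return 2.0 * ds.k(y) * e(y) / relative_growth(y, a_val, gp, al) * inner

    a = y_nodes[:-1]
    b = y_nodes[1:]
    x = 0.5 * (b - a)[:, None] * _GL_X[None, :] + 0.5 * (a + b)[:, None]
    w = 0.5 * (b - a)[:, None] * _GL_W[None, :]
    return float(np.sum(w * outer(x)))


def solve_nutrient_general(ds: DivisionSpec, m_shape: Callable,
                           gp: GrowthParams,
                           N_hi: Optional[float] = None,
                           alpha: Optional[float] = None) -> float:
    """Nutrient level N* at which the renewal condition int h/e = 1 holds.

    The renewal integral increases with nutrient (faster growth means fewer
    deaths per cycle), so the root is unique; found by Brent bracketing."""
    N_hi = 10.0 * gp.r if N_hi is None else N_hi
    margin = 1.0 + 1e-6
    if gp.b * margin >= gp.a_inf:
        raise InfeasibleGrowthError("a_inf barely exceeds b: no feasible bracket")
    N_lo = nutrient_for_uptake(gp.b * margin, gp) * (1 + 1e-9)

    def f(N):
        return renewal_integral(monod_uptake(N, gp), ds, m_shape, gp, alpha) - 1.0

    if f(N_hi) < 0:
        raise ExtinctionOnlyError(
            "renewal condition stays below 1 at the nutrient ceiling: extinction only")
    if f(N_lo) > 0:
        raise ExtinctionOnlyError("renewal condition exceeds 1 even at stalling growth")
    return brentq(f, N_lo, N_hi, xtol=1e-15, rtol=1e-13)


def solve_uptake_general(ds: DivisionSpec, m_shape: Callable, gp: GrowthParams,
                         a_hi: Optional[float] = None,
                         alpha: Optional[float] = None) -> float:
    """Uptake coefficient a* at which int h/e = 1 (no Monod curve involved;
    used for the zooplankton boundary condition where a_pz is unconstrained)."""
    a_lo = gp.b * (1 + 1e-6)
    a_hi = a_hi if a_hi is not None else max(4.0, 4 * gp.b)

    def f(av):
        return renewal_integral(av, ds, m_shape, gp, alpha) - 1.0

    if f(a_lo) > 0:
        raise ExtinctionOnlyError("renewal condition exceeds 1 at stalling growth")
    for _ in range(30):
        if f(a_hi) > 0:
            break
        a_hi *= 2.0
    else:
        raise ExtinctionOnlyError("renewal condition stays below 1: no feasible uptake")
    return brentq(f, a_lo, a_hi, xtol=1e-14, rtol=1e-13)


def build_general_profile(ds: DivisionSpec, m_shape: Callable, gp: GrowthParams,
                          N_star: Optional[float] = None,
                          a_val: Optional[float] = None,
                          n_grid: int = 512,
                          alpha: Optional[float] = None) -> GeneralProfile:
    """Tabulate e, h, Theta and psi on a pole-refined grid of (0, 1]."""
    al = _alpha(gp, alpha)
    if a_val is None:
        if N_star is None:
            N_star = solve_nutrient_general(ds, m_shape, gp, alpha=alpha)
        a_val = monod_uptake(N_star, gp)
    elif N_star is None:
        N_star = (nutrient_for_uptake(a_val, gp)
                  if a_val < gp.a_inf else None)

    xp = ds.x_plus
    e = _hazard_cumulative(ds, m_shape, a_val, gp, alpha)
    h = _renewal_grid(ds, a_val, gp, alpha, e)

    n_lo = n_grid // 2
    lo = np.linspace(ds.x_lo * 0.5, xp, n_lo)
    hi = pole_clustered_nodes(xp, n_grid - n_lo + 1, tiny=1e-10)[1:]
    xs = np.concatenate([lo, hi])

    e_vals = e(xs)
    h_vals = h(np.minimum(xs, xp))
    h_vals[xs > xp] = 0.0

    # Theta: cumulative renewal fraction on the small-cell branch
    ratio = np.where(xs <= xp, h_vals / e_vals, 0.0)
    theta = cumulative_trapezoid(ratio, xs, initial=0.0)
    renewal = float(theta[lo.size - 1])
    theta = np.where(xs >= xp, 1.0, np.minimum(theta, 1.0))

    g_vals = relative_growth(xs, a_val, gp, al)
    psi = relative_growth(xp, a_val, gp, al) / g_vals * e_vals * theta
    psi[-1] = 0.0

    prof = GeneralProfile(x_grid=xs, psi=psi, e_vals=e_vals, h_vals=h_vals,
                          theta_vals=theta, N_star=N_star, a_val=a_val,
                          renewal=renewal, alpha_eff=alpha)
    prof._psi_interp = PchipInterpolator(xs, psi, extrapolate=False)
    return prof


def psi_profile(x, ds: DivisionSpec, m_shape: Callable, a_val: float,
                gp: GrowthParams, alpha: Optional[float] = None,
                n_grid: int = 512):
    """Convenience evaluation of psi(x) at a supplied uptake level."""
    prof = build_general_profile(ds, m_shape, gp, a_val=a_val, n_grid=n_grid,
                                 alpha=alpha)
    return prof(x)


def profile_moment(prof: GeneralProfile, eta: float) -> float:
    """J(eta) = int_0^1 x^eta psi(x) dx on the tabulated grid."""
    return float(np.trapezoid(prof.x_grid ** eta * prof.psi, prof.x_grid))


# ---------------------------------------------------------------------------
# growth eigenvalue in absolute size coordinates
# ---------------------------------------------------------------------------

def _renewal_integral_absolute(Lambda: float, w_star: float, ds: DivisionSpec,
                               gp: GrowthParams, a_val: float) -> float:
    """int_0^{w_+} H/E dw with E, H built from the absolute-size kernels
    K(w, w*), G(w, w*) and the growth rate Lambda in place of mortality."""
    xi = gp.xi
    wth = ds.xth * w_star
    w_plus = ds.x_plus * w_star

    def G(w):
        return w_star ** (1 - xi) * relative_growth(w / w_star, a_val, gp)

    def K(w):
        return w_star ** (-xi) * ds.k(w / w_star)

    def hazard(w):
        return (K(w) + Lambda) / G(w)

    # cumulative hazard from w_+ (panels proportional to w_star keep the
    # resolution of the pole at w = w_star independent of species size)
    lo_nodes = w_star * np.linspace(ds.x_lo * 0.5, ds.x_plus, 129)
    mid_nodes = w_star * np.linspace(ds.x_plus, ds.xth, 65)
    hi_nodes = w_star * pole_clustered_nodes(ds.xth, 256, tiny=1e-13)
    A_lo = cumulative_gauss(hazard, lo_nodes)
    A_mid = cumulative_gauss(hazard, mid_nodes)
    A_hi = A_mid[-1] + cumulative_gauss(hazard, hi_nodes)
    nodes = np.concatenate([lo_nodes[:-1], mid_nodes[:-1], hi_nodes])
    A = np.concatenate([A_lo[:-1] - A_lo[-1], A_mid[:-1], A_hi])
    interp = PchipInterpolator(nodes, A, extrapolate=False)

    def E(w):
        w = np.asarray(w, float)
        a_v = interp(np.clip(w, nodes[0], nodes[-1]))
        out = np.exp(-np.minimum(np.where(w >= w_star, np.inf, a_v), 700.0))
        return np.where(w >= w_star, 0.0, out)

    qlo, qhi = (1 - ds.delta) / 2, (1 + ds.delta) / 2
    u = 0.5 * (qhi - qlo) * _GL_X + 0.5 * (qhi + qlo)
    wq = 0.5 * (qhi - qlo) * _GL_W

    def outer(y):
        # inner: int Q(w|y)/E(w) dw over daughters w = u y
        inner = np.sum(wq[None, :] * ds.q(u)[None, :] /
                       E(y[..., None] * u[None, :]), axis=-1)
        return 2.0 * K(y) * E(y) / G(y) * inner

    y_nodes = w_star * pole_clustered_nodes(ds.xth, 96, tiny=1e-13)
    a = y_nodes[:-1]
    b = y_nodes[1:]
    yy = 0.5 * (b - a)[:, None] * _GL_X[None, :] + 0.5 * (a + b)[:, None]
    ww = 0.5 * (b - a)[:, None] * _GL_W[None, :]
    return float(np.sum(ww * outer(yy)))


def solve_growth_eigenvalue(w_star: float, ds: DivisionSpec, gp: GrowthParams,
                            a_val: float) -> EigenResult:
    """Population growth rate Lambda of a single species in a nutrient-rich
    culture (fixed uptake, no death), from the renewal condition
    int_0^{w_+} H/E dw = 1.  The integral decreases monotonically in Lambda."""
    if a_val <= gp.b:
        raise InfeasibleGrowthError("eigenvalue requires a_val > b")

    def f(L):
        return _renewal_integral_absolute(L, w_star, ds, gp, a_val) - 1.0

    lo = 0.0
    if f(lo) < 0:
        raise InfeasibleGrowthError("parameters cannot sustain population growth")
    hi = a_val * w_star ** (-gp.xi)
    for _ in range(60):
        if f(hi) < 0:
            break
        hi *= 2.0
    else:
        raise InfeasibleGrowthError("failed to bracket the growth eigenvalue")
    Lam = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
    return EigenResult(Lambda=Lam, ell=Lam * w_star ** gp.xi, w_star=w_star,
                       residual=f(Lam))
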