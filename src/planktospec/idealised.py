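"""Steady state for the idealised division process.

Cells grow from w*/2 to w*, split exactly in half, and the steady transport
balance fixes the within-species profile

    phi(x) = (a - b) / g(x) * exp( int_x^1 m(y)/g(y) dy ),   g(x) = a x^alpha - b x^beta,

on x in [1/2, 1], normalised so phi(1) = 1.  Coexistence of every species
requires the single nutrient level N* at which

    int_{1/2}^1 m(x)/g(x) dx = log 2,

equivalently, at which the boundary flux ratio G(w*/2) p(w*/2) / (G(w*) p(w*))
equals 2 (two daughters per division).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

from .errors import ExtinctionOnlyError, InfeasibleGrowthError
from .params import (GrowthParams, MortalitySpec, NutrientState,
                     monod_uptake, nutrient_for_uptake, relative_growth)

__all__ = [
    "IdealisedProfile",
    "phi_profile",
    "coexistence_residual",
    "solve_nutrient_idealised",
    "solve_nutrient_by_shooting",
    "shoot_boundary_ratio",
    "build_idealised_profile",
    "boundary_ratio",
    "abundance_constraint_rhs",
    "profile_moment",
]

_LOG2 = np.log(2.0)


@dataclass
class IdealisedProfile:
    """Within-species relative-size distribution for exact halving.

    Calling the profile interpolates the tabulated grid (phi is smooth);
    ``exact(x)`` re-evaluates the quadrature formula pointwise."""

    x_grid: np.ndarray
    phi: np.ndarray
    N_star: float
    a_val: float
    norm: float = 1.0          # overall abundance scale p(w*, w*)
    alpha_eff: Optional[float] = None
    m_shape: Callable = None
    gp: GrowthParams = None
    _interp: object = None

    @property
    def x_support(self) -> float:
        return 0.5

    def __call__(self, x):
        if self._interp is None:
            from scipy.interpolate import PchipInterpolator
            self._interp = PchipInterpolator(self.x_grid, self.phi,
                                             extrapolate=False)
        x = np.asarray(x, float)
        out = np.where((x >= 0.5) & (x <= 1.0),
                       self._interp(np.clip(x, 0.5, 1.0)), 0.0)
        return out if out.ndim else float(out)

    def exact(self, x):
        return phi_profile(x, self.m_shape, self.a_val, self.gp,
                           alpha=self.alpha_eff)


def _alpha(gp: GrowthParams, alpha: Optional[float]) -> float:
    return gp.alpha if alpha is None else alpha


def phi_profile(x, m_shape: Callable, a_val: float, gp: GrowthParams,
                alpha: Optional[float] = None):
    """Evaluate phi(x) by adaptive quadrature of the mortality integral.

    ``alpha`` overrides the uptake exponent (the zooplankton profile uses
    1 - xi with a_val = a_pz)."""
    al = _alpha(gp, alpha)
    if a_val <= gp.b:
        raise InfeasibleGrowthError("phi requires a_val > b")

    def one(xv: float) -> float:
        I, _ = quad(lambda y: m_shape(y) / relative_growth(y, a_val, gp, al),
                    xv, 1.0, epsabs=1e-13, epsrel=1e-12, limit=200)
        return (a_val - gp.b) / relative_growth(xv, a_val, gp, al) * np.exp(I)

    xs = np.asarray(x, float)
    if xs.ndim == 0:
        return one(float(xs))
    return np.array([one(v) for v in xs])


def coexistence_residual(N: float, m_shape: Callable, gp: GrowthParams,
                         alpha: Optional[float] = None,
                         a_val: Optional[float] = None) -> float:
    """int_{1/2}^1 m/g dx - log 2 at nutrient N (or directly at uptake a_val).

    Strictly decreasing in N because a(N) is increasing."""
    av = monod_uptake(N, gp) if a_val is None else a_val
    if av <= gp.b:
        raise InfeasibleGrowthError(
            f"a(N)={av:.6g} <= b={gp.b}: growth infeasible at this nutrient level")
    al = _alpha(gp, alpha)
    val, _ = quad(lambda y: m_shape(y) / relative_growth(y, av, gp, al),
                  0.5, 1.0, epsabs=1e-12, epsrel=1e-11, limit=200)
    return val - _LOG2


def _nutrient_bracket(gp: GrowthParams, N_hi: float):
    margin = 1.0 + 1e-6
    if gp.b * margin >= gp.a_inf:
        raise InfeasibleGrowthError("a_inf barely exceeds b: no feasible nutrient bracket")
    N_lo = nutrient_for_uptake(gp.b * margin, gp)
    if N_lo >= N_hi:
        raise InfeasibleGrowthError("growth infeasible everywhere below the chemostat capacity")
    return N_lo, N_hi


def solve_nutrient_idealised(m_shape: Callable, gp: GrowthParams,
                             N_hi: Optional[float] = None,
                             alpha: Optional[float] = None) -> float:
    """Unique nutrient root of the coexistence condition, by bracketed
    bisection (Brent) to relative tolerance 1e-12."""
    N_hi = 10.0 * gp.r if N_hi is None else N_hi
    N_lo, N_hi = _nutrient_bracket(gp, N_hi)
    f_lo = coexistence_residual(N_lo * (1 + 1e-9), m_shape, gp, alpha)
    f_hi = coexistence_residual(N_hi, m_shape, gp, alpha)
    if f_lo < 0 or f_hi > 0:
        raise ExtinctionOnlyError(
            "coexistence condition has no root in the feasible nutrient bracket: "
            "no steady state is possible except full extinction")
    return brentq(lambda N: coexistence_residual(N, m_shape, gp, alpha),
                  N_lo * (1 + 1e-9), N_hi, xtol=1e-15, rtol=1e-13)


# -- independent route: ODE shooting ---------------------------------------

def shoot_boundary_ratio(a_val: float, m_shape: Callable, gp: GrowthParams,
                         alpha: Optional[float] = None,
                         rtol: float = 1e-11) -> float:
    """Integrate the steady transport ODE d/dx[g phi] + m phi = 0 downward
    from x = 1 (phi = 1) and return the flux ratio g(1/2) phi(1/2) / g(1).

    Works on the flux variable F = g phi, for which dF/dx = -m F / g."""
    al = _alpha(gp, alpha)
    if a_val <= gp.b:
        raise InfeasibleGrowthError("shooting requires a_val > b")

    def rhs(x, F):
        return [-m_shape(x) * F[0] / relative_growth(x, a_val, gp, al)]

    F1 = relative_growth(1.0, a_val, gp, al)
    sol = solve_ivp(rhs, (1.0, 0.5), [F1], rtol=rtol, atol=1e-13 * F1,
                    dense_output=False, method="DOP853")
    return float(sol.y[0, -1] / F1)


def solve_nutrient_by_shooting(m_shape: Callable, gp: GrowthParams,
                               N_hi: Optional[float] = None) -> float:
    """Solve for N* using only the ODE + the two-daughter flux boundary
    condition (independent of the closed-form coexistence integral)."""
    N_hi = 10.0 * gp.r if N_hi is None else N_hi
    N_lo, N_hi = _nutrient_bracket(gp, N_hi)

    def f(N):
        return shoot_boundary_ratio(monod_uptake(N, gp), m_shape, gp) - 2.0

    if f(N_lo * (1 + 1e-9)) < 0 or f(N_hi) > 0:
        raise ExtinctionOnlyError("flux boundary condition has no root: extinction only")
    return brentq(f, N_lo * (1 + 1e-9), N_hi, xtol=1e-15, rtol=1e-13)


def build_idealised_profile(m_shape: Callable, gp: GrowthParams,
                            N_star: Optional[float] = None,
                            n_grid: int = 257,
                            alpha: Optional[float] = None,
                            a_val: Optional[float] = None) -> IdealisedProfile:
    """Tabulate phi on [1/2, 1] at the solved (or supplied) nutrient."""
    if a_val is None:
        if N_star is None:
            N_star = solve_nutrient_idealised(m_shape, gp, alpha=alpha)
        a_val = monod_uptake(N_star, gp)
    elif N_star is None:
        N_star = nutrient_for_uptake(min(a_val, gp.a_inf * (1 - 1e-12)), gp)
    xs = np.linspace(0.5, 1.0, n_grid)
    prof = IdealisedProfile(x_grid=xs,
                            phi=phi_profile(xs, m_shape, a_val, gp, alpha=alpha),
                            N_star=N_star, a_val=a_val, alpha_eff=alpha)
    prof.m_shape = m_shape
    prof.gp = gp
    return prof


def boundary_ratio(profile: IdealisedProfile, gp: GrowthParams) -> float:
    """Flux ratio g(1/2) phi(1/2) / (g(1) phi(1)); equals 2 at the solved
    nutrient, < 2 when nutrient exceeds the coexistence level."""
    al = _alpha(gp, profile.alpha_eff)
    g_half = relative_growth(0.5, profile.a_val, gp, al)
    g_one = relative_growth(1.0, profile.a_val, gp, al)
    return float(g_half * profile.phi[0] / (g_one * profile.phi[-1]))


def profile_moment(profile: IdealisedProfile, eta: float) -> float:
    """I(eta) = int_0^1 x^eta phi(x) dx (phi vanishes below 1/2)."""
    def f(x):
        return x ** eta * phi_profile(x, profile.m_shape, profile.a_val,
                                      profile.gp, alpha=profile.alpha_eff)
    val, _ = quad(f, 0.5, 1.0, epsabs=1e-12, epsrel=1e-11, limit=200)
    return val


def abundance_constraint_rhs(N_star: float, gp: GrowthParams,
                             nutrient: NutrientState,
                             profile: IdealisedProfile) -> float:
    """Total abundance moment required by the nutrient balance:

        int_0^inf w*^(2-xi) p(w*,w*) dw* = theta rho(N*) / a(N*) / int x^alpha phi dx.
    """
    a_val = monod_uptake(N_star, gp)
    I_alpha = profile_moment(profile, gp.alpha)
    return nutrient.theta * nutrient.replenishment(N_star) / (a_val * I_alpha)
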