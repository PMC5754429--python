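"""Predation coupling and the self-consistent plankton community.

Zooplankton of size w feed on cells of size w' at rate S(w, w') = w^nu s(w/w'),
where s is a preference kernel of the predator:prey size ratio and nu the
foraging exponent.  The central structural result implemented here: the death
rate acquired from predation and the zooplankton growth rate scale
allometrically with exponents -xi and 1-xi exactly when both community
spectra are power laws w^{-gamma} with

    gamma = 1 + nu + xi,

and conversely.  With nu = 0.85 and xi = 0.15 this gives gamma = 2: constant
biomass per logarithmic size interval (the Sheldon spectrum).

On the power-law spectrum the predation integrals collapse to two moments of
the preference kernel,

    m(x)  = m_b(x) + z0 x^{-xi} * int y^{-xi-1} s(y) dy,
    a_pz  = eps (p0 + z0) * int x^{gamma-3} s(x) dx,

and the coupled steady state reduces to one scalar equation for the
zooplankton coefficient z0 (the phytoplankton nutrient condition, the
chemostat balance for p0 and the zooplankton renewal condition are solved
inside its residual).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from . import general as gen
from . import idealised as ideal
from .errors import (DomainError, KernelError, NoZooplanktonStateError)
from .params import (DivisionSpec, GrowthParams, MortalitySpec, NutrientState,
                     SpeciesAssemblage, monod_uptake, relative_growth)

__all__ = [
    "PredationSpec",
    "CommunitySolution",
    "feeding_rate",
    "predation_mortality_shape",
    "death_rate_powerlaw",
    "zoo_growth_rate",
    "scaling_theorem_check",
    "renormalisation_factor",
    "solve_coupled_steady_state",
    "zoo_profile",
]


@dataclass(frozen=True)
class PredationSpec:
    """Predation kernel S(w, w') = w^nu s(w/w') and conversion efficiency.

    The default preference kernel is log-normal in the log size ratio with
    mode ``ratio_mode`` and log-width ``ratio_width`` (natural log).  Both
    kernel moments that enter the community solution must be finite; they are
    checked on first use.
    """

    nu: float = 0.85
    epsilon: float = 0.6
    s_shape: Optional[Callable] = None
    ratio_mode: float = 100.0
    ratio_width: float = 1.0

    def __post_init__(self):
        if not (0 < self.epsilon <= 1):
            raise DomainError(f"conversion efficiency must lie in (0, 1], got {self.epsilon}")

    def s(self, y):
        y = np.asarray(y, float)
        if self.s_shape is not None:
            out = np.asarray(self.s_shape(y), float)
        else:
            out = np.exp(-(np.log(y) - np.log(self.ratio_mode)) ** 2
                         / (2 * self.ratio_width ** 2))
        return out if out.ndim else float(out)

    def s_moment(self, c: float) -> float:
        """int_0^inf y^c s(y) dy (closed form for the log-normal default)."""
        if self.s_shape is None:
            mu, sig = np.log(self.ratio_mode), self.ratio_width
            return float(np.sqrt(2 * np.pi) * sig
                         * np.exp((c + 1) * mu + (c + 1) ** 2 * sig ** 2 / 2))
        val, err = quad(lambda t: np.exp((c + 1) * t) * self.s(np.exp(t)),
                        -60, 60, epsabs=1e-13, epsrel=1e-11, limit=400)
        if not np.isfinite(val) or val > 1e12:
            raise KernelError(f"preference-kernel moment c={c} diverges")
        return float(val)

    def mortality_moment(self, gp: GrowthParams) -> float:
        """int y^{-xi-1} s(y) dy, entering the predation death rate."""
        return self.s_moment(-gp.xi - 1)

    def growth_moment(self, gp: GrowthParams) -> float:
        """int x^{gamma-3} s(x) dx, entering the zooplankton uptake a_pz."""
        return self.s_moment(self.gamma(gp) - 3)

    def gamma(self, gp: GrowthParams) -> float:
        return 1.0 + self.nu + gp.xi


def feeding_rate(w_pred, w_prey, ps: PredationSpec):
    """S(w_pred, w_prey); homogeneous of degree nu in (w, w')."""
    w_pred = np.asarray(w_pred, float)
    w_prey = np.asarray(w_prey, float)
    if np.any(w_pred <= 0) or np.any(w_prey <= 0):
        raise DomainError("sizes must be strictly positive")
    out = w_pred ** ps.nu * ps.s(w_pred / w_prey)
    return out if np.ndim(out) else float(out)


def predation_mortality_shape(z0: float, ps: PredationSpec, gp: GrowthParams,
                              mb_shape: Callable) -> MortalitySpec:
    """Total mortality shape m(x) = m_b(x) + z0 x^{-xi} int y^{-xi-1} s dy
    induced by a zooplankton spectrum z_c = z0 w^{-gamma}."""
    Sm = ps.mortality_moment(gp)

    def m(x, _Sm=Sm, _z0=z0, _xi=gp.xi):
        x = np.asarray(x, float)
        return mb_shape(x) + _z0 * x ** (-_xi) * _Sm

    return MortalitySpec(mb_shape=mb_shape, composed_m=m)


def death_rate_powerlaw(x, w_star, z0: float, ps: PredationSpec,
                        ms: MortalitySpec, gp: GrowthParams):
    """Death rate M(w, w*) under a power-law zooplankton spectrum; returns
    the closed-form w*^{-xi} m(x) with the predation term folded in."""
    spec = predation_mortality_shape(z0, ps, gp, ms.mb_shape)
    w_star = np.asarray(w_star, float)
    out = w_star ** (-gp.xi) * spec(x)
    return out if np.ndim(out) else float(out)


def death_rate_direct(w, w_star, z_c: Callable, ps: PredationSpec,
                      ms: MortalitySpec, gp: GrowthParams) -> float:
    """Predation mortality by direct quadrature of the predator spectrum:
    int S(w', w) z_c(w') dw' + background (oracle route for the closed form)."""
    val, _ = quad(lambda t: feeding_rate(np.exp(t), w, ps) * z_c(np.exp(t)) * np.exp(t),
                  np.log(w) - 40, np.log(w) + 40, epsabs=1e-13, epsrel=1e-10,
                  limit=400)
    return float(val + w_star ** (-gp.xi) * ms.mb_shape(np.asarray(w / w_star)))


def zoo_growth_rate(w, w_star, p0: float, z0: float, ps: PredationSpec,
                    gp: GrowthParams):
    """Zooplankton growth rate on power-law community spectra:

        G_z = w*^{1-xi} [ a_pz (w/w*)^{1-xi} - b (w/w*)^beta ],
        a_pz = eps (p0 + z0) int x^{gamma-3} s(x) dx.
    """
    a_pz = ps.epsilon * (p0 + z0) * ps.growth_moment(gp)
    w = np.asarray(w, float)
    w_star = np.asarray(w_star, float)
    out = w_star ** (1 - gp.xi) * relative_growth(w / w_star, a_pz, gp,
                                                  alpha=1 - gp.xi)
    return (out if np.ndim(out) else float(out)), float(a_pz)


def zoo_growth_direct(w, eps: float, p_c: Callable, z_c: Callable,
                      ps: PredationSpec, gp: GrowthParams, w_star: float) -> float:
    """Uptake term of G_z by direct quadrature over the prey spectra."""
    val, _ = quad(lambda t: feeding_rate(w, np.exp(t), ps) * np.exp(2 * t)
                  * (p_c(np.exp(t)) + z_c(np.exp(t))),
                  np.log(w) - 40, np.log(w) + 40, epsabs=1e-13, epsrel=1e-10,
                  limit=400)
    return float(eps * val - gp.b * w_star ** (1 - gp.xi) * (w / w_star) ** gp.beta)


def scaling_theorem_check(g_test: float, ps: PredationSpec, gp: GrowthParams,
                          lam: float = 2.0, n_probe: int = 7) -> float:
    """Homogeneity defect of the predation mortality under a trial spectrum
    z_c = w^{-g_test}: max over probe sizes of
    | lam^xi M(lam w) / M(w) - 1 |.  Vanishes iff g_test = 1 + nu + xi."""
    def z_c(w, _g=g_test):
        return w ** (-_g)

    ms = MortalitySpec.zero()
    probes = np.logspace(-1.5, 1.5, n_probe)
    defect = 0.0
    for w in probes:
        m1 = death_rate_direct(w, 1.0, z_c, ps, ms, gp)
        m2 = death_rate_direct(lam * w, lam, z_c, ps, ms, gp)
        defect = max(defect, abs(lam ** gp.xi * m2 / m1 - 1.0))
    return defect


def renormalisation_factor(w_min: float, w_max: float, gamma: float,
                           gp: GrowthParams) -> float:
    """Xi = int_{w_min}^{w_max} w*^{1-xi-gamma} dw* (closed form; +inf when
    the community bounds make the trait integral diverge)."""
    if w_min > w_max:
        raise DomainError("w_min must not exceed w_max")
    expo = 1.0 - gp.xi - gamma
    if w_min == 0.0 and expo <= -1.0:
        return np.inf
    if np.isinf(w_max) and expo >= -1.0:
        return np.inf
    if expo == -1.0:
        return float(np.log(w_max / w_min))
    hi = w_max ** (expo + 1) if not np.isinf(w_max) else 0.0
    lo = w_min ** (expo + 1) if w_min > 0 else 0.0
    return float((hi - lo) / (expo + 1))


# ---------------------------------------------------------------------------
# coupled steady state
# ---------------------------------------------------------------------------

@dataclass
class CommunitySolution:
    """Self-consistent across-species steady state.

    Species abundance normalisations follow p(.|w*) = coeff * w*^{-gamma-1}
    with coeff = p0 / I_p(gamma-1) (idealised) or p0 / J_p(gamma-1)
    (general), and likewise for zooplankton.
    """

    gamma: float
    p0: float
    z0: float
    a_pz: float
    N_hat: float
    a_hat: float
    division: str
    Ip_alpha: float
    Ip_gm1: float
    Iz_gm1: float
    m_spec: MortalitySpec
    phyto_profile: object
    zoo_profile: object
    Xi: Optional[float] = None
    assemblage: Optional[SpeciesAssemblage] = None
    evaluations: int = 0
    trace: List[Tuple[float, float]] = field(default_factory=list)

    @property
    def p_coeff(self) -> float:
        return self.p0 / self.Ip_gm1

    @property
    def z_coeff(self) -> float:
        return self.z0 / self.Iz_gm1

    def p_norm(self, w_star):
        """Phytoplankton normalisation p(w*,w*) (idealised) / p(w_+,w*)."""
        return self.p_coeff * np.asarray(w_star, float) ** (-self.gamma - 1)

    def z_norm(self, w_star):
        return self.z_coeff * np.asarray(w_star, float) ** (-self.gamma - 1)


def zoo_profile(x, a_pz: float, m_shape: Callable, gp: GrowthParams,
                ds: DivisionSpec, n_grid: int = 512):
    """Within-species zooplankton profile: phi or psi with uptake exponent
    1 - xi and coefficient a_pz."""
    if ds.idealised:
        return ideal.phi_profile(x, m_shape, a_pz, gp, alpha=1 - gp.xi)
    return gen.psi_profile(x, ds, m_shape, a_pz, gp, alpha=1 - gp.xi,
                           n_grid=n_grid)


def _phyto_solution(ds, m_spec, gp, nutrient, gamma):
    """Solve the phytoplankton nutrient condition and return
    (N_hat, a_hat, profile, I_alpha, I_gm1)."""
    if ds.idealised:
        N = ideal.solve_nutrient_idealised(m_spec, gp, N_hi=nutrient.N0)
        prof = ideal.build_idealised_profile(m_spec, gp, N_star=N)
        I_a = ideal.profile_moment(prof, gp.alpha)
        I_g = ideal.profile_moment(prof, gamma - 1.0)
    else:
        N = gen.solve_nutrient_general(ds, m_spec, gp, N_hi=nutrient.N0)
        prof = gen.build_general_profile(ds, m_spec, gp, N_star=N)
        I_a = gen.profile_moment(prof, gp.alpha)
        I_g = gen.profile_moment(prof, gamma - 1.0)
    return N, monod_uptake(N, gp), prof, I_a, I_g


def _zoo_uptake(ds, m_spec, gp):
    """Uptake coefficient a_pz satisfying the zooplankton renewal/boundary
    condition at the current mortality."""
    if ds.idealised:
        def f(apz):
            return ideal.coexistence_residual(0.0, m_spec, gp, alpha=1 - gp.xi,
                                              a_val=apz)
        lo = gp.b * (1 + 1e-8)
        hi = 4.0 * max(1.0, gp.b)
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e6:
                raise NoZooplanktonStateError("zooplankton boundary condition unsolvable")
        return brentq(f, lo, hi, xtol=1e-14, rtol=1e-13)
    return gen.solve_uptake_general(ds, m_spec, gp, alpha=1 - gp.xi)


def solve_coupled_steady_state(ps: PredationSpec, ds: DivisionSpec,
                               gp: GrowthParams, nutrient: NutrientState,
                               mb_shape: Optional[Callable] = None,
                               assemblage: Optional[SpeciesAssemblage] = None,
                               z_tol: float = 1e-10,
                               ) -> CommunitySolution:
    """Solve the coupled phyto-zooplankton power-law steady state.

    The scalar residual in the zooplankton coefficient z0,

        F(z0) = a_pz(m(z0)) / (eps * Sg) - p0(z0) - z0,

    compares the total prey spectrum the zooplankton renewal condition
    requires with the prey actually available.  F > 0 means zooplankton are
    underfed (declining), F < 0 overfed (growing); the steady state is the
    sign change, located by Brent bracketing.  A non-negative F at z0 = 0
    means zooplankton cannot invade and no coexistence state exists.
    """
    if mb_shape is None:
        mb_shape = MortalitySpec.constant(0.05).mb_shape
    gamma = ps.gamma(gp)
    Sm = ps.mortality_moment(gp)
    Sg = ps.growth_moment(gp)
    if not np.isfinite(Sm) or not np.isfinite(Sg):
        raise KernelError("preference kernel moments must be finite")

    trace: List[Tuple[float, float]] = []
    cache = {}

    def residual(z0: float) -> float:
        m_spec = predation_mortality_shape(z0, ps, gp, mb_shape)
        N, a_hat, prof, I_a, I_g = _phyto_solution(ds, m_spec, gp, nutrient, gamma)
        p0 = nutrient.theta * nutrient.replenishment(N) * I_g / (a_hat * I_a)
        a_pz = _zoo_uptake(ds, m_spec, gp)
        F = a_pz / (ps.epsilon * Sg) - p0 - z0
        cache[z0] = (m_spec, N, a_hat, prof, I_a, I_g, p0, a_pz)
        trace.append((z0, F))
        return F

    F0 = residual(0.0)
    if F0 >= 0:
        raise NoZooplanktonStateError(
            "no zooplankton-supporting steady state: available prey spectrum "
            f"falls short of the renewal requirement (F(0)={F0:.4g} >= 0)",
            trace=trace)
    z_hi = 0.05
    for _ in range(40):
        try:
            if residual(z_hi) > 0:
                break
        except Exception as exc:  # phytoplankton infeasible at this mortality
            z_hi_bad = z_hi
            z_hi = 0.5 * (trace[-1][0] + z_hi_bad) if trace else z_hi / 2
            continue
        z_hi *= 2.0
    else:
        raise NoZooplanktonStateError(
            "failed to bracket the zooplankton coefficient", trace=trace)

    z_lo = max([z for z, F in trace if F < 0])
    z0 = brentq(residual, z_lo, z_hi, xtol=1e-14, rtol=1e-12)
    m_spec, N, a_hat, prof, I_a, I_g, p0, a_pz = cache[min(
        cache, key=lambda z: abs(z - z0))]

    zprof_m = m_spec
    if ds.idealised:
        zprof = ideal.build_idealised_profile(zprof_m, gp, a_val=a_pz,
                                              alpha=1 - gp.xi)
        Iz_g = ideal.profile_moment(zprof, gamma - 1.0)
    else:
        zprof = gen.build_general_profile(ds, zprof_m, gp, a_val=a_pz,
                                          alpha=1 - gp.xi)
        Iz_g = gen.profile_moment(zprof, gamma - 1.0)

    Xi = None
    if assemblage is not None:
        Xi = renormalisation_factor(assemblage.w_min, assemblage.w_max,
                                    gamma, gp)

    return CommunitySolution(
        gamma=gamma, p0=p0, z0=z0, a_pz=a_pz, N_hat=N, a_hat=a_hat,
        division="idealised" if ds.idealised else "general",
        Ip_alpha=I_a, Ip_gm1=I_g, Iz_gm1=Iz_g, m_spec=m_spec,
        phyto_profile=prof, zoo_profile=zprof, Xi=Xi, assemblage=assemblage,
        evaluations=len(trace), trace=trace)
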