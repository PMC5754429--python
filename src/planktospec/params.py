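"""Model parameters and the four kernel families.

All sizes are dimensionless (measured relative to a reference size of 1), so
allometric exponents act on pure numbers.  The central structural fact of the
model is homogeneity of every rate in (w, w*):

* cell growth rate            ``G(lam w, lam w*) = lam^(1-xi) G(w, w*)``
* division and death rates    scale with exponent ``-xi``
* daughter-size density       scales with exponent ``-1``

so every rate reduces to a shape function of the relative size x = w/w*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import quad

from .errors import DomainError, InfeasibleGrowthError, KernelError

__all__ = [
    "GrowthParams",
    "NutrientState",
    "DivisionSpec",
    "MortalitySpec",
    "SpeciesAssemblage",
    "growth_rate",
    "relative_growth",
    "monod_uptake",
    "nutrient_for_uptake",
    "doubling_time",
    "tau_constant",
    "division_rate",
    "daughter_density",
    "mortality_rate",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthParams:
    """Physiological allometry constants for von Bertalanffy cell growth
    with Monod-limited uptake.

    Parameters
    ----------
    a_inf : float
        Nutrient-saturated uptake coefficient (1/time in dimensionless-size
        units).  Must exceed the metabolic coefficient ``b`` or no cell can
        ever complete a division cycle.
    b : float
        Metabolic loss coefficient.
    alpha, beta : float
        Uptake and metabolic allometric exponents, ``alpha < beta``.
    xi : float
        Doubling-period exponent: the doubling time scales as ``tau * w*^xi``.
    r : float
        Monod half-saturation constant, in nutrient units.
    """

    a_inf: float = 1.4
    b: float = 0.5
    alpha: float = 0.85
    beta: float = 1.0
    xi: float = 0.15
    r: float = 1.0

    def __post_init__(self):
        if not self.alpha < self.beta:
            raise DomainError(f"alpha must be < beta (got {self.alpha} >= {self.beta})")
        if not (self.a_inf > self.b > 0):
            raise DomainError(f"require a_inf > b > 0 (got a_inf={self.a_inf}, b={self.b})")
        if not (0 < self.xi < 1):
            raise DomainError(f"xi must lie in (0, 1) (got {self.xi})")
        if self.r <= 0:
            raise DomainError(f"Monod half-saturation r must be positive (got {self.r})")


@dataclass
class NutrientState:
    """Chemostat state: nutrient concentration and replenishment parameters.

    ``rho0`` is the replenishment rate at zero nutrient, ``N0`` the chemostat
    capacity and ``theta`` the yield (biomass produced per unit nutrient).
    ``N_hat`` optionally holds a renormalised nutrient value used by the
    infinite-community solver.
    """

    N: float = 1.0
    rho0: float = 0.25
    N0: float = 5.0
    theta: float = 1.0
    N_hat: Optional[float] = None

    def __post_init__(self):
        if self.N < 0:
            raise DomainError("nutrient concentration N must be non-negative")
        if self.N0 <= 0 or self.theta <= 0 or self.rho0 < 0:
            raise DomainError("require N0 > 0, theta > 0, rho0 >= 0")

    def replenishment(self, N: Optional[float] = None) -> float:
        """Chemostat inflow rho(N) = rho0 (1 - N/N0)."""
        n = self.N if N is None else N
        return self.rho0 * (1.0 - n / self.N0)


def _check_q_shape(q: Callable[[np.ndarray], np.ndarray], delta: float) -> None:
    lo, hi = (1 - delta) / 2, (1 + delta) / 2
    total, _ = quad(q, lo, hi, epsabs=1e-12, limit=200)
    if abs(total - 1.0) > 1e-8:
        raise KernelError(f"daughter-size density q must integrate to 1 (got {total})")
    xs = np.linspace(lo + 1e-9, hi - 1e-9, 101)
    if not np.allclose(np.asarray(q(xs), float), np.asarray(q(1 - xs), float),
                       rtol=1e-9, atol=1e-9):
        raise KernelError("daughter-size density q must satisfy q(x) = q(1-x)")


def _check_k_divergence(k: Callable, xth: float) -> None:
    # The cumulative division hazard must diverge at x = 1 so that no cell
    # outgrows its maximum size.  Numerical probe: the integral up to 1 - eps
    # must keep growing as eps is squared.  Integrated in u with
    # x = 1 - e^{-u}, which regularises the admissible 1/(1-x) pole.
    span = 1.0 - xth

    def ku(u):
        return k(1 - span * np.exp(-u)) * span * np.exp(-u)

    i1, _ = quad(ku, 0.0, np.log(span / 1e-3), epsabs=1e-10, epsrel=1e-7, limit=400)
    i2, _ = quad(ku, 0.0, np.log(span / 1e-6), epsabs=1e-10, epsrel=1e-7, limit=400)
    i3, _ = quad(ku, 0.0, np.log(span / 1e-12), epsabs=1e-10, epsrel=1e-7, limit=400)
    if not (i3 - i2 > 0.5 * (i2 - i1) > 0):
        raise KernelError("division-rate shape k(x) must have a divergent integral at x=1")


@dataclass(frozen=True)
class DivisionSpec:
    """Division process: rate shape ``k(x)`` on (xth, 1) and daughter-size
    density ``q(x)`` on ((1-delta)/2, (1+delta)/2).

    ``idealised=True`` selects the degenerate process in which cells divide
    exactly at w* into two equal halves (delta-function kernels); the shape
    callables are then unused.
    """

    xth: float = 0.7
    delta: float = 0.2
    k_shape: Optional[Callable] = None
    q_shape: Optional[Callable] = None
    idealised: bool = False
    k_name: str = ""
    q_name: str = ""

    def __post_init__(self):
        if self.idealised:
            return
        if not (0 < self.xth < 1):
            raise KernelError(f"threshold fraction xth must lie in (0,1), got {self.xth}")
        if not (0 < self.delta < 1):
            raise KernelError(f"daughter half-width delta must lie in (0,1), got {self.delta}")
        if not (1 + self.delta) / 2 < self.xth:
            raise KernelError(
                "largest daughter exceeds the division threshold: require "
                f"(1+delta)/2 < xth, got (1+{self.delta})/2 = {(1 + self.delta) / 2} "
                f">= {self.xth}")
        if self.k_shape is None or self.q_shape is None:
            raise KernelError("sloppy division requires both k_shape and q_shape")
        _check_q_shape(self.q_shape, self.delta)
        _check_k_divergence(self.k_shape, self.xth)

    # -- derived geometry ---------------------------------------------------
    @property
    def x_plus(self) -> float:
        """Largest relative daughter size w_+/w* = (1+delta)/2."""
        return 0.5 if self.idealised else (1 + self.delta) / 2

    @property
    def x_lo(self) -> float:
        """Smallest relative size any cell can have: xth (1-delta)/2."""
        return 0.5 if self.idealised else self.xth * (1 - self.delta) / 2

    def k(self, x):
        """Division-rate shape; 0 below threshold, +inf at x = 1."""
        scalar = np.ndim(x) == 0
        x = np.atleast_1d(np.asarray(x, float))
        out = np.zeros(x.shape)
        inside = (x > self.xth) & (x < 1.0)
        if np.any(inside):
            out[inside] = self.k_shape(x[inside])
        out[x >= 1.0] = np.inf
        return float(out[0]) if scalar else out

    def q(self, x):
        """Daughter-size density shape; 0 outside ((1-delta)/2, (1+delta)/2)."""
        x = np.asarray(x, float)
        lo, hi = (1 - self.delta) / 2, (1 + self.delta) / 2
        out = np.where((x > lo) & (x < hi), self.q_shape(np.clip(x, lo, hi)), 0.0)
        return out if out.ndim else float(out)

    # -- canonical shape constructors ----------------------------------------
    @classmethod
    def sloppy(cls, xth: float = 0.7, delta: float = 0.2,
               k_shape: str = "power_pole", q_shape: str = "uniform",
               k_coef: float = 4.0, k_power: float = 2.0) -> "DivisionSpec":
        """Sloppy size control with registered shape functions.

        ``power_pole``: k(x) = k_coef (x - xth)^k_power / (1 - x) — the
        canonical choice with k_coef=4, k_power=2, xth=0.7.
        ``uniform`` / ``triangular``: daughter sizes on ((1-delta)/2, (1+delta)/2).
        """
        if k_shape == "power_pole":
            def kfun(x, _c=k_coef, _p=k_power, _t=xth):
                return _c * (x - _t) ** _p / (1.0 - x)
        else:
            raise KernelError(f"unknown division-rate shape {k_shape!r}")
        lo, hi = (1 - delta) / 2, (1 + delta) / 2
        if q_shape == "uniform":
            def qfun(x, _lo=lo, _hi=hi):
                return np.full_like(np.asarray(x, float), 1.0 / (_hi - _lo))
        elif q_shape == "triangular":
            def qfun(x, _lo=lo, _hi=hi):
                x = np.asarray(x, float)
                half = (_hi - _lo) / 2
                return np.maximum(0.0, (half - np.abs(x - 0.5)) / half ** 2)
        else:
            raise KernelError(f"unknown daughter-size shape {q_shape!r}")
        return cls(xth=xth, delta=delta, k_shape=kfun, q_shape=qfun,
                   k_name=k_shape, q_name=q_shape)

    @classmethod
    def exact_halving(cls) -> "DivisionSpec":
        """Idealised process: split exactly at w* into two equal halves."""
        return cls(idealised=True)


@dataclass(frozen=True)
class MortalitySpec:
    """Death-rate shape m(x) in M(w, w*) = w*^(-xi) m(w/w*).

    ``mb_shape`` is the background component; ``composed_m`` the total shape
    including any predation contribution (defaults to the background alone).
    """

    mb_shape: Callable = field(default=lambda x: np.zeros_like(np.asarray(x, float)))
    composed_m: Optional[Callable] = None

    @property
    def m(self) -> Callable:
        return self.composed_m if self.composed_m is not None else self.mb_shape

    def __call__(self, x):
        val = np.asarray(self.m(np.asarray(x, float)), float)
        if np.any(val < 0):
            raise DomainError("mortality shape m(x) must be non-negative")
        return val if val.ndim else float(val)

    @classmethod
    def constant(cls, m0: float) -> "MortalitySpec":
        if m0 < 0:
            raise DomainError("constant mortality must be non-negative")
        return cls(mb_shape=lambda x, _m=m0: np.full_like(np.asarray(x, float), _m))

    @classmethod
    def zero(cls) -> "MortalitySpec":
        return cls.constant(0.0)


@dataclass(frozen=True)
class SpeciesAssemblage:
    """A finite set of characteristic sizes w* within community bounds."""

    w_stars: np.ndarray
    w_min: float
    w_max: float

    def __post_init__(self):
        ws = np.asarray(self.w_stars, float)
        object.__setattr__(self, "w_stars", ws)
        if ws.size < 1 or np.any(ws <= 0) or self.w_min <= 0:
            raise DomainError("assemblage sizes must be strictly positive")
        if not (self.w_min <= ws.min() and ws.max() <= self.w_max):
            raise DomainError("w_stars must lie within [w_min, w_max]")
        if np.any(np.diff(ws) <= 0):
            raise DomainError("w_stars must be strictly increasing")

    @property
    def n_species(self) -> int:
        return int(self.w_stars.size)

    def trapezoid_weights(self) -> np.ndarray:
        """Weights approximating an integral over w* by a sum over species
        (trapezoid rule in log w*, multiplied back by w*)."""
        ws = self.w_stars
        if ws.size == 1:
            return np.array([ws[0] * np.log(self.w_max / self.w_min)])
        lw = np.log(ws)
        dl = np.zeros_like(lw)
        dl[1:-1] = (lw[2:] - lw[:-2]) / 2
        dl[0] = lw[1] - lw[0]
        dl[-1] = lw[-1] - lw[-2]
        # endpoints inset by half a log-step get full-step weights
        return ws * dl


# ---------------------------------------------------------------------------
# rate functions
# ---------------------------------------------------------------------------

def relative_growth(x, a_val: float, gp: GrowthParams, alpha: Optional[float] = None):
    """Relative-size growth shape g(x) = a x^alpha - b x^beta.

    ``alpha`` may be overridden (the zooplankton growth rate uses 1 - xi)."""
    al = gp.alpha if alpha is None else alpha
    x = np.asarray(x, float)
    out = a_val * x ** al - gp.b * x ** gp.beta
    return out if out.ndim else float(out)


def growth_rate(w, w_star, gp: GrowthParams, a_val: float,
                alpha: Optional[float] = None):
    """Cell mass growth rate G(w, w*) = w*^(1-xi) g(w/w*)."""
    w = np.asarray(w, float)
    w_star = np.asarray(w_star, float)
    if np.any(w <= 0) or np.any(w_star <= 0):
        raise DomainError("sizes must be strictly positive")
    out = w_star ** (1 - gp.xi) * relative_growth(w / w_star, a_val, gp, alpha)
    return out if np.ndim(out) else float(out)


def monod_uptake(N, gp: GrowthParams):
    """Monod uptake coefficient a(N) = a_inf N / (r + N)."""
    N = np.asarray(N, float)
    if np.any(N < 0):
        raise DomainError("nutrient concentration must be non-negative")
    out = gp.a_inf * N / (gp.r + N)
    return out if out.ndim else float(out)


def nutrient_for_uptake(a_val: float, gp: GrowthParams) -> float:
    """Invert the Monod curve: the N at which a(N) = a_val."""
    if not 0 <= a_val < gp.a_inf:
        raise DomainError("uptake coefficient must lie in [0, a_inf)")
    return gp.r * a_val / (gp.a_inf - a_val)


def tau_constant(gp: GrowthParams, a_val: float) -> float:
    """Species-independent doubling-time constant
    tau = int_{1/2}^{1} du / (a u^alpha - b u^beta)."""
    if a_val <= gp.b:
        raise InfeasibleGrowthError(
            f"uptake a={a_val} does not exceed metabolism b={gp.b}: growth stalls")
    val, _ = quad(lambda u: 1.0 / relative_growth(u, a_val, gp), 0.5, 1.0,
                  epsabs=1e-14, epsrel=1e-13, limit=200)
    return val


def doubling_time(w_star: float, gp: GrowthParams, a_val: float) -> float:
    """Doubling period T(w*) = tau w*^xi (time to grow from w*/2 to w*)."""
    if w_star <= 0:
        raise DomainError("w_star must be positive")
    return tau_constant(gp, a_val) * w_star ** gp.xi


def division_rate(w, w_star, ds: DivisionSpec, gp: GrowthParams):
    """Division rate K(w, w*) = w*^(-xi) k(w/w*); +inf at the pole w = w*."""
    if ds.idealised:
        raise DomainError("division_rate is undefined for the idealised process "
                          "(the rate is a delta function at w = w*)")
    w = np.asarray(w, float)
    w_star = np.asarray(w_star, float)
    if np.any(w <= 0) or np.any(w_star <= 0):
        raise DomainError("sizes must be strictly positive")
    out = w_star ** (-gp.xi) * ds.k(w / w_star)
    return out if np.ndim(out) else float(out)


def daughter_density(w, w_parent, ds: DivisionSpec):
    """Daughter-size density Q(w | w') = q(w/w') / w'."""
    w = np.asarray(w, float)
    if np.any(np.asarray(w_parent, float) <= 0):
        raise DomainError("parent size must be positive")
    out = ds.q(w / w_parent) / w_parent
    return out if np.ndim(out) else float(out)


def mortality_rate(w, w_star, ms: MortalitySpec, gp: GrowthParams):
    """Death rate M(w, w*) = w*^(-xi) m(w/w*)."""
    w = np.asarray(w, float)
    w_star = np.asarray(w_star, float)
    out = w_star ** (-gp.xi) * ms(w / w_star)
    return out if np.ndim(out) else float(out)
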