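"""Canonical parameter sets and species assemblages.

The canonical single-species setup uses the growth constants a = 0.7,
b = 0.5, alpha = 0.85, beta = 1, a division threshold at 0.7 w* with rate
shape k(x) = 4 (x - 0.7)^2 / (1 - x), daughter sizes uniform on
[0.4, 0.6] w*, and doubling-period exponent xi = 0.15.  Chemostat and
predation parameters are not constrained by the within-species theory; the
defaults below are the package's recorded choices and are echoed into every
output header.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .params import (DivisionSpec, GrowthParams, MortalitySpec, NutrientState,
                     SpeciesAssemblage)
from .predation import PredationSpec

__all__ = [
    "canonical_growth",
    "canonical_division",
    "canonical_idealised_division",
    "canonical_mortality",
    "canonical_chemostat",
    "canonical_predation",
    "CANONICAL_UPTAKE",
    "make_assemblage",
]

#: nutrient-saturated uptake level used in single-species examples
CANONICAL_UPTAKE = 0.7


def canonical_growth() -> GrowthParams:
    """Growth constants with a Monod curve reaching a(N) = 0.7 at N = r.

    ``a_inf = 1.4`` is twice the canonical uptake 0.7, so the canonical level
    sits at the half-saturation point of the Monod curve."""
    return GrowthParams(a_inf=1.4, b=0.5, alpha=0.85, beta=1.0, xi=0.15, r=1.0)


def canonical_division() -> DivisionSpec:
    """Sloppy size control: threshold 0.7, k(x) = 4 (x-0.7)^2/(1-x),
    daughters uniform on [0.4, 0.6] of the parent (delta = 0.2)."""
    return DivisionSpec.sloppy(xth=0.7, delta=0.2,
                               k_shape="power_pole", q_shape="uniform",
                               k_coef=4.0, k_power=2.0)


def canonical_idealised_division() -> DivisionSpec:
    return DivisionSpec.exact_halving()


def canonical_mortality(m0: float = 0.1) -> MortalitySpec:
    """Constant background mortality shape, default m0 = 0.1."""
    return MortalitySpec.constant(m0)


def canonical_chemostat(N: float = 1.0) -> NutrientState:
    """Chemostat defaults: rho0 = 0.25, N0 = 5, theta = 1."""
    return NutrientState(N=N, rho0=0.25, N0=5.0, theta=1.0)


def canonical_predation() -> PredationSpec:
    """Foraging exponent nu = 0.85 (so gamma = 2 with xi = 0.15), log-normal
    prey preference with mode 100 and log-width 1, efficiency 0.6."""
    return PredationSpec(nu=0.85, epsilon=0.6, ratio_mode=100.0,
                         ratio_width=1.0)


def make_assemblage(n_species: int, w_min: float = 1e-3, w_max: float = 1e3,
                    spacing: str = "log") -> SpeciesAssemblage:
    """Log-spaced species traits on [w_min, w_max], endpoints inset by half
    a log-step so trapezoid weights tile the range exactly."""
    if n_species < 1:
        raise ValueError("need at least one species")
    if spacing != "log":
        raise ValueError(f"unknown spacing {spacing!r}")
    if n_species == 1:
        ws = np.array([np.sqrt(w_min * w_max)])
    else:
        step = (np.log(w_max) - np.log(w_min)) / n_species
        ws = np.exp(np.log(w_min) + step * (0.5 + np.arange(n_species)))
    return SpeciesAssemblage(w_stars=ws, w_min=w_min, w_max=w_max)
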