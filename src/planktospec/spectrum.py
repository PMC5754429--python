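"""Community-level diagnostics: assembling the across-species size spectrum,
fitting its power-law exponent, the Sheldon biomass-per-log-bin flatness
statistic, and the profile-collapse audit of scale invariance.

The community spectrum is the trait integral p_c(w) = int p(w, w*) dw*.  On
the analytic coupled steady state this is an exact power law p0 w^{-gamma}
away from the [w_min, w_max] edges; gamma = 2 makes biomass per logarithmic
size bin exactly flat (the Sheldon observation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import quad

from .errors import DomainError, EstimationError
from .params import SpeciesAssemblage
from .pbe import PBEState, SimGrid
from .predation import CommunitySolution

__all__ = [
    "CommunitySpectrumTable",
    "community_spectrum",
    "spectrum_from_state",
    "fit_exponent",
    "sheldon_flatness",
    "collapse_profiles",
]


@dataclass
class CommunitySpectrumTable:
    w_grid: np.ndarray
    p_c: np.ndarray
    z_c: Optional[np.ndarray] = None
    fitted_gamma: Optional[float] = None
    fit_window: Optional[Tuple[float, float]] = None
    fit_residual: Optional[float] = None
    meta: dict = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        return self.p_c if self.z_c is None else self.p_c + self.z_c


def community_spectrum(solution: CommunitySolution,
                       assemblage: Optional[SpeciesAssemblage] = None,
                       w_grid: Optional[np.ndarray] = None,
                       n_grid: int = 256) -> CommunitySpectrumTable:
    """Trait-integrate the analytic coupled steady state.

    With ``assemblage=None`` the continuum integral over w* is evaluated by
    adaptive quadrature within the solution's bounds (defaulting to an
    unbounded community, for which the result is the exact power law);
    otherwise a finite log-spaced species sum with trapezoid weights."""
    asm = assemblage if assemblage is not None else solution.assemblage
    w_lo = asm.w_min if asm is not None else 1e-3
    w_hi = asm.w_max if asm is not None else 1e3
    if w_grid is None:
        w_grid = np.geomspace(w_lo, w_hi, n_grid)

    pprof = solution.phyto_profile
    zprof = solution.zoo_profile
    pc = np.zeros(w_grid.size)
    zc = np.zeros(w_grid.size)
    gamma = solution.gamma

    if assemblage is None:
        # continuum: p_c(w) = int_{max(w, w_lo)}^{w_hi} coeff w*^{-gamma-1}
        #                     profile(w/w*) w.r.t. w*
        for i, w in enumerate(w_grid):
            lo = max(w, w_lo)
            for coeff, prof, acc in ((solution.p_coeff, pprof, pc),
                                     (solution.z_coeff, zprof, zc)):
                # substitute u = w / w*; restrict to the profile support
                u_lo = max(w / w_hi, getattr(prof, "x_support", 0.0))
                u_hi = min(w / lo, 1.0)
                if u_lo >= u_hi:
                    continue
                val, _ = quad(lambda u: coeff * (w / u) ** (-gamma - 1)
                              * prof(u) * w / u ** 2,
                              u_lo, u_hi, epsabs=1e-12, epsrel=1e-9, limit=200)
                acc[i] += val
    else:
        tw = assemblage.trapezoid_weights()
        for ws, wt in zip(assemblage.w_stars, tw):
            x = w_grid / ws
            sel = (x > 0) & (x <= 1.0)
            pc[sel] += wt * solution.p_norm(ws) * np.asarray(pprof(x[sel]), float)
            zc[sel] += wt * solution.z_norm(ws) * np.asarray(zprof(x[sel]), float)

    return CommunitySpectrumTable(w_grid=w_grid, p_c=pc, z_c=zc,
                                  meta={"gamma": gamma,
                                        "w_min": w_lo, "w_max": w_hi})


def spectrum_from_state(state: PBEState, grid: SimGrid,
                        w_grid: Optional[np.ndarray] = None
                        ) -> CommunitySpectrumTable:
    """Community spectrum of a simulated state: each (species, cell) parcel
    contributes density n_s(x)/w* per unit absolute size, binned onto a log
    grid of w."""
    wabs = (state.w_stars[:, None] * grid.centers[None, :]).ravel()
    if w_grid is None:
        w_grid = np.geomspace(wabs.min(), wabs.max(), 128)
    edges = np.sqrt(w_grid[1:] * w_grid[:-1])
    edges = np.concatenate([[w_grid[0] * (w_grid[0] / edges[0])], edges,
                            [w_grid[-1] * (w_grid[-1] / edges[-1])]])
    dw = np.diff(edges)

    def binned(dens):
        num = (dens * grid.widths[None, :]).ravel()
        idx = np.searchsorted(edges, wabs) - 1
        ok = (idx >= 0) & (idx < w_grid.size)
        out = np.bincount(idx[ok], weights=num[ok], minlength=w_grid.size)
        return out / dw

    pc = binned(state.p)
    zc = binned(state.z) if state.z is not None else None
    return CommunitySpectrumTable(w_grid=w_grid, p_c=pc, z_c=zc)


def fit_exponent(table: CommunitySpectrumTable,
                 window: Tuple[float, float],
                 use_total: bool = True) -> float:
    """Least-squares slope of log density vs log w inside the window,
    sign-flipped so a pure power law w^{-gamma} returns gamma."""
    lo, hi = window
    sel = (table.w_grid >= lo) & (table.w_grid <= hi)
    if sel.sum() < 10:
        raise EstimationError("need at least 10 grid points in the fit window")
    dens = (table.total if use_total else table.p_c)[sel]
    if np.any(dens <= 0):
        raise EstimationError("non-positive densities in the fit window")
    lw = np.log(table.w_grid[sel])
    coef, res = np.polyfit(lw, np.log(dens), 1, full=False), None
    fit = np.polyval(coef, lw)
    table.fitted_gamma = float(-coef[0])
    table.fit_window = (lo, hi)
    table.fit_residual = float(np.sqrt(np.mean((fit - np.log(dens)) ** 2)))
    return table.fitted_gamma


def sheldon_flatness(table: CommunitySpectrumTable,
                     bins_per_decade: float = 8,
                     window: Optional[Tuple[float, float]] = None) -> float:
    """Max relative deviation of biomass per logarithmic size bin.

    Biomass per bin is int w * density dw over each log bin; returns
    (max/min - 1) across bins.  Exactly 0 for a w^{-2} spectrum."""
    w = table.w_grid
    dens = table.total
    if window is not None:
        sel = (w >= window[0]) & (w <= window[1])
        w, dens = w[sel], dens[sel]
    n_bins = max(1, int(round(np.log10(w[-1] / w[0]) * bins_per_decade)))
    edges = np.geomspace(w[0], w[-1], n_bins + 1)
    biomass = np.empty(n_bins)
    lw = np.log(w)
    integrand = w ** 2 * dens        # biomass density per unit log w
    for i in range(n_bins):
        sel = (w >= edges[i]) & (w <= edges[i + 1])
        if sel.sum() < 2:
            raise EstimationError(f"empty log bin [{edges[i]:.3g}, {edges[i+1]:.3g}]")
        biomass[i] = np.trapezoid(integrand[sel], lw[sel]) / (lw[sel][-1] - lw[sel][0])
    if np.any(biomass <= 0):
        raise EstimationError("non-positive biomass in a log bin")
    return float(biomass.max() / biomass.min() - 1.0)


def collapse_profiles(profiles: Sequence[Tuple[float, np.ndarray, np.ndarray]],
                      gamma: float, n_common: int = 200) -> float:
    """Scale-invariance audit: rescale each species' absolute-size profile
    (w_star, w, p(w, w_star)) by w*^{gamma+1}, overlay on x = w/w*, and
    return the maximum pairwise L1 distance (0 for a perfect collapse).

    Each rescaled profile is f(x) = w*^{gamma+1} p(x w*, w*)."""
    if len(profiles) == 0:
        raise DomainError("no profiles supplied")
    xs_common = np.linspace(0.05, 1.0, n_common)
    curves = []
    for w_star, w, dens in profiles:
        x = np.asarray(w, float) / w_star
        f = w_star ** (gamma + 1.0) * np.asarray(dens, float)
        curves.append(np.interp(xs_common, x, f, left=0.0, right=0.0))
    worst = 0.0
    scale = max(float(np.trapezoid(np.abs(c), xs_common)) for c in curves)
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            d = float(np.trapezoid(np.abs(curves[i] - curves[j]), xs_common))
            worst = max(worst, d / max(scale, 1e-300))
    return worst
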