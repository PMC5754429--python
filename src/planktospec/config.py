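"""Structured-text (YAML) run configuration with full invariant validation.

A config file mirrors the parameter types section by section::

    growth:      {a_inf, b, alpha, beta, xi, r}
    division:    {kind: sloppy|idealised, xth, delta, k_shape, q_shape, ...}
    mortality:   {m0}
    predation:   {nu, epsilon, ratio_mode, ratio_width}
    chemostat:   {N, rho0, N0, theta}
    assemblage:  {n_species, w_min, w_max}
    run:         {seed, n_cells, x_min, spacing, cfl}

Unknown keys are rejected; every defaulted value is materialised so the
echoed config reproduces the run exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml

from .errors import ConfigError, DomainError, KernelError
from .fixtures import (canonical_chemostat, canonical_division,
                       canonical_growth, canonical_idealised_division,
                       canonical_mortality, canonical_predation,
                       make_assemblage)
from .params import (DivisionSpec, GrowthParams, MortalitySpec, NutrientState,
                     SpeciesAssemblage)
from .predation import PredationSpec

__all__ = ["RunConfig", "load_config", "default_config_dict"]

_SECTIONS = {"growth", "division", "mortality", "predation", "chemostat",
             "assemblage", "run"}

_DEFAULTS = {
    "growth": {"a_inf": 1.4, "b": 0.5, "alpha": 0.85, "beta": 1.0,
               "xi": 0.15, "r": 1.0},
    "division": {"kind": "sloppy", "xth": 0.7, "delta": 0.2,
                 "k_shape": "power_pole", "q_shape": "uniform",
                 "k_coef": 4.0, "k_power": 2.0},
    "mortality": {"m0": 0.1},
    "predation": {"nu": 0.85, "epsilon": 0.6, "ratio_mode": 100.0,
                  "ratio_width": 1.0},
    "chemostat": {"N": 1.0, "rho0": 0.25, "N0": 5.0, "theta": 1.0},
    "assemblage": {"n_species": 1, "w_min": 1e-3, "w_max": 1e3},
    "run": {"seed": 0, "n_cells": 512, "x_min": 0.14, "spacing": "log",
            "cfl": 0.5},
}


@dataclass
class RunConfig:
    growth: GrowthParams
    division: DivisionSpec
    mortality: MortalitySpec
    predation: PredationSpec
    chemostat: NutrientState
    assemblage: SpeciesAssemblage
    seed: int = 0
    n_cells: int = 512
    x_min: float = 0.14
    spacing: str = "log"
    cfl: float = 0.5
    echo: dict = field(default_factory=dict)

    def echo_lines(self) -> list:
        """Fully materialised parameter echo for output headers."""
        out = []
        for sec in sorted(self.echo):
            for key in sorted(self.echo[sec]):
                out.append(f"{sec}.{key} = {self.echo[sec][key]}")
        return out


def default_config_dict() -> dict:
    return {sec: dict(vals) for sec, vals in _DEFAULTS.items()}


def _merge(section: str, user: dict) -> dict:
    merged = dict(_DEFAULTS[section])
    for key, val in (user or {}).items():
        if key not in merged:
            raise ConfigError(f"{section}.{key}", "unknown key")
        merged[key] = val
    return merged


def _build(data: dict, require_all: bool = False) -> RunConfig:
    unknown = set(data) - _SECTIONS
    if unknown:
        raise ConfigError(sorted(unknown)[0], "unknown section")
    if require_all:
        missing = _SECTIONS - set(data)
        if missing:
            raise ConfigError(sorted(missing)[0], "missing section")

    sec = {name: _merge(name, data.get(name)) for name in _SECTIONS}

    g = sec["growth"]
    if g["alpha"] >= g["beta"]:
        raise ConfigError("growth.alpha", f"uptake exponent alpha={g['alpha']} must be "
                          f"smaller than metabolic exponent beta={g['beta']}")
    if g["a_inf"] <= g["b"]:
        raise ConfigError("growth.a_inf", f"saturated uptake a_inf={g['a_inf']} must "
                          f"exceed metabolism b={g['b']}")
    try:
        growth = GrowthParams(**g)
    except DomainError as exc:
        raise ConfigError("growth", str(exc)) from exc

    d = sec["division"]
    kind = d.pop("kind")
    if kind == "idealised":
        division = DivisionSpec.exact_halving()
    elif kind == "sloppy":
        if (1 + d["delta"]) / 2 >= d["xth"]:
            raise ConfigError(
                "division.xth", "largest daughter exceeds the division threshold: "
                f"require (1+delta)/2 < xth, got {(1 + d['delta']) / 2} >= {d['xth']}")
        try:
            division = DivisionSpec.sloppy(**d)
        except KernelError as exc:
            raise ConfigError("division", str(exc)) from exc
    else:
        raise ConfigError("division.kind", f"must be 'sloppy' or 'idealised', got {kind!r}")
    d["kind"] = kind

    try:
        mortality = MortalitySpec.constant(sec["mortality"]["m0"])
        predation = PredationSpec(**sec["predation"])
        chemostat = NutrientState(**sec["chemostat"])
        asm = sec["assemblage"]
        assemblage = make_assemblage(asm["n_species"], asm["w_min"], asm["w_max"])
    except (DomainError, ValueError) as exc:
        raise ConfigError("config", str(exc)) from exc

    run = sec["run"]
    return RunConfig(growth=growth, division=division, mortality=mortality,
                     predation=predation, chemostat=chemostat,
                     assemblage=assemblage, seed=int(run["seed"]),
                     n_cells=int(run["n_cells"]), x_min=float(run["x_min"]),
                     spacing=run["spacing"], cfl=float(run["cfl"]), echo=sec)


def load_config(path: Optional[str] = None, text: Optional[str] = None,
                require_all: Optional[bool] = None) -> RunConfig:
    """Load and validate a YAML config; ``text`` may be passed directly.

    A config read from a file (or text) must spell out every section;
    ``load_config()`` with no arguments yields the fully defaulted setup.
    Keys omitted inside a present section fall back to their defaults and
    are materialised in the echo."""
    if text is None:
        if path is None:
            data = {}
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config", "top level must be a mapping of sections")
    if require_all is None:
        require_all = path is not None or text is not None
    return _build(data, require_all=require_all)
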