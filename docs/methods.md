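# Methods

## Model

`planktospec` implements a trait-based size-spectrum model of unicellular
plankton. A species is indexed by its characteristic (maximum) cell size
w\*, and its population is resolved in current cell size w. Sizes are
dimensionless (measured against a reference size of 1). Four processes
drive the dynamics, each an allometrically scaling rate:

- **Growth** (von Bertalanffy with Monod-limited uptake):
  G(w, w\*) = w\*^(1−ξ) [a(N) x^α − b x^β] with x = w/w\* and
  a(N) = a∞ N/(r+N). Growth requires a(N) > b.
- **Division** (sloppy size control): cells above a threshold fraction
  x_th divide at rate K = w\*^(−ξ) k(x), with k carrying a 1/(1−x) pole so
  the cumulative hazard diverges and no cell outgrows w\*. Daughter sizes
  follow a symmetric density q on ((1−δ)/2, (1+δ)/2) of the parent size.
  The idealised variant divides exactly at w\* into two equal halves.
- **Death**: M = w\*^(−ξ) m(x), background plus (in the community model)
  predation by larger cells.
- **Predation**: S(w, w′) = w^ν s(w/w′), a foraging factor times a
  preference kernel of the predator:prey size ratio.

The homogeneity degrees (1−ξ for growth, −ξ for division and death, −1 for
the daughter density, ν for predation) mean every within-species quantity
reduces to a shape function of x, which is why a single relative-size
profile describes all coexisting species — the model's resolution of the
paradox of the plankton — and why the community spectrum is a power law
w^(−γ) with γ = 1 + ν + ξ. With the empirical ν = 0.85 and ξ = 0.15, γ = 2:
constant biomass per logarithmic size interval (the Sheldon spectrum).

## Steady states

*Idealised division.* The within-species profile is
φ(x) = (a−b)/g(x) · exp(∫_x^1 m/g dy) on [1/2, 1], with g(x) = a x^α − b x^β.
Coexistence of every species requires ∫_{1/2}^1 m/g dx = log 2, which pins
the nutrient level N\*; equivalently the boundary flux ratio
G(w\*/2)φ(1/2) / G(w\*)φ(1) equals 2 (two daughters per division). Both
routes are implemented: the closed-form integral with a Brent root in N,
and an independent ODE-shooting solver that integrates the steady transport
equation downward from x = 1 and imposes the flux ratio directly.

*Sloppy size control.* The profile factorises through a survival factor
e(x) (through division and death hazards, e((1+δ)/2) = 1, e(1) = 0), a
renewal density h(x) (daughters per unit relative size, supported on
(x_th(1−δ)/2, (1+δ)/2)), and the cumulative renewal fraction Θ. The
steady-state nutrient satisfies ∫_0^{(1+δ)/2} h/e dx = 1 — one surviving
descendant per cell. At zero mortality this integral equals exactly 2 (two
daughters each certain to survive); the package uses this identity as a
quadrature self-check. In a nutrient-rich, death-free culture the same
renewal structure with the exponential rate Λ in place of mortality becomes
an eigenvalue problem; Λ = ℓ w\*^(−ξ) with ℓ independent of species.

*Coupled community.* On power-law spectra the predation integrals collapse
to two moments of the preference kernel: the induced mortality shape
m(x) = m_b(x) + z₀ x^(−ξ) ∫ y^(−ξ−1) s(y) dy and the zooplankton uptake
a_pz = ε (p₀ + z₀) ∫ x^(γ−3) s(x) dx. The coupled steady state solves one
scalar equation in the zooplankton coefficient z₀: the residual
F(z₀) = a_pz(m(z₀))/(ε S_g) − p₀(z₀) − z₀ compares the prey spectrum the
zooplankton renewal condition requires with the prey actually present
(F > 0: zooplankton underfed and declining; F < 0: growing). The root is
located by Brent bracketing. A plain damped fixed-point iteration on the
same map is not contracting here — the map slope at the equilibrium exceeds
one (≈1.7 at the default parameters) — which is why a bracketed scalar
root solve was chosen; the iteration trace is still recorded. F(0) ≥ 0
means zooplankton cannot invade at all and is reported as a distinct
no-coexistence outcome rather than clipped.

The trait integral over an unbounded community diverges; all
nutrient-related quantities are treated per unit of the renormalisation
factor Ξ = ∫ w\*^(1−ξ−γ) dw\*. Because the Monod ratio is invariant under a
common rescaling of N, r and N₀, the chemostat section of a config simply
holds the renormalised values. Finite assemblages multiply back by their
finite Ξ.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| a∞, b | 1.4, 0.5 | saturated uptake, metabolic loss (1/time) |
| α, β | 0.85, 1.0 | uptake / metabolic exponents |
| ξ | 0.15 | doubling-period exponent, T = τ w\*^ξ |
| x_th, δ | 0.7, 0.2 | division threshold fraction, daughter half-width |
| k(x) | 4(x−0.7)²/(1−x) | division-rate shape |
| q | uniform on [0.4, 0.6] | daughter-size density |
| m₀ | 0.1 (single species), 0.05 background (community) | constant mortality shape |
| ν, ε | 0.85, 0.6 | foraging exponent, conversion efficiency |
| s | log-normal, mode 100, log-width 1 | prey-preference kernel |
| r, N₀, ϱ₀, θ | 1, 5, 0.25, 1 | Monod half-saturation, chemostat capacity/rate, yield |

The growth/division constants and ν, ξ are the canonical set used
throughout; the chemostat numbers are the package's own recorded choice
(nothing in the within-species theory constrains them) — a∞ is set to twice
the canonical uptake 0.7 so that level sits at the Monod half-saturation,
and ϱ₀ is small enough that the phytoplankton standing stock leaves room
for a viable zooplankton community. ε = 0.6 is at the upper end of reported
gross growth efficiencies for unicellular grazers; below ≈0.45 with the
mode-100 preference the model's zooplankton cannot invade (the package
reports this regime explicitly, and a test pins it at ε = 0.3). Time units
are free: only ratios of rates matter.

## Numerics

- **Pole handling.** k has a simple pole at x = 1, so the cumulative
  hazard is log-divergent there. Grids and panel quadratures near the pole
  use x = 1 − e^(−u); the survival factor then decays as (1−x)^c with
  c = k-residue/g(1), reaching exactly 0 at x = 1 (never NaN).
- **Quadratures.** Profile builders use composite 16/32-point
  Gauss–Legendre panels with cumulative tables and shape-preserving (PCHIP)
  interpolation; the renewal integral swaps the order of the (x, y) double
  integral so both passes are smooth. Pointwise oracle-grade versions of
  e and h via adaptive quadrature are kept alongside and used in tests.
  Root solves (nutrient, uptake, eigenvalue, z₀) use Brent bracketing with
  relative tolerances 1e−12 or tighter.
- **Eigenvalue in absolute coordinates.** The growth eigenvalue is solved
  entirely in absolute size w (no scaling shortcut): panel meshes are laid
  out proportionally to w\* so the pole at w = w\* is equally resolved for
  every species, and the fitted log Λ–log w\* slope reproduces −ξ to
  machine precision.
- **PBE discretisation.** Per-species relative-size grid shared across
  species (all rates are homogeneous, so one division matrix serves all).
  First-order conservative upwind advection; explicit Euler with a combined
  CFL/sink bound dt ≤ cfl/max(v/Δx + k + m); densities remain non-negative
  by construction. The discrete division operator allocates each parent's
  daughters by exact integrals of q over receiving cells, then applies a
  two-moment correction so every division yields exactly two daughters
  carrying exactly the parent's biomass (machine-precision number and
  biomass bookkeeping). Idealised division is a reinjection boundary
  condition: the flux through x = 1 reappears doubled at x = 1/2.
- **Grids.** 512 geometric cells on [0.14, 1] by default; the
  division-wave bookkeeping run uses 1024 (the leak of cells past x = 1
  before dividing scales like Δx^c and must stay below 1e−3); the
  scale-invariance audit uses 96 cells to keep the pairwise predation sums
  cheap. The chemostat run settles its nutrient to a relative spread below
  1e−9 over the trailing window before measurement.
- **Community coupling.** For dynamic states the predation mortality and
  zooplankton uptake are evaluated by direct sums over all (species × cell)
  parcels, chunked to bound memory; for power-law closures the closed-form
  moment expressions are used and cross-checked against the direct
  integrals in tests.

## What the simulator does and does not emulate

The PBE simulator evolves the same deterministic continuum equations the
analytic solutions solve; it is an independent *numerical* route, not an
independent *biological* model. Agreement between the two (settled nutrient,
profile shape, growth rate, scale-invariance residuals) validates the
analysis and the discretisation against each other. It does not test
demographic stochasticity, seasonality, multiple nutrients, behavioural
adaptation of the preference kernel, or species-dependent predation — all
outside the model class. Default initial conditions (Gaussian cohort at
x = 0.5, width 0.05) are a fixture choice; steady-state results are
insensitive to them, transient results are not.

## Known limitations

- The idealised division model has periodic, non-convergent dynamics by
  construction; its "steady state" is meaningful as a time-average and is
  verified through the flux boundary condition, not through settling.
- First-order upwind advection introduces numerical diffusion; steady
  profiles converge at first order, so tight profile comparisons use the
  analytic builders, and dynamic comparisons carry ~1e−2 L1 tolerances at
  512 cells.
- The linear stability of the coupled steady state is not analysed here;
  the solver finds the steady state, and the scale-invariance audit checks
  it is (numerically) steady, nothing more.
- Finite assemblages truncate the power-law spectrum; fits exclude one
  decade at each end, and assemblage sums converge to the continuum at
  second order only for profiles continuous at their support edges (the
  sloppy-division ψ, not the idealised φ with its jump at x = 1/2).
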