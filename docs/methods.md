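# Methods

## Model

Three cover fractions on a 1-D domain: savanna saplings *S*, adult
savanna trees *T*, forest trees *F*; grass is the complement
`G = 1 − S − T − F`.  Demographic rates respond to mean annual rainfall
*P* (mm/y): cover expansion `R_Y(P) = max(0, r_Y (1 − e^{−k_RY P + a_RY}))`
saturates to `r_Y` in wet climates and is clamped at zero below the
wilting rainfall `a_RY/k_RY`; drought mortality
`M_Y(P) = m_{o,Y} + e^{−k_MY P + a_MY}` decays to the baseline
`m_{o,Y}`.  Fire is a fast process summarized by the burnt-area
fraction `Φ(T,F;P) = τ⁻¹ Y_c⁴ / (Y_c⁴ + (T+F)⁴)`, a decreasing Hill
function of woody cover with half-point at the percolation threshold
`Y_c(P) = max(0, Y_c0 + k_c P)`: a connected grassy fuel layer only
percolates while woody cover is below `Y_c`, and wetter climates have a
lower threshold (`k_c < 0`).  Fire suppresses sapling-to-adult
recruitment, `Q(Φ) = Q0 (1 − hΦ)`, and kills forest trees at rate `bΦ`.
Human impact removes forest at `C(z) = c e^{−k_C z}`, decaying with
distance *z* (metres) from cultivation.  Only saplings and forest
diffuse (`D_S`, `D_F` in km²/y); adult savanna trees do not.

The bundled parameter file `src/forestfronts/data/default_params.toml`
is the reference set (average rainfall seasonality and soils folded into
the rainfall responses).  Two printed entries need interpretation:

* the savanna/adult mortality offset is unspecified; we take
  `a_MS = a_MT = 0`, i.e. `M_S = m_So + e^{−k_MS P}`, and expose it as a
  parameter.  The alternative (no exponential term at all) differs only
  below ~700 mm/y and changes none of the headline results (checked).
* the Hill exponent `n_fire` is a parameter (default 4); the arctan
  closed form of the potential below requires 4, other values fall back
  to numerical quadrature.

## Scalar forest model, potential and Maxwell point

With `S = T = 0` and time rescaled by the fire timescale (`t → b t/τ`,
so each rate maps to `rate·τ/b` and the fire term has unit coefficient)
the forest model becomes `u_t = α(P,z)u − β(P)u² − u f(u) + u_xx` with
`f(u) = u_c⁴/(u_c⁴+u⁴)`, `α = ρr − μm − γc − μ0`, `β = ρr`.  The
interpretation of the rescaled constants as `rate·τ/b` is the unique one
that leaves the fire term unprefixed; it is guarded by a test asserting
that the dimensional and rescaled reactions share their equilibria
exactly over a rainfall grid.

The reaction derives from a potential, `u_t = −V'(u) + u_xx`, with

```
V(u) = β u³/3 − α u²/2 + (u_c²/2)·arctan[(u/u_c)²],   V(0) = 0.
```

Fronts are oriented with grassland (`u₋ = 0`) on the left and forest
(`u₊`) on the right, ξ = x − ct, so `sign(c) = sign(ΔV)` with
`ΔV = V(u₊) − V(0)`: negative ΔV means forest has the lower potential
and invades (c < 0).  The Maxwell point `P_MP(z)` is the bracketed root
of `P ↦ ΔV(P, z)` inside the bistable rainfall range; the root search
uses Brent's method to sub-mm tolerance, with `u₊` found by a
2000-point sign-change scan of `α − βu − f(u)` polished to 1e−12.  The
closed form is verified in tests against direct quadrature of the
*dimensional* reaction (the MP condition `∫₀^{u₊} R(F) dF = 0` is
invariant to the rescaling), the two routes agreeing to ~1e−12.

Degenerate cases: at `u_c = 0` (rainfall above `Y_c0/|k_c|` ≈ 3916 mm)
the fire response vanishes for `u > 0` while `f(0) = 1`; the stability
of the bare state is therefore classified from the right-limit of the
reaction derivative, which makes the bare branch destabilize exactly at
that rainfall.  This is what terminates the bistable range from above.

### Agreement with published reference values

With the printed two-significant-digit parameter set the computed MP is
1411.6 mm/y, not the published 1438; sensitivity analysis shows single
rounding steps of the printed values move the MP by 20–45 mm (e.g.
b 0.46→0.47: +21 mm; r_F 0.20→0.195: +43 mm), fully explaining the gap.
Likewise the upper endpoint of the bistable range is the exact
threshold-extinction rainfall 3916 mm vs a published "~3500".  We keep
the printed values and report the computed numbers; the corresponding
acceptance tests fail openly with this explanation.  The same applies,
more strongly, to the savanna-woodland bistability limits (below).

## Simulation

Method of lines: central differences on a uniform grid, no-flux ends by
mirror ghost nodes, adaptive RK4(5) (`scipy.integrate.solve_ivp`,
rtol 1e−6, atol 1e−9 by default).  Reactions are evaluated on covers
clipped to [0,1] and a post-hoc projection zeroes O(atol) negative
undershoots; with mirror boundaries pure diffusion conserves the
half-end-weighted (trapezoid) mass, which is the conservation check the
tests use.  The reference heterogeneous setup is a 0–3000 km domain at
Δx = 0.67 km with the linear forcing `P(x) = x` (1 mm/y per km) and
i.i.d. Uniform(0,1) random initial conditions per node (triples rescaled
by `max(1, S+T+F)` into the simplex for the three-field variants); the
results shown are attractor states and insensitive to the IC law.
`run_to_steady` integrates in windows until `max|du/dt|` drops below a
tolerance.  With rtol 1e−6 the residual floors near 1e−5 (integrator
noise), so steady-state runs that need the 1e−8 criterion use rtol 1e−8.

Grid resolution matters physically: the front width is
`√(D_F τ/b)` ≈ 0.77 km, so on grids much coarser than that the discrete
front locks onto lattice sites ("pinning") tens of mm away from the MP.
Δx = 0.67 km resolves the front; there the simulated front settles
within ~1 mm of the MP, and halving Δx moves it by less than one cell.
Coarser grids (Δx = 2 km) are used only where front position is not the
quantity of interest (ensemble bistability scatter, eigenvalue
cross-checks).

## Front extraction

Logistic fits `F(P) = A/(1+e^{−k(P−P_f)})` use soft-L1 robust least
squares (plain least squares available), initialized from the profile
maximum, the gradient argmax and the corresponding logistic slope;
`R² = 1 − SS_res/SS_tot`.  The gradient estimator takes the argmax of
the centred derivative with ties broken to the lowest rainfall.  Front
speeds come from level-crossing positions (level: half the final
maximum) regressed against time over the second half of a
homogeneous-rainfall run started from a half-domain forest step.

## Stationary fronts, stability and continuation

Pinned fronts solve `R(u; P(x), z) + D_F u_xx = 0`, by damped Newton on
the central-difference discretization with a tridiagonal Jacobian
(banded elimination).  The translation mode of a pinned front has a
near-zero eigenvalue, which can stall plain Newton; the solver then
switches to bursts of unconditional backward-Euler steps (shifted
Jacobian, dt = 2000 y) — legitimate because the scalar problem is a
gradient flow — and resumes Newton.  Accepted fronts have residuals
below 1e−10.

The linearization `L = diag(∂R/∂u(u*, P)) + D_F Lap/Δx²` is similar to
a symmetric tridiagonal matrix under the half-weighted boundary inner
product (end off-diagonals √2·d), so its spectrum is provably real;
`stability()` offers a dense eigensolve that also measures the imaginary
parts numerically, and an O(n) banded mode extracting the top eigenvalue
along branches.  Tests cross-check the two on truncated profiles.

On the lattice, the continuum's neutrally-translating front family
breaks into stable-node/saddle pairs separated by depinning micro-folds,
one per grid cell, with leading eigenvalues of order ±1e−3/y (all other
modes are strongly negative).  Two consequences shaped the continuation
design:

* `continue_branch` (secant predictor, bordered Newton corrector with
  the arclength condition, z scaled at 500 m per unit cover) rejects
  landings whose leading eigenvalue exceeds 1e−2/y (spurious
  multi-plateau solutions) and relaxes saddle micro-states onto the
  adjacent stable node via an eigenvector kick plus backward-Euler
  relaxation.
* a dense arclength walk through thousands of micro-folds is wasteful
  for the full z sweep, so `trace_front_branch` samples the (in z
  single-valued) stable branch at a geometric ladder of z stations,
  seeding each Newton solve with the previous profile re-masked at the
  station's Maxwell point.  80 stations cover z ∈ [0, 5 km] in under a
  minute; every station front is a stable node with real spectrum and
  its pinning rainfall P_f (gradient argmax) lies within 2 grid cells
  of the homogeneous Maxwell point — the branch and the MP curve are
  numerically indistinguishable, with continuation and long simulations
  agreeing on P_f within 2 cells as well.

The branch domain extends to 3500 km so that the MP at z = 0
(≈ 3220 mm) stays inside the grid.

## Regime diagnostics

Ensemble experiments integrate seeded random ICs to a fixed end time
(default 10000 y; scatter bistability is insensitive to halving this)
and pool final covers per 50-mm rainfall bin across runs and nodes.  A
bin is "bistable" when exact 1-D two-means clustering separates two
clusters by more than 0.2 cover and neither cluster holds under 5% of
the points (an outlier guard verified by a false-positive test on
unimodal synthetic scatter).  Note that in cycling regimes a final-time
snapshot also spreads into two bands (the relaxation cycle dwells near
its extremes), so detected intervals include both genuinely bistable and
cycling rainfall bands.

Cycle statistics: transients (first 30%) discarded,
prominence-filtered peak detection (prominence 0.05 cover), periods from
inter-peak gaps; the coefficient of variation of the periods classifies
the series (CV < 0.02 regular, CV > 0.1 irregular, otherwise
undetermined; fewer than 3 peaks is steady).  The thresholds are our
choice of the simplest defensible irregularity proxy; whether the
irregular cycles are chaotic is left open.  In the high-savanna regime
(r_S = 0.13, Q0 = 0.2, τ = 1, P = 1500 mm) the nonspatial model
produces a regular relaxation cycle (period ~560 y, state transitions
~90 y, forest peaks trailing savanna peaks), while the spatially
homogeneous model with diffusion on a domain large compared to the
        ~100 km decoherence scale (tests use 1000 km) produces irregular
cycles — irregularity induced by diffusion alone.

### Savanna-woodland bistability with the printed parameters

The printed equations do not reproduce the published bistability
limits.  At r_S = 0.13, Q0 = 0.2, τ = 1 the savanna-only (S,T)
subsystem has a savanna/woodland fold pair only in a narrow window
around 520–580 mm and is monostable woodland above it — verified by
multi-start Newton, by a 1-D reduction of the equilibrium problem and by
direct ODE integration; with τ = 1 no burnt-area normalization
ambiguity can alter this, because the grass state is a saddle whenever
`R_S Q_grass > (Q_grass + M_S) M_T`, which holds by a factor ~3.  The
ensemble detector therefore reports an upper limit of ~650 mm for the
savanna-only variant (published: ~2500) and ~1750 mm for the full model
(published: ~1000 — our detected interval extends through the cycling
band, see above).  The corresponding acceptance tests fail openly.

## Synthetic fixtures

`fixtures` generates exact and noisy logistic profiles with known
(A, k, P_f) and sharpened-sine oscillation series with known period
(lognormal per-cycle jitter for aperiodic variants).  They exercise the
estimators, not the PDE: noise is additive Gaussian and stationary,
unlike model output where deviations from a logistic shape are
structured (savanna-induced gradients), so estimator tests on fixtures
demonstrate recovery accuracy, not realism of the error model.

## Problem sizes

Acceptance-style computations use: the full reference grid (4479 nodes)
for the headline pinning run; 1000–2000 km subdomains at Δx = 0.67 for
front-resolving tests; Δx = 2 km, 6–8 run ensembles to 8000–10000 y for
bistability scatter; 80 z-stations for the branch sweep.  These sizes
were chosen so each quantity is resolved well inside its assertion
tolerance.

## Known limitations

* 1-D only; no stochastic forcing; no geographic (map-based) inputs.
* The environmental-vector forms of the responses (seasonality, soil
  regressions) are folded into the rainfall responses at their average.
* Published-value mismatches documented above are inherent to the
  printed parameter precision, not tunable away without inventing
  parameter values.
* `run_to_steady` cannot certify convergence below the integrator noise
  floor; converged flags must be read together with the tolerance used.
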