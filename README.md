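# forestfronts

Reaction-diffusion modelling of tropical tree cover along rainfall
gradients: where does the forest–savanna boundary settle, when is it a
true boundary between alternative stable states, and when does the
fire–vegetation feedback produce oscillations instead?

The package is aimed at spatial ecologists and modellers working on
forest–savanna bistability.  It implements a three-compartment
fire–vegetation model — savanna sapling cover *S*, adult savanna tree
cover *T* and forest tree cover *F* on a 1-D domain —

```
∂t S = R_S(P) (1−S−T−F) T − Q0 [1−h Φ] S − M_S(P) S − R_F S F + D_S ∂xx S
∂t T = Q0 [1−h Φ] S − M_T(P) T − R_F T F
∂t F = R_F(P) (1−F) F − b Φ F − M_F(P) F − C(z) F + D_F ∂xx F
```

with burnt-area fraction `Φ = τ⁻¹ Y_c⁴/(Y_c⁴+(T+F)⁴)`, a percolation
threshold `Y_c(P) = max(0, Y_c0 + k_c P)` decreasing with mean annual
rainfall *P*, and deforestation pressure `C(z) = c·e^{−k_C z}` decaying
with the distance *z* from cultivated land.  Setting `S = T = 0` gives
the scalar **forest model**, which after rescaling takes the bistable
form `u_t = α(P,z) u − β(P) u² − u f(u) + u_xx` and admits a potential
`V(u) = βu³/3 − αu²/2 + (u_c²/2)·arctan[(u/u_c)²]`.  The rainfall at
which `ΔV = V(u₊) − V(0)` vanishes is the **Maxwell point** (MP): above
it forest invades grassland, below it forest retreats, and under a
rainfall gradient the forest front pins there.

What the library does:

* `model` — parameters (bundled reference set), response functions,
  reaction terms, nondimensionalization.
* `homogeneous` — steady-state branches, the potential, ΔV, Maxwell
  points, bistable rainfall ranges, multi-start equilibrium scans of the
  full model and the savanna-only subsystem.
* `simulate` — method-of-lines integration (adaptive RK45, central
  differences, no-flux boundaries) of all three model variants.
* `fronts` — logistic front fits `F(P) = A/(1+e^{−k(P−P_f)})`, gradient
  argmax front location, and front-speed estimation.
* `continuation` — stationary pinned fronts as a boundary-value problem,
  pseudo-arclength continuation in *z*, linear stability of the
  discretized operator.
* `regimes` — ensemble scatter experiments, two-cluster bistability
  detection, and cycle statistics (regular vs irregular oscillations).
* `cli` / `experiments` — a `forestfronts` command with subcommands
  `mp`, `hss`, `simulate`, `front`, `continue`, `ensemble`, `cycles`,
  `experiment` and `fixtures`.

## Worked example

```python
import math
from forestfronts import (ModelParameters, maxwell_point, build_grid, Forcing,
                          random_initial_condition, run_to_steady,
                          fit_logistic_front)

params = ModelParameters()                    # reference parameter set
mp = maxwell_point(math.inf, params)          # no human impact
print(f"Maxwell point: {mp.P_MP:.1f} mm/y")

grid = build_grid(0.0, 3000.0, 0.67)          # 1 mm/y of rain per km
forcing = Forcing(P=0.0, z=math.inf, gradient="linear")
ic = random_initial_condition(grid, "forest", seed=1)
sim = run_to_steady(ic, grid, forcing, params, "forest", t_max=30000.0,
                    window=5000.0, rtol=1e-8, atol=1e-11)
fit = fit_logistic_front(grid.x, sim.final[0])
print(f"front pinned at {fit.P_f:.1f} mm/y (R2 = {fit.R2:.4f})")
```

prints

```
Maxwell point: 1411.6 mm/y
front pinned at 1410.6 mm/y (R2 = 0.9991)
```

i.e. the simulated forest front settles within one grid cell of the
analytically derived Maxwell point: below ~1410 mm/y the landscape ends
up grass/savanna, above it forest, and the boundary is predicted by the
nonspatial potential analysis alone.

From the shell, the same analyses:

```
forestfronts mp --z-km 1 --z-km 2
forestfronts continue --z-start 5 --z-end 0
forestfronts ensemble --variant savanna-only --rs 0.13 --q0 0.2 --tau 1
```

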