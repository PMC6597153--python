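"""Nonspatial analysis: steady states, the potential V(u) and Maxwell points.

For the scalar forest model the reaction can be written as minus the
gradient of a potential, ``u_t = -V'(u) + u_xx``.  Between two stable
states the front moves toward the state of higher potential, and the
rainfall at which the potential difference ``dV = V(u+) - V(u-)``
vanishes — the Maxwell point — is where a front is stationary.  With the
quartic Hill fire term the fire contribution to V integrates in closed
form to an arctan, so dV is evaluated analytically up to the numerically
determined roots u+-.

Sign convention: fronts are oriented with grassland (u- = 0) on the left
and forest (u+) on the right, xi = x - c t, so dV < 0 means forest
invades (c < 0 moves the front toward the grassland side).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .model import (
    ModelParameters,
    NondimParams,
    nondim_reaction_du,
    nondimensionalize,
    reaction_terms,
)

__all__ = [
    "SteadyStateSet",
    "MaxwellResult",
    "Equilibrium",
    "forest_steady_states",
    "bistable_range",
    "potential",
    "delta_V",
    "maxwell_point",
    "full_model_steady_states",
    "savanna_subsystem_range",
    "probe_limit_cycle",
]

_SCAN_N = 2000  # root-scan resolution on u in [0, 1]


@dataclass(frozen=True)
class SteadyStateSet:
    """Equilibria of the scalar forest model at one (P, z)."""

    P: float
    z: float
    roots: tuple[float, ...]          # ascending; 0 is always included
    stability: tuple[str, ...]        # "stable" | "unstable" per root

    @property
    def stable_roots(self) -> tuple[float, ...]:
        return tuple(r for r, s in zip(self.roots, self.stability) if s == "stable")

    @property
    def upper(self) -> float | None:
        """The forested stable state u+, if present."""
        nontrivial = [r for r in self.stable_roots if r > 1e-6]
        return max(nontrivial) if nontrivial else None


@dataclass(frozen=True)
class MaxwellResult:
    z: float
    P_MP: float
    deltaV_at_root: float
    bracket: tuple[float, float]


@dataclass(frozen=True)
class Equilibrium:
    """A root of the full-model reaction with its local linearization."""

    state: tuple[float, float, float]
    eigenvalues: tuple[complex, ...]
    classification: str  # stable_node | stable_focus | unstable
    residual: float

    @property
    def stable(self) -> bool:
        return self.classification.startswith("stable")


def forest_steady_states(P: float, z: float, params: ModelParameters | None = None,
                         nd: NondimParams | None = None) -> SteadyStateSet:
    """All equilibria of the scalar forest reaction on [0, 1].

    Roots of ``[alpha - beta u - f(u)] u``: zero is always an
    equilibrium (fire keeps bare ground bare whenever alpha < 1); the
    nontrivial roots are located by a dense sign-change scan of
    ``g(u) = alpha - beta u - f(u)`` polished with Brent's method.
    """
    if nd is None:
        nd = nondimensionalize(params if params is not None else ModelParameters())

    def g(u):
        return nd.alpha(P, z) - nd.beta(P) * u - nd.f(u, P)

    us = np.linspace(0.0, 1.0, _SCAN_N + 1)
    gs = g(us)
    roots = [0.0]
    for i in range(_SCAN_N):
        a, b = gs[i], gs[i + 1]
        if a == 0.0 and us[i] > 0:
            roots.append(us[i])
        elif a * b < 0:
            roots.append(optimize.brentq(g, us[i], us[i + 1], xtol=1e-12))
    if gs[-1] == 0.0:
        roots.append(1.0)
    roots = sorted(set(round(r, 12) for r in roots))
    # classify from the right-limit of the reaction derivative: at u_c = 0
    # the fire response drops to 0 for any u > 0, so the bare state is
    # judged by alpha, not by the f(0) = 1 convention
    stab = tuple(
        "stable" if nondim_reaction_du(max(r, 1e-9), P, z, nd) < 0 else "unstable"
        for r in roots)
    return SteadyStateSet(P=float(P), z=float(z), roots=tuple(roots), stability=stab)


def _is_bistable(P: float, z: float, nd: NondimParams) -> bool:
    ss = forest_steady_states(P, z, nd=nd)
    zero_stable = ss.stability[0] == "stable"
    return zero_stable and ss.upper is not None


def bistable_range(z: float, params: ModelParameters | None = None,
                   P_grid: np.ndarray | None = None,
                   xtol: float = 0.05) -> tuple[float, float] | None:
    """Rainfall interval where bare ground and forest are both stable.

    Scans a rainfall grid for coexistence of the stable zero branch and
    a stable high-cover branch, then bisects each saddle-node boundary.
    Returns ``None`` when no bistability is found on the grid.
    """
    nd = nondimensionalize(params if params is not None else ModelParameters())
    if P_grid is None:
        P_grid = np.arange(200.0, 5000.0, 20.0)
    flags = np.array([_is_bistable(P, z, nd) for P in P_grid])
    if not flags.any():
        return None
    idx = np.nonzero(flags)[0]
    i0, i1 = idx[0], idx[-1]

    def bisect(lo, hi, want_inside_hi):
        # invariant: exactly one of (lo, hi) is bistable
        while hi - lo > xtol:
            mid = 0.5 * (lo + hi)
            if _is_bistable(mid, z, nd) == want_inside_hi:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    lo_edge = P_grid[i0] if i0 == 0 else bisect(P_grid[i0 - 1], P_grid[i0], True)
    hi_edge = P_grid[i1] if i1 == len(P_grid) - 1 else bisect(P_grid[i1], P_grid[i1 + 1], False)
    if i1 != len(P_grid) - 1:
        # for the upper edge the bistable side is the *lower* end
        lo, hi = P_grid[i1], P_grid[i1 + 1]
        while hi - lo > xtol:
            mid = 0.5 * (lo + hi)
            if _is_bistable(mid, z, nd):
                lo = mid
            else:
                hi = mid
        hi_edge = 0.5 * (lo + hi)
    return float(lo_edge), float(hi_edge)


def potential(u, P: float, z: float, nd: NondimParams):
    """Potential V(u) with V(0) = 0 and V'(u) = -[alpha - beta u - f(u)] u.

    Closed form (cubic plus arctan) for the quartic fire exponent;
    other exponents integrate the fire term numerically.
    """
    u = np.asarray(u, float)
    a = nd.alpha(P, z)
    b = nd.beta(P)
    uc = float(nd.u_c(P))
    core = b * u ** 3 / 3.0 - a * u ** 2 / 2.0
    if uc == 0.0:
        return core  # f vanishes for u > 0 in the no-fire-threshold limit
    if nd.n_fire == 4:
        return core + (uc ** 2 / 2.0) * np.arctan((u / uc) ** 2)
    fire = np.vectorize(
        lambda x: integrate.quad(lambda s: s * nd.f(s, P), 0.0, x, limit=200)[0]
    )(u)
    return core + fire


def delta_V(P: float, z: float, nd: NondimParams) -> float:
    """Potential difference V(u+) - V(0) between forest and bare ground.

    Negative values mean forest has the lower potential and invades.
    Raises if (P, z) is not bistable (no front exists there).
    """
    ss = forest_steady_states(P, z, nd=nd)
    if ss.stability[0] != "stable" or ss.upper is None:
        raise ValueError(f"no front exists at P={P}, z={z}: system is not bistable")
    return float(potential(ss.upper, P, z, nd))


def maxwell_point(z: float, params: ModelParameters | None = None,
                  xtol: float = 1e-3) -> MaxwellResult:
    """Rainfall at which the forest/grassland front is stationary.

    Brackets the root of ``P -> dV(P, z)`` inside the bistable rainfall
    range (shrunk 1 mm from each saddle-node) and solves with Brent's
    method to sub-mm tolerance.
    """
    params = params if params is not None else ModelParameters()
    nd = nondimensionalize(params)
    rng = bistable_range(z, params)
    if rng is None:
        raise ValueError(f"no bistable rainfall range at z={z}")
    lo, hi = rng[0] + 1.0, rng[1] - 1.0
    f_lo, f_hi = delta_V(lo, z, nd), delta_V(hi, z, nd)
    if f_lo * f_hi > 0:
        raise ValueError(f"delta_V does not change sign on ({lo:.1f}, {hi:.1f})")
    P_mp = optimize.brentq(lambda P: delta_V(P, z, nd), lo, hi, xtol=xtol)
    return MaxwellResult(z=float(z), P_MP=float(P_mp),
                         deltaV_at_root=delta_V(P_mp, z, nd), bracket=(lo, hi))


# ---------------------------------------------------------------------------
# full three-species nonspatial system


def _full_reaction(y: np.ndarray, P: float, z: float, params: ModelParameters,
                   clip: bool = True) -> np.ndarray:
    S, T, F = y
    if clip:
        S, T, F = (min(max(v, 0.0), 1.0) for v in (S, T, F))
    dS, dT, dF = reaction_terms(S, T, F, P, z, params, check=False)
    return np.array([dS, dT, dF], float)


def _jacobian_fd(y: np.ndarray, P: float, z: float, params: ModelParameters,
                 eps: float = 1e-7) -> np.ndarray:
    J = np.empty((3, 3))
    for j in range(3):
        yp, ym = y.copy(), y.copy()
        yp[j] += eps
        ym[j] -= eps
        J[:, j] = (_full_reaction(yp, P, z, params, clip=False)
                   - _full_reaction(ym, P, z, params, clip=False)) / (2 * eps)
    return J


def full_model_steady_states(P: float, z: float, params: ModelParameters,
                             n_starts: int = 40, seed: int = 0,
                             savanna_only: bool = False) -> list[Equilibrium]:
    """Multi-start equilibria of the nonspatial three-species system.

    Newton (scipy hybr) from random simplex points plus the corners;
    converged roots inside the simplex are deduplicated and classified
    from the eigenvalues of a finite-difference Jacobian.  With
    ``savanna_only`` the forest component is frozen at zero (the
    savanna-woodland subsystem).
    """
    rng = np.random.default_rng(seed)
    starts = [np.zeros(3), np.array([0.05, 0.05, 0.8]), np.array([0.1, 0.6, 0.0]),
              np.array([0.02, 0.1, 0.0]), np.array([0.3, 0.3, 0.3])]
    draws = rng.uniform(0, 1, size=(n_starts, 3))
    draws /= np.maximum(1.0, draws.sum(axis=1))[:, None]
    starts.extend(draws)

    def fun(y):
        r = _full_reaction(y, P, z, params, clip=False)
        if savanna_only:
            r[2] = y[2]  # pin F = 0
        return r

    found: list[Equilibrium] = []
    for y0 in starts:
        if savanna_only:
            y0 = y0.copy()
            y0[2] = 0.0
        sol = optimize.root(fun, y0, method="hybr", tol=1e-12)
        y = sol.x
        if not sol.success:
            continue
        if np.any(y < -1e-8) or np.any(y > 1 + 1e-8) or y.sum() > 1 + 1e-6:
            continue
        y = np.clip(y, 0.0, 1.0)
        res = float(np.max(np.abs(fun(y))))
        if res > 1e-10:
            continue
        if any(np.max(np.abs(np.array(e.state) - y)) < 1e-6 for e in found):
            continue
        J = _jacobian_fd(y, P, z, params)
        if savanna_only:
            J = J[:2, :2]
        lam = np.linalg.eigvals(J)
        if np.max(lam.real) < 0:
            cls = "stable_focus" if np.max(np.abs(lam.imag)) > 1e-10 else "stable_node"
        else:
            cls = "unstable"
        found.append(Equilibrium(state=tuple(float(v) for v in y),
                                 eigenvalues=tuple(lam), classification=cls,
                                 residual=res))
    found.sort(key=lambda e: e.state[1])
    return found


def probe_limit_cycle(P: float, z: float, params: ModelParameters,
                      y0: np.ndarray | None = None, t_end: float = 3000.0,
                      seed: int = 0) -> bool:
    """Integrate the nonspatial system and test for sustained oscillation.

    Returns True when the adult-tree cover still swings by more than
    0.05 cover over the last third of the run.
    """
    rng = np.random.default_rng(seed)
    if y0 is None:
        y0 = rng.uniform(0, 1, 3)
        y0 /= max(1.0, y0.sum())
    sol = integrate.solve_ivp(
        lambda t, y: _full_reaction(y, P, z, params), (0.0, t_end), y0,
        method="RK45", rtol=1e-8, atol=1e-10, dense_output=False,
        t_eval=np.linspace(0, t_end, 2000))
    tail = sol.y[1, int(2000 * 2 / 3):]
    return bool(tail.max() - tail.min() > 0.05)


def savanna_subsystem_range(params: ModelParameters,
                            P_grid: np.ndarray | None = None,
                            full_model: bool = False,
                            seed: int = 0) -> list[tuple[float, float]]:
    """Rainfall interval(s) with two coexisting stable equilibria.

    By default scans the savanna-woodland subsystem (forest frozen at
    zero); with ``full_model`` the whole three-species system is
    scanned.  Contiguous rainfall bins with >= 2 stable equilibria are
    merged into intervals.
    """
    if P_grid is None:
        P_grid = np.arange(100.0, 3500.0, 50.0)
    flags = []
    for P in P_grid:
        eq = full_model_steady_states(P, math.inf, params, n_starts=25, seed=seed,
                                      savanna_only=not full_model)
        flags.append(sum(e.stable for e in eq) >= 2)
    intervals: list[tuple[float, float]] = []
    start = None
    for P, f in zip(P_grid, flags):
        if f and start is None:
            start = P
        elif not f and start is not None:
            intervals.append((float(start), float(prev)))
            start = None
        prev = P
    if start is not None:
        intervals.append((float(start), float(P_grid[-1])))
    return intervals
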