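"""Stationary fronts of the heterogeneous forest model and their stability.

A pinned front is a solution of the boundary-value problem
``R(u; P(x), z) + D_F u_xx = 0`` with no-flux ends, computed by damped
Newton iteration on the central-difference discretization (the Jacobian
is tridiagonal and solved in banded form).  Linear stability follows
from the eigenvalues of the discretized operator
``L = diag(dR/du(u*, P)) + D_F Lap / dx^2``: the front is a stable node
when all eigenvalues are real and negative.  Pseudo-arclength
continuation in the human-impact distance z traces the branch of front
solutions and records the pinning rainfall P_f(z) along the way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .fronts import front_from_gradient
from .homogeneous import forest_steady_states, maxwell_point
from .model import (
    ModelParameters,
    deforestation_rate,
    forest_reaction,
    forest_reaction_du,
)
from .simulate import Grid, build_grid, laplacian_noflux

__all__ = ["StationaryFront", "Branch", "solve_stationary_front",
           "jacobian_operator", "stability", "continue_branch",
           "trace_front_branch", "initial_front_guess"]

_Z_SCALE = 500.0  # m; weights z against cover in the arclength metric


@dataclass
class StationaryFront:
    z: float                    # m
    u_star: np.ndarray          # cover profile on the grid
    grid: Grid
    P_f: float                  # pinning rainfall via gradient argmax, mm/y
    newton_residual: float
    max_re_lambda: float | None = None   # 1/y
    spectrum_real: bool | None = None


@dataclass
class Branch:
    fronts: list[StationaryFront] = field(default_factory=list)
    ds: float = 0.0

    @property
    def z_values(self) -> np.ndarray:
        return np.array([f.z for f in self.fronts])

    @property
    def P_f_values(self) -> np.ndarray:
        return np.array([f.P_f for f in self.fronts])


def _residual(u: np.ndarray, grid: Grid, z: float, params: ModelParameters) -> np.ndarray:
    P = grid.x  # linear forcing P(x) = x
    return (np.asarray(forest_reaction(u, P, z, params, check=False))
            + params.D_F * laplacian_noflux(u, grid.dx))


def _jacobian_banded(u: np.ndarray, grid: Grid, z: float,
                     params: ModelParameters) -> np.ndarray:
    """Tridiagonal Jacobian in solve_banded (ab) layout."""
    n = grid.n
    d = params.D_F / grid.dx ** 2
    diag = forest_reaction_du(u, grid.x, z, params) - 2.0 * d
    upper = np.full(n, d)
    lower = np.full(n, d)
    upper[1] = 2.0 * d   # mirror BC: row 0 couples twice to node 1
    lower[-2] = 2.0 * d  # row n-1 couples twice to node n-2
    ab = np.zeros((3, n))
    ab[0, 1:] = upper[1:]
    ab[1] = diag
    ab[2, :-1] = lower[:-1]
    return ab


def initial_front_guess(grid: Grid, z: float,
                        params: ModelParameters) -> np.ndarray:
    """Step-like guess: the local forest equilibrium above the Maxwell
    point, bare ground below, blended over the physical front width
    sqrt(D_F tau / b) so Newton only has to correct the shape."""
    P_mp = maxwell_point(z, params).P_MP
    u = np.zeros(grid.n)
    for i, P in enumerate(grid.x):
        ss = forest_steady_states(P, z, params)
        up = ss.upper
        u[i] = up if up is not None else 0.0
    width = math.sqrt(params.D_F * params.tau / params.b)
    arg = np.clip((grid.x - P_mp) / width, -60.0, 60.0)
    return u / (1.0 + np.exp(-arg))


def solve_stationary_front(u_guess: np.ndarray, grid: Grid, z: float,
                           params: ModelParameters, tol: float = 1e-10,
                           max_iter: int = 50) -> StationaryFront:
    """Damped Newton solution of the stationary-front BVP."""
    u = np.asarray(u_guess, float).copy()
    r = _residual(u, grid, z, params)
    history = [float(np.max(np.abs(r)))]
    rescues = 0
    for _ in range(max_iter):
        if history[-1] < tol:
            break
        rn2 = np.linalg.norm(r)
        ab = _jacobian_banded(u, grid, z, params)
        step = solve_banded((1, 1), ab, -r)
        lam = 1.0
        while lam > 1e-6:  # Armijo backtracking on the 2-norm
            u_new = u + lam * step
            r_new = _residual(u_new, grid, z, params)
            if np.linalg.norm(r_new) < rn2 * (1.0 - 1e-4 * lam):
                break
            lam *= 0.5
        else:
            # Stall: the near-neutral translation mode of a pinned front
            # makes the Jacobian ill-conditioned.  The stationary problem
            # is the equilibrium of a gradient-like flow, so a burst of
            # unconditional backward-Euler steps (shifted Jacobian,
            # dt = 2000 y) slides the iterate down the slow manifold.
            rescues += 1
            if rescues > 5:
                raise RuntimeError(
                    f"Newton stalled; residual history {history}")
            for _ in range(25):
                ab = _jacobian_banded(u, grid, z, params).copy()
                ab[1] -= 5e-4  # 1/dt
                u = u - solve_banded((1, 1), ab, _residual(u, grid, z, params))
            r = _residual(u, grid, z, params)
            history.append(float(np.max(np.abs(r))))
            continue
        u, r = u_new, r_new
        history.append(float(np.max(np.abs(r))))
    else:
        raise RuntimeError(f"Newton did not converge; residual history {history}")
    rn = history[-1]
    pf = front_from_gradient(grid.x, u).P_f
    return StationaryFront(z=float(z), u_star=u, grid=grid, P_f=pf,
                           newton_residual=float(rn))


def jacobian_operator(u_star: np.ndarray, grid: Grid, z: float,
                      params: ModelParameters) -> np.ndarray:
    """Dense discretized linearization diag(dR/du) + D_F Lap / dx^2."""
    n = grid.n
    d = params.D_F / grid.dx ** 2
    L = np.zeros((n, n))
    idx = np.arange(n)
    L[idx, idx] = forest_reaction_du(u_star, grid.x, z, params) - 2.0 * d
    L[idx[:-1], idx[:-1] + 1] += d
    L[idx[1:], idx[1:] - 1] += d
    L[0, 1] += d
    L[-1, -2] += d
    return L


def stability(front: StationaryFront, params: ModelParameters,
              imag_tol: float = 1e-10, method: str = "dense") -> tuple[float, bool]:
    """Max real eigenvalue of the linearization and spectrum reality.

    Updates the front record in place and returns the pair.  ``dense``
    computes the full nonsymmetric spectrum and measures its imaginary
    parts.  ``banded`` exploits that the operator is similar to a
    symmetric tridiagonal matrix under the half-weighted boundary inner
    product (off-diagonal entries sqrt(2) d at the ends), so the
    spectrum is real by construction and only the top eigenvalue is
    extracted, at O(n) cost — used along long continuation branches.
    """
    if method == "banded":
        from scipy.linalg import eigh_tridiagonal
        g = front.grid
        d = params.D_F / g.dx ** 2
        diag = forest_reaction_du(front.u_star, g.x, front.z, params) - 2.0 * d
        off = np.full(g.n - 1, d)
        off[0] = off[-1] = math.sqrt(2.0) * d
        lam_max = eigh_tridiagonal(diag, off, eigvals_only=True, select="i",
                                   select_range=(g.n - 1, g.n - 1))[0]
        front.max_re_lambda = float(lam_max)
        front.spectrum_real = True  # exact, by the similarity transform
    else:
        L = jacobian_operator(front.u_star, front.grid, front.z, params)
        lam = np.linalg.eigvals(L)
        front.max_re_lambda = float(lam.real.max())
        front.spectrum_real = bool(np.max(np.abs(lam.imag)) < imag_tol)
    return front.max_re_lambda, front.spectrum_real


def _top_eig_pair(u: np.ndarray, grid: Grid, z: float,
                  params: ModelParameters) -> tuple[float, np.ndarray]:
    from scipy.linalg import eigh_tridiagonal
    d = params.D_F / grid.dx ** 2
    diag = forest_reaction_du(u, grid.x, z, params) - 2.0 * d
    off = np.full(grid.n - 1, d)
    off[0] = off[-1] = math.sqrt(2.0) * d
    w, v = eigh_tridiagonal(diag, off, select="i",
                            select_range=(grid.n - 1, grid.n - 1))
    return float(w[0]), v[:, 0]


def _stabilize_front(front: StationaryFront, params: ModelParameters) -> StationaryFront:
    """Walk off a saddle micro-state onto the adjacent stable pinned front.

    Discrete pinned fronts come in stable-node/saddle pairs separated by
    depinning folds; the saddle's unstable (translation) eigenvalue is
    tiny.  A kick along that eigenvector followed by shifted-Jacobian
    relaxation (backward-Euler steps with dt ~ 0.5/lambda) drains into
    the neighbouring stable state, which Newton then polishes.
    """
    grid = front.grid
    z = front.z
    for sign in (1.0, -1.0):
        lam, v = _top_eig_pair(front.u_star, grid, z, params)
        if lam < 0:
            return front
        u = front.u_star + sign * 1e-2 * v * np.sign(v[np.argmax(np.abs(v))])
        dt = 0.5 / max(lam, 1e-4)
        for _ in range(30):
            r = _residual(u, grid, z, params)
            ab = _jacobian_banded(u, grid, z, params)
            ab = ab.copy()
            ab[1] -= 1.0 / dt
            u = u - solve_banded((1, 1), ab, r)
        try:
            cand = solve_stationary_front(u, grid, z, params)
        except RuntimeError:
            continue
        stability(cand, params, method="banded")
        if cand.max_re_lambda < 0:
            return cand
    return front


def continue_branch(start: StationaryFront, params: ModelParameters,
                    z_end: float, ds: float = 0.5,
                    max_steps: int = 400,
                    compute_stability: bool = False,
                    stability_method: str = "dense",
                    max_unstable_eig: float = 1e-2) -> Branch:
    """Pseudo-arclength continuation of the front branch in z.

    Secant predictor with a Newton corrector on the bordered system
    (residual plus arclength condition); step halving on corrector
    failure, truncating the branch after repeated failure.  ``ds`` is
    the arclength step in the scaled metric where 500 m of z counts as
    one unit of cover change.

    The stationary-front BVP also admits spurious unstable solutions
    (multi-plateau nuclei); a landing whose leading eigenvalue exceeds
    ``max_unstable_eig`` — far above the near-neutral translation-mode
    scale of a pinned front — is rejected and the step halved.
    """
    grid = start.grid
    branch = Branch(fronts=[start], ds=ds)
    if compute_stability and start.max_re_lambda is None:
        stability(start, params, method=stability_method)
    direction = 1.0 if z_end >= start.z else -1.0
    # first step: natural continuation to get a secant; the z offset is
    # shrunk until Newton converges (steep P_f(z) stretches need tiny steps)
    dz1 = direction * ds * _Z_SCALE * 0.5
    while True:
        try:
            f1 = solve_stationary_front(start.u_star, grid, start.z + dz1,
                                        params)
            break
        except RuntimeError:
            dz1 *= 0.25
            if abs(dz1) < 1e-2:
                raise
    stability(f1, params, method="banded")
    if f1.max_re_lambda is not None and f1.max_re_lambda > 0:
        f1 = _stabilize_front(f1, params)
    if compute_stability and stability_method != "banded":
        stability(f1, params, method=stability_method)
    branch.fronts.append(f1)

    def corrector(u_pred, z_pred, tu, tz):
        u, z = u_pred.copy(), z_pred
        for _ in range(30):
            r = _residual(u, grid, z, params)
            N = tu @ (u - u_pred) + tz * (z - z_pred) / _Z_SCALE ** 2
            if max(np.max(np.abs(r)), abs(N)) < 1e-10:
                return u, z
            ab = _jacobian_banded(u, grid, z, params)
            # dG/dz of the -C(z) u term
            gz = params.k_C * deforestation_rate(z, params) * u
            a = solve_banded((1, 1), ab, -r)
            bb = solve_banded((1, 1), ab, gz)
            denom = tz / _Z_SCALE ** 2 - tu @ bb
            if denom == 0:
                return None
            dz = (-N - tu @ a) / denom
            u = u + a - bb * dz
            z = max(z + dz, 0.0)
        return None

    step = ds
    fails = 0
    z_lo = min(start.z, z_end) - ds * _Z_SCALE
    z_hi = max(start.z, z_end) + ds * _Z_SCALE
    tu_ref = None
    tz_ref = 0.0
    for _ in range(max_steps):
        f_prev, f_cur = branch.fronts[-2], branch.fronts[-1]
        du = f_cur.u_star - f_prev.u_star
        dz = f_cur.z - f_prev.z
        norm = math.sqrt(du @ du + (dz / _Z_SCALE) ** 2)
        if norm < 1e-12:
            break
        tu, tz = du / norm, dz / norm
        # keep the tangent orientation continuous (a stabilized landing
        # can otherwise flip the secant and reverse the walk)
        if tu_ref is not None and (tu @ tu_ref + tz * tz_ref) < 0:
            tu, tz, du, dz = -tu, -tz, -du, -dz
        tu_ref, tz_ref = tu, tz
        scale = step / norm
        u_pred = f_cur.u_star + scale * du
        z_pred = f_cur.z + scale * dz
        out = corrector(u_pred, z_pred, tu, tz)
        if out is not None and not (z_lo <= out[1] <= z_hi):
            out = None  # left the continuation window
        if out is None:
            step *= 0.5
            fails += 1
            if fails > 6:
                break
            continue
        u, z = out
        front = StationaryFront(
            z=float(z), u_star=u, grid=grid,
            P_f=front_from_gradient(grid.x, u).P_f,
            newton_residual=float(np.max(np.abs(_residual(u, grid, z, params)))))
        stability(front, params, method="banded")
        if front.max_re_lambda > max_unstable_eig:
            # a large positive eigenvalue means the corrector jumped to a
            # spurious (multi-plateau) solution branch
            step *= 0.5
            fails += 1
            if fails > 6:
                break
            continue
        if front.max_re_lambda > 0.0:
            front = _stabilize_front(front, params)
        fails = 0
        if compute_stability and stability_method != "banded":
            stability(front, params, method=stability_method)
        branch.fronts.append(front)
        step = min(step * 1.3, ds * 4)
        if (direction > 0 and z >= z_end) or (direction < 0 and z <= z_end):
            break
        if direction < 0 and z <= 0.0:
            break
    return branch


def trace_front_branch(params: ModelParameters, z_start: float = 5000.0,
                       z_end: float = 0.0, grid: Grid | None = None,
                       n_stations: int = 80,
                       stability_method: str = "banded") -> Branch:
    """Sample the stable pinned-front branch at a ladder of z stations.

    P_f(z) is single-valued but traverses one lattice-pinning micro-fold
    per grid cell, which makes a dense arclength walk of the steep
    small-z stretch needlessly expensive (:func:`continue_branch`
    remains the pseudo-arclength engine and is the right tool across
    folds and locally).  Here each station is solved directly: the
    previous profile is re-masked at the station's Maxwell point to seed
    Newton, and saddle landings are relaxed onto the adjacent stable
    node.  Stations are geometrically spaced in z so the steep
    exponential tail of the human-impact response is well resolved.
    """
    if grid is None:
        grid = build_grid(0.0, 3500.0, 0.67)
    offset = 200.0  # m; sets the smallest station spacing near z = 0
    ladder = np.geomspace(z_start + offset, max(z_end, 0.0) + offset,
                          n_stations) - offset
    ladder[-1] = max(z_end, 0.0)
    width = math.sqrt(params.D_F * params.tau / params.b)
    branch = Branch(fronts=[], ds=0.0)
    u_prev = initial_front_guess(grid, float(ladder[0]), params)
    for z in ladder:
        mp = maxwell_point(float(z), params).P_MP
        arg = np.clip((grid.x - mp) / width, -60.0, 60.0)
        guess = u_prev / (1.0 + np.exp(-arg))
        try:
            front = solve_stationary_front(guess, grid, float(z), params)
        except RuntimeError:
            guess = initial_front_guess(grid, float(z), params)
            front = solve_stationary_front(guess, grid, float(z), params)
        stability(front, params, method="banded")
        if front.max_re_lambda > 0:
            front = _stabilize_front(front, params)
        if stability_method != "banded":
            stability(front, params, method=stability_method)
        branch.fronts.append(front)
        u_prev = front.u_star
    return branch
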