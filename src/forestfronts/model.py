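"""Core model definitions for the forest-savanna reaction-diffusion system.

The dimensional model tracks three cover fractions on a 1-D domain:
savanna sapling cover ``S``, adult savanna tree cover ``T`` and forest
tree cover ``F`` (grass is the complement ``1 - S - T - F``).  Growth and
drought mortality respond to mean annual rainfall ``P`` (mm/y), fire is a
Hill-type function of woody cover ``T + F`` with a rainfall-dependent
percolation threshold, and forest close to cultivated land is removed at
an exponentially decaying rate in the distance ``z`` (m).

The reduced forest model (``S = T = 0``) admits a nondimensional scalar
form ``u_t = alpha(P, z) u - beta(P) u^2 - u f(u; P) + u_xx`` used for
potential/Maxwell-point analysis; :func:`nondimensionalize` maps the
dimensional parameter set onto it and the equivalence of the two forms is
covered by tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "ModelParameters",
    "NondimParams",
    "Forcing",
    "growth_rate",
    "mortality_rate",
    "fire_threshold",
    "burnt_fraction",
    "deforestation_rate",
    "reaction_terms",
    "forest_reaction",
    "forest_reaction_du",
    "nondimensionalize",
    "nondim_reaction",
    "load_parameters",
    "save_parameters",
    "default_parameters",
]

Species = Literal["S", "T", "F"]


@dataclass(frozen=True)
class ModelParameters:
    """Dimensional constants of the forest-savanna model.

    Defaults are the published reference parameterization (average
    rainfall seasonality and soils).  Rates are per year, rainfall
    sensitivities per mm, ``k_C`` per metre, diffusivities in km^2/y.
    """

    r_S: float = 0.09      # savanna sapling growth ceiling, 1/y
    r_F: float = 0.20      # forest growth ceiling, 1/y
    k_RS: float = 0.005    # growth steepness vs rainfall, 1/mm
    k_RF: float = 0.003
    a_RS: float = 0.25     # growth offsets (dimensionless)
    a_RF: float = 1.54
    m_So: float = 0.023    # baseline mortalities, 1/y (m_To = m_So)
    m_Fo: float = 0.041
    a_MS: float = 0.0      # mortality offsets; savanna offset not specified -> 0
    a_MF: float = -2.15
    k_MS: float = 0.008    # mortality steepness, 1/mm (k_MT = k_MS)
    k_MF: float = 0.008
    Q0: float = 0.04       # max sapling->adult recruitment, 1/y
    h: float = 0.85        # fire sensitivity of recruitment, in [0, 1]
    tau: float = 2.7       # maximum fire return time, y
    n_fire: int = 4        # Hill exponent of the burnt-area function
    Y_c0: float = 0.56     # fire-spread threshold at P = 0, cover fraction
    k_c: float = -1.43e-4  # threshold slope, 1/mm (negative)
    b: float = 0.46        # forest fire sensitivity (dimensionless)
    c_def: float = 0.092   # deforestation amplitude, 1/y
    k_C: float = 0.0015    # deforestation decay, 1/m
    D_S: float = 0.2       # sapling diffusion, km^2/y
    D_F: float = 0.1       # forest diffusion, km^2/y

    def __post_init__(self) -> None:
        for name in ("r_S", "r_F", "k_RS", "k_RF", "m_So", "m_Fo",
                     "k_MS", "k_MF", "Q0", "c_def", "k_C", "D_S", "D_F"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be nonnegative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must lie in [0, 1]")
        if self.k_c >= 0:
            raise ValueError("k_c must be negative")
        if self.n_fire < 1:
            raise ValueError("n_fire must be >= 1")

    def with_overrides(self, **kwargs: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NondimParams:
    """Constants of the rescaled scalar forest model.

    Time is rescaled by the fire timescale, ``t -> b t / tau``, so every
    dimensional rate maps to ``rate * tau / b`` and the fire term carries
    a unit coefficient.
    """

    rho: float      # r_F * tau / b
    mu: float       # e^{a_MF} * tau / b
    mu0: float      # m_Fo * tau / b
    gamma: float    # c_def * tau / b
    deltaF: float   # D_F * tau / b
    kappa_r: float  # = k_RF, 1/mm
    kappa_m: float  # = k_MF, 1/mm
    a: float        # = a_RF
    u_c0: float     # = Y_c0
    k_c: float      # unchanged, 1/mm
    n_fire: int = 4
    k_C: float = 0.0015

    def r(self, P):
        """Dimensionless growth response, clamped at zero for dry P."""
        return np.maximum(0.0, 1.0 - np.exp(-self.kappa_r * np.asarray(P, float) + self.a))

    def m(self, P):
        """Dimensionless drought-mortality response, ``e^{-kappa_m P}``."""
        return np.exp(-self.kappa_m * np.asarray(P, float))

    def c(self, z):
        """Dimensionless human-impact response, ``e^{-k_C z}``."""
        return np.exp(-self.k_C * np.asarray(z, float))

    def u_c(self, P):
        """Fire-spread percolation threshold, clamped linear in rainfall."""
        return np.maximum(0.0, self.u_c0 + self.k_c * np.asarray(P, float))

    def f(self, u, P):
        """Hill fire response ``u_c^n / (u_c^n + u^n)``; 1 at u = 0."""
        u = np.asarray(u, float)
        uc = self.u_c(P)
        n = self.n_fire
        ucn = uc ** n
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(ucn + u ** n > 0, ucn / (ucn + u ** n), 1.0)
        return out

    def alpha(self, P, z):
        """Net linear growth coefficient alpha(P, z)."""
        return self.rho * self.r(P) - self.mu * self.m(P) - self.gamma * self.c(z) - self.mu0

    def beta(self, P):
        """Quadratic self-limitation coefficient beta(P) = rho r(P)."""
        return self.rho * self.r(P)


@dataclass(frozen=True)
class Forcing:
    """Environmental forcing of a run.

    ``P`` is either a scalar (homogeneous runs) or a per-node rainfall
    array; ``z`` is the scalar distance from cultivation in metres
    (``inf`` switches human impact off).
    """

    P: float | np.ndarray
    z: float = math.inf
    gradient: Literal["homogeneous", "linear"] = "homogeneous"

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.P) < 0):
            raise ValueError("rainfall must be nonnegative")
        if self.z < 0:
            raise ValueError("distance from cultivation must be nonnegative")


_SPECIES_GROWTH = {"S": ("r_S", "k_RS", "a_RS"), "F": ("r_F", "k_RF", "a_RF")}
_SPECIES_MORT = {
    "S": ("m_So", "k_MS", "a_MS"),
    "T": ("m_So", "k_MS", "a_MS"),
    "F": ("m_Fo", "k_MF", "a_MF"),
}


def growth_rate(P, species: Species, params: ModelParameters):
    """Rainfall-limited cover expansion rate R_Y(P), 1/y.

    ``max(0, r_Y (1 - e^{-k_RY P + a_RY}))``: zero below the wilting
    rainfall ``a_RY / k_RY`` and saturating to ``r_Y`` in wet climates.
    """
    if species not in _SPECIES_GROWTH:
        raise ValueError(f"no growth rate defined for species {species!r}")
    r_name, k_name, a_name = _SPECIES_GROWTH[species]
    r = getattr(params, r_name)
    k = getattr(params, k_name)
    a = getattr(params, a_name)
    P = np.asarray(P, float)
    if np.any(P < 0):
        raise ValueError("rainfall must be nonnegative")
    return np.maximum(0.0, r * (1.0 - np.exp(-k * P + a)))


def mortality_rate(P, species: Species, params: ModelParameters):
    """Drought mortality M_Y(P) = m_o,Y + e^{-k_MY P + a_MY}, 1/y."""
    if species not in _SPECIES_MORT:
        raise ValueError(f"no mortality defined for species {species!r}")
    m_name, k_name, a_name = _SPECIES_MORT[species]
    P = np.asarray(P, float)
    if np.any(P < 0):
        raise ValueError("rainfall must be nonnegative")
    return getattr(params, m_name) + np.exp(-getattr(params, k_name) * P + getattr(params, a_name))


def fire_threshold(P, params: ModelParameters):
    """Percolation threshold Y_c(P) = max(0, Y_c0 + k_c P), cover fraction."""
    P = np.asarray(P, float)
    return np.maximum(0.0, params.Y_c0 + params.k_c * P)


def burnt_fraction(T, F, P, params: ModelParameters, check: bool = True):
    """Burnt-area fraction Phi(T, F; P), 1/y-scale capped at 1/tau.

    A decreasing Hill function of woody cover ``T + F``: fire spreads
    freely through open grassland and is shut off once woody cover
    exceeds the percolation threshold ``Y_c(P)``.
    """
    T = np.asarray(T, float)
    F = np.asarray(F, float)
    if check and (np.any(T < -1e-12) or np.any(F < -1e-12)):
        raise ValueError("cover fractions must be nonnegative")
    w = T + F
    Yc = fire_threshold(P, params)
    n = params.n_fire
    ycn = Yc ** n
    with np.errstate(divide="ignore", invalid="ignore"):
        hill = np.where(ycn + w ** n > 0, ycn / (ycn + w ** n), 1.0)
    return hill / params.tau


def deforestation_rate(z, params: ModelParameters):
    """Forest removal rate C(z) = c e^{-k_C z}, 1/y; z in metres."""
    z = np.asarray(z, float)
    return params.c_def * np.exp(-params.k_C * z)


def _check_simplex(S, T, F) -> None:
    arrs = [np.asarray(a, float) for a in (S, T, F)]
    for a in arrs:
        if np.any(a < -1e-9) or np.any(a > 1 + 1e-9):
            raise ValueError("cover fractions must lie in [0, 1]")
    if np.any(arrs[0] + arrs[1] + arrs[2] > 1 + 1e-6):
        raise ValueError("cover fractions must sum to at most 1")


def reaction_terms(S, T, F, P, z, params: ModelParameters, check: bool = True):
    """Local (non-diffusive) rates of change (dS/dt, dT/dt, dF/dt), 1/y.

    Saplings establish on grass under adult-tree seed rain, are recruited
    to adults at a rate suppressed by fire, and both savanna stages are
    outcompeted by forest; forest grows logistically, burns when woody
    cover is below threshold, and is cleared near cultivation.
    ``check=False`` skips simplex validation (finite-difference callers
    need to step slightly outside the admissible region).
    """
    if check:
        _check_simplex(S, T, F)
    S = np.asarray(S, float)
    T = np.asarray(T, float)
    F = np.asarray(F, float)
    R_S = growth_rate(P, "S", params)
    R_F = growth_rate(P, "F", params)
    M_S = mortality_rate(P, "S", params)
    M_T = mortality_rate(P, "T", params)
    M_F = mortality_rate(P, "F", params)
    Phi = burnt_fraction(T, F, P, params, check=check)
    C = deforestation_rate(z, params) if np.isfinite(z) else 0.0
    recruit = params.Q0 * (1.0 - params.h * Phi)
    dS = R_S * (1.0 - S - T - F) * T - recruit * S - M_S * S - R_F * S * F
    dT = recruit * S - M_T * T - R_F * T * F
    dF = R_F * (1.0 - F) * F - params.b * Phi * F - M_F * F - C * F
    return dS, dT, dF


def forest_reaction(F, P, z, params: ModelParameters, check: bool = True):
    """Reaction term of the scalar forest model (savanna absent), 1/y."""
    F = np.asarray(F, float)
    R_F = growth_rate(P, "F", params)
    M_F = mortality_rate(P, "F", params)
    Phi = burnt_fraction(np.zeros_like(F), F, P, params, check=check)
    C = deforestation_rate(z, params) if np.isfinite(z) else 0.0
    return R_F * (1.0 - F) * F - params.b * Phi * F - M_F * F - C * F


def forest_reaction_du(F, P, z, params: ModelParameters):
    """Analytic derivative of :func:`forest_reaction` with respect to F."""
    F = np.asarray(F, float)
    R_F = growth_rate(P, "F", params)
    M_F = mortality_rate(P, "F", params)
    C = deforestation_rate(z, params) if np.isfinite(z) else 0.0
    Yc = fire_threshold(P, params)
    n = params.n_fire
    ycn = Yc ** n
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = ycn + F ** n
        hill = np.where(denom > 0, ycn / denom, 1.0)
        dhill = np.where(denom > 0, -n * F ** (n - 1) * ycn / denom ** 2, 0.0)
    return (R_F * (1.0 - 2.0 * F) - M_F - C
            - (params.b / params.tau) * (hill + F * dhill))


def nondimensionalize(params: ModelParameters) -> NondimParams:
    """Map the dimensional forest model onto its rescaled scalar form.

    With ``t -> b t / tau`` each rate picks up a factor ``tau / b`` and
    the burnt-area term becomes ``u f(u)`` with unit prefactor.
    """
    if params.b <= 0 or params.tau <= 0:
        raise ValueError("nondimensionalization requires b > 0 and tau > 0")
    scale = params.tau / params.b
    return NondimParams(
        rho=params.r_F * scale,
        mu=math.exp(params.a_MF) * scale,
        mu0=params.m_Fo * scale,
        gamma=params.c_def * scale,
        deltaF=params.D_F * scale,
        kappa_r=params.k_RF,
        kappa_m=params.k_MF,
        a=params.a_RF,
        u_c0=params.Y_c0,
        k_c=params.k_c,
        n_fire=params.n_fire,
        k_C=params.k_C,
    )


def nondim_reaction(u, P, z, nd: NondimParams):
    """Reaction of the rescaled forest model: alpha u - beta u^2 - u f(u)."""
    u = np.asarray(u, float)
    if np.any(u < -1e-9) or np.any(u > 1 + 1e-9):
        raise ValueError("cover must lie in [0, 1]")
    return nd.alpha(P, z) * u - nd.beta(P) * u ** 2 - u * nd.f(u, P)


def nondim_reaction_du(u, P, z, nd: NondimParams):
    """Analytic d/du of :func:`nondim_reaction`."""
    u = np.asarray(u, float)
    uc = nd.u_c(P)
    n = nd.n_fire
    ucn = uc ** n
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = ucn + u ** n
        hill = np.where(denom > 0, ucn / denom, 1.0)
        dhill = np.where(denom > 0, -n * u ** (n - 1) * ucn / denom ** 2, 0.0)
    return nd.alpha(P, z) - 2.0 * nd.beta(P) * u - hill - u * dhill


# ---------------------------------------------------------------------------
# parameter file round-trip (flat TOML key-value)

def default_parameters() -> ModelParameters:
    """The bundled reference parameter set."""
    return load_parameters(Path(__file__).parent / "data" / "default_params.toml")


def load_parameters(path: str | Path) -> ModelParameters:
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in fields(ModelParameters)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    if "n_fire" in raw:
        raw["n_fire"] = int(raw["n_fire"])
    return ModelParameters(**raw)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    lines = []
    for f in fields(ModelParameters):
        v = getattr(params, f.name)
        lines.append(f"{f.name} = {v!r}")
    Path(path).write_text("\n".join(lines) + "\n")
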