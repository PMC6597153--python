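"""Ensemble experiments, bistability detection and cycle statistics.

Bistability in the spatial models is diagnosed the way scatterplots of
cover versus rainfall reveal it: an ensemble of simulations from random
initial conditions is run to late time, final cover is pooled per
rainfall bin across runs and nodes, and a bin is flagged bistable when
the pooled values split into two well-separated clusters.  Cycling
regimes are summarized by peak statistics of a cover time series; the
coefficient of variation of the inter-peak intervals separates regular
from irregular oscillations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .model import Forcing, ModelParameters
from .simulate import Grid, SimResult, build_grid, integrate, random_initial_condition

__all__ = ["EnsembleScatter", "CycleStats", "ensemble_scatter",
           "detect_bistability", "cycle_statistics", "spacetime_export"]


@dataclass
class EnsembleScatter:
    rainfall: np.ndarray                 # (n,) mm/y, shared across runs
    finals: list[np.ndarray]             # per-run (nfields, n) final covers
    field_names: tuple[str, ...]
    seeds: list[int]
    variant: str
    params: ModelParameters
    z: float

    def pooled(self, field: str) -> tuple[np.ndarray, np.ndarray]:
        """(rainfall, value) pairs pooled over runs and nodes."""
        i = self.field_names.index(field)
        P = np.tile(self.rainfall, len(self.finals))
        v = np.concatenate([f[i] for f in self.finals])
        return P, v


@dataclass(frozen=True)
class CycleStats:
    peak_times: np.ndarray   # y
    periods: np.ndarray      # y
    amplitude: float         # max - min cover after transient
    period_cv: float
    classification: str      # steady | regular_cycle | irregular_cycle | undetermined


def ensemble_scatter(variant: str, params: ModelParameters, z: float = math.inf,
                     n_runs: int = 8, seed: int = 0, grid: Grid | None = None,
                     t_end: float = 10000.0, rtol: float = 1e-6) -> EnsembleScatter:
    """Seeded ensemble of heterogeneous runs collected at final time."""
    if grid is None:
        grid = build_grid(0.0, 3000.0, 2.0)
    forcing = Forcing(P=0.0, z=z, gradient="linear")
    seeds = [seed + 1000 * k for k in range(n_runs)]
    finals = []
    names = None
    for s in seeds:
        ic = random_initial_condition(grid, variant, seed=s)
        sim = integrate(ic, grid, forcing, params, variant, t_end=t_end,
                        rtol=rtol, seed=s)
        finals.append(sim.final)
        names = sim.field_names
    return EnsembleScatter(rainfall=grid.rainfall(forcing), finals=finals,
                           field_names=names, seeds=seeds, variant=variant,
                           params=params, z=z)


def _two_means_1d(v: np.ndarray) -> tuple[float, float, float]:
    """Exact 1-D two-means split; returns (lower mean, upper mean,
    fraction in smaller cluster)."""
    v = np.sort(v)
    n = len(v)
    csum = np.cumsum(v)
    total = csum[-1]
    best, best_k = np.inf, 1
    for k in range(1, n):
        m1 = csum[k - 1] / k
        m2 = (total - csum[k - 1]) / (n - k)
        ss = (np.sum((v[:k] - m1) ** 2) + np.sum((v[k:] - m2) ** 2))
        if ss < best:
            best, best_k = ss, k
    k = best_k
    return (float(csum[k - 1] / k), float((total - csum[k - 1]) / (n - k)),
            min(k, n - k) / n)


def detect_bistability(scatter: EnsembleScatter, field: str = "T",
                       gap: float = 0.2, bin_width: float = 50.0,
                       min_points: int = 8,
                       min_fraction: float = 0.05) -> list[tuple[float, float]]:
    """Rainfall interval(s) where final cover splits into two clusters.

    Per rainfall bin the pooled values are split by exact 1-D two-means
    clustering; a bin is flagged when the cluster separation exceeds
    ``gap`` and neither cluster is a negligible fraction of the points
    (guarding against single-outlier splits).  Contiguous flagged bins
    are merged into intervals.
    """
    if len(scatter.finals) < 2:
        raise ValueError("need at least 2 ensemble runs")
    P, v = scatter.pooled(field)
    edges = np.arange(P.min(), P.max() + bin_width, bin_width)
    flagged = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (P >= lo) & (P < hi)
        if sel.sum() < min_points:
            continue
        m1, m2, frac = _two_means_1d(v[sel])
        flagged.append((lo, hi, (m2 - m1) > gap and frac >= min_fraction))
    intervals: list[tuple[float, float]] = []
    for lo, hi, flag in flagged:
        if flag:
            if intervals and abs(intervals[-1][1] - lo) < 1e-9:
                intervals[-1] = (intervals[-1][0], hi)
            else:
                intervals.append((lo, hi))
    return intervals


def cycle_statistics(times, values, min_prominence: float = 0.05,
                     transient_fraction: float = 0.3,
                     cv_regular: float = 0.02,
                     cv_irregular: float = 0.1) -> CycleStats:
    """Peak statistics of one cover time series.

    The leading transient is discarded, peaks are detected with a
    prominence filter, and the series is classified from the
    coefficient of variation (CV) of the inter-peak intervals:
    CV < ``cv_regular`` is a regular cycle, CV > ``cv_irregular`` an
    irregular one, in between undetermined.  Fewer than 3 peaks counts
    as steady.
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    start = int(len(t) * transient_fraction)
    t, v = t[start:], v[start:]
    idx, _ = find_peaks(v, prominence=min_prominence)
    peak_times = t[idx]
    periods = np.diff(peak_times)
    amplitude = float(v.max() - v.min()) if len(v) else 0.0
    if len(idx) < 3:
        cls = "steady"
        cv = 0.0
    else:
        cv = float(periods.std() / periods.mean())
        if cv < cv_regular:
            cls = "regular_cycle"
        elif cv > cv_irregular:
            cls = "irregular_cycle"
        else:
            cls = "undetermined"
    return CycleStats(peak_times=peak_times, periods=periods,
                      amplitude=amplitude, period_cv=cv, classification=cls)


def spacetime_export(sim: SimResult, field: str = "F"):
    """Space-time matrix of one cover field with (rainfall, time) axes.

    Returns ``(rainfall, times, matrix)`` with matrix shape
    (n_times, n_nodes), ready for CSV export or Hovmoller-style plots.
    """
    mat = sim.field(field)
    rain = sim.grid.rainfall(sim.forcing)
    return rain, sim.times.copy(), mat.copy()
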