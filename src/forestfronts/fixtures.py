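"""Synthetic inputs for exercising the fitting and cycle-statistics code.

These generators produce profiles and time series with known ground
truth (logistic parameters, oscillation periods), so estimator accuracy
can be checked exactly.  All randomness is seeded.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .fronts import logistic_profile

__all__ = ["synthetic_logistic_profile", "synthetic_oscillation",
           "write_fixture_files"]


def synthetic_logistic_profile(A: float = 0.8, k: float = 0.05,
                               P_f: float = 1400.0, noise_sd: float = 0.0,
                               P_min: float = 0.0, P_max: float = 3000.0,
                               n: int = 600, seed: int | None = None):
    """(P, F) arrays for a logistic front with optional Gaussian noise."""
    P = np.linspace(P_min, P_max, n)
    F = logistic_profile(P, A, k, P_f)
    if noise_sd > 0:
        F = F + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return P, F


def synthetic_oscillation(period: float = 120.0, t_end: float = 6000.0,
                          dt: float = 1.0, amplitude: float = 0.3,
                          offset: float = 0.4, jitter: float = 0.0,
                          seed: int | None = None):
    """(t, v) arrays for a relaxation-style oscillation of known period.

    ``jitter`` > 0 perturbs each cycle length by a lognormal factor,
    producing an aperiodic series with the same mean period.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_end, dt)
    if jitter <= 0:
        phase = 2 * np.pi * t / period
    else:
        # build a piecewise phase with per-cycle period jitter
        phase = np.empty_like(t)
        t0, ph = 0.0, 0.0
        per = period * rng.lognormal(0.0, jitter)
        for i, ti in enumerate(t):
            while ti - t0 > per:
                t0 += per
                ph += 2 * np.pi
                per = period * rng.lognormal(0.0, jitter)
            phase[i] = ph + 2 * np.pi * (ti - t0) / per
    # sharpened sinusoid: fast transitions, long dwells
    v = offset + amplitude * np.tanh(3.0 * np.sin(phase))
    return t, v


def write_fixture_files(outdir: str | Path, seed: int = 0) -> list[Path]:
    """Write the standard fixture CSVs; reproducible from the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    P, F = synthetic_logistic_profile()
    path = outdir / "logistic_exact.csv"
    np.savetxt(path, np.column_stack([P, F]), delimiter=",",
               header="P_mm,F", comments="")
    written.append(path)

    P, F = synthetic_logistic_profile(noise_sd=0.02, seed=seed)
    path = outdir / "logistic_noisy.csv"
    np.savetxt(path, np.column_stack([P, F]), delimiter=",",
               header="P_mm,F", comments="")
    written.append(path)

    t, v = synthetic_oscillation(period=120.0, seed=seed)
    path = outdir / "cycle_regular.csv"
    np.savetxt(path, np.column_stack([t, v]), delimiter=",",
               header="t_y,T", comments="")
    written.append(path)

    t, v = synthetic_oscillation(period=120.0, jitter=0.3, seed=seed)
    path = outdir / "cycle_irregular.csv"
    np.savetxt(path, np.column_stack([t, v]), delimiter=",",
               header="t_y,T", comments="")
    written.append(path)
    return written
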