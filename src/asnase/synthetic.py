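"""Seeded synthetic-data generators.

Every analysis stage in this package can be exercised without laboratory
data: these generators produce time courses, DoE response tables,
Michaelis-Menten velocity series and 4PL dose-response curves from known
ground-truth parameters plus additive Gaussian noise. A generator is a
pure function of its arguments and seed, so fixtures are reproducible
byte for byte; noise_sd = 0 returns the exact model values, which makes
the generator itself the oracle for parameter-recovery tests.

Channels within one artifact draw from independent sub-streams of a
single seed, so adding or removing a channel never perturbs the others.
"""

from __future__ import annotations

import numpy as np

from .enzymology import four_param_logistic, michaelis_menten
from .kinetics import (GompertzParams, LogisticParams, TimeCourse,
                       gompertz_curve, logistic_curve)
from .response_surface import DimensionError, QuadraticSurface

__all__ = [
    "gen_timecourse",
    "gen_doe_response",
    "gen_mm_velocity",
    "gen_dose_response",
]


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def gen_timecourse(
    logistic: LogisticParams,
    product: GompertzParams | None = None,
    substrate: GompertzParams | None = None,
    t_end: float = 96.0,
    dt: float = 6.0,
    noise_sd_frac: float = 0.0,
    seed: int = 0,
) -> TimeCourse:
    """Sampled fermentation run: logistic biomass plus optional Gompertz
    product and cumulative-substrate-consumption channels.

    Default sampling is every 6 h over 96 h, the cadence of a typical
    bench-scale run. ``noise_sd_frac`` scales iid Gaussian noise by each
    channel's range; values are clipped at zero (no negative biomass or
    activity).
    """
    t = np.arange(0.0, t_end + dt / 2, dt)
    rngs = _streams(seed, 3)
    channels: dict[str, np.ndarray] = {}
    channels["X"] = logistic_curve(logistic, t)
    if product is not None:
        channels["P"] = gompertz_curve(product, t)
    if substrate is not None:
        channels["S"] = gompertz_curve(substrate, t)
    for (name, clean), rng in zip(channels.items(), rngs):
        if noise_sd_frac > 0:
            sd = noise_sd_frac * np.ptp(clean)
            channels[name] = np.clip(clean + rng.normal(0, sd, t.shape), 0, None)
    return TimeCourse(t=t, **channels)


def gen_doe_response(
    surface: QuadraticSurface,
    design,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Responses for a coded design: surface evaluation plus Gaussian noise."""
    design = np.asarray(design, dtype=float)
    if design.ndim != 2 or design.shape[1] != surface.k:
        raise DimensionError(
            f"design must be (n, {surface.k}), got {design.shape}")
    clean = surface.evaluate(design)
    if noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    return clean + rng.normal(0, noise_sd, clean.shape)


def gen_mm_velocity(
    Km: float,
    Vmax: float,
    S_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Michaelis-Menten velocities over a substrate grid plus noise."""
    if Km <= 0 or Vmax <= 0:
        raise ValueError("Km and Vmax must be > 0")
    clean = michaelis_menten(np.asarray(S_grid, dtype=float), Km, Vmax)
    if noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    return np.clip(clean + rng.normal(0, noise_sd, clean.shape), 1e-12, None)


def gen_dose_response(
    ic50: float,
    hill: float,
    doses,
    top: float = 100.0,
    bottom: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Percent-viability readings from a descending 4PL plus noise."""
    if ic50 <= 0 or hill <= 0:
        raise ValueError("ic50 and hill must be > 0")
    doses = np.asarray(doses, dtype=float)
    clean = four_param_logistic(doses, top, bottom, ic50, hill)
    if noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    return np.clip(clean + rng.normal(0, noise_sd, clean.shape), 0, None)
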