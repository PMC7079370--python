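"""Replicate sweep protocols for the waiting-time analysis.

These helpers bundle the standard experiment: run the agent model for
several seeds under one parameter setting, push one labelled count series
per run through the inversion pipeline over a fixed epoch, average the
normalised waiting-time densities and summarise their modes.  Count series
with a 1 s step are analysed with a 2.5 s kernel bandwidth so the kernel
bridges the integer spacing of the sampled SIPs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .config import SimulationConfig, apply_scale
from .engine import run_simulation
from .filtering import FilterParams
from .wtd import KDEParams, epoch_wtd, find_modes

#: analysis defaults for dt = 1 s molecular count series
ABM_FILTER = FilterParams(tau1=50.0, tau2=10.0)
ABM_BANDWIDTH = 2.5


def make_config(seed: int, duration: float = 3.0e4,
                timers: dict[str, float] | None = None,
                scale: float = 1.0, **kwargs) -> SimulationConfig:
    """Baseline configuration with optional timer overrides and count
    rescaling (the interaction range is rescaled jointly)."""
    config = SimulationConfig(seed=seed, duration=duration,
                              timers=timers or {}, **kwargs)
    if scale != 1.0:
        config = apply_scale(config, scale)
    return config


def replicate_wtds(label: str, seeds: Sequence[int],
                   duration: float = 3.0e4,
                   timers: dict[str, float] | None = None,
                   scale: float = 1.0,
                   epoch_start: float = 1.0e4,
                   epoch_length: float = 1.0e4,
                   grid: np.ndarray | None = None,
                   filter_params: FilterParams | None = None,
                   bandwidth: float = ABM_BANDWIDTH) -> tuple[np.ndarray, np.ndarray]:
    """Per-seed normalised waiting-time densities for one labelled state.

    Returns ``(psis, grid)`` with one row per seed.
    """
    if grid is None:
        grid = np.arange(0.0, 100.0 + 0.25, 0.25)
    kde = KDEParams(bandwidth=bandwidth, grid=grid)
    fp = filter_params or ABM_FILTER
    psis = []
    for seed in seeds:
        config = make_config(seed, duration=duration, timers=timers,
                             scale=scale)
        series = run_simulation(config)
        result = epoch_wtd(series.times, series.column(label),
                           t0=epoch_start, length=epoch_length,
                           filter_params=fp, kde_params=kde)
        psis.append(result.psi)
    return np.vstack(psis), grid


def main_modes(psi: np.ndarray, grid: np.ndarray,
               n: int = 2) -> list[tuple[float, float]]:
    """The ``n`` highest modes of a density, sorted by location."""
    modes = find_modes(psi, grid)
    top = sorted(modes, key=lambda m: m[1], reverse=True)[:n]
    return sorted(top)


def lower_mode(psi: np.ndarray, grid: np.ndarray) -> float:
    """Location of the smaller-tau of the two main modes."""
    modes = main_modes(psi, grid)
    if not modes:
        raise ValueError("density has no modes")
    return modes[0][0]


def upper_mode(psi: np.ndarray, grid: np.ndarray) -> float:
    """Location of the larger-tau of the two main modes."""
    modes = main_modes(psi, grid)
    if not modes:
        raise ValueError("density has no modes")
    return modes[-1][0]


def global_mode(psi: np.ndarray, grid: np.ndarray) -> float:
    """Location of the global maximum of the density."""
    return float(grid[int(np.argmax(psi))])


def support_bound(psi: np.ndarray, grid: np.ndarray,
                  floor: float = 0.01) -> float:
    """Largest tau whose density is non-negligible (>= floor * max)."""
    idx = np.flatnonzero(psi >= floor * float(psi.max()))
    return float(grid[idx[-1]]) if idx.size else 0.0
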