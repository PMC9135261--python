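"""Exact continuous-time Monte Carlo (SSA) for the birth-death chain.

The stochastic simulation algorithm draws an exponential waiting time with
the total propensity ``birth[n] + death[n]`` and picks the channel with
probability proportional to its propensity, so trajectories are exact
samples of the master equation.  Ensembles derive one child seed per
trajectory from the master seed through a counter-based spawn scheme, making
them reproducible and independent of evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import RateTable

__all__ = ["Trajectory", "EnsembleSummary", "ssa_trajectory", "sample_on_grid", "ensemble"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Trajectory:
    """One SSA realisation: piecewise-constant state path n(t).

    ``times[0] = 0`` with ``states[0] = n0``; each subsequent entry is an
    event.  The state is constant between events and after the last event up
    to ``t_max``.
    """

    times: np.ndarray
    states: np.ndarray
    t_max: float
    seed: object
    rates: RateTable

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=np.int64)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        if times.shape != states.shape or times.ndim != 1 or times.shape[0] == 0:
            raise ValueError("times and states must be equal-length non-empty vectors")
        if np.any(np.diff(times) <= 0):
            raise ValueError("event times must be strictly increasing")
        N = self.rates.N
        if states.min() < 0 or states.max() > N:
            raise ValueError(f"states must lie in [0, {N}]")

    @property
    def n0(self) -> int:
        return int(self.states[0])


@dataclass(frozen=True)
class EnsembleSummary:
    """Empirical per-time distribution, mean and variance of an SSA ensemble."""

    grid: np.ndarray
    distributions: np.ndarray  # (n_times, N+1), each row normalised
    mean: np.ndarray
    variance: np.ndarray
    n_traj: int


def _rng_for(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def ssa_trajectory(rates: RateTable, n0: int, t_max: float, seed) -> Trajectory:
    """Simulate one exact trajectory on [0, t_max] from state ``n0``.

    If both propensities vanish the state is absorbing and the trajectory
    terminates early (logged); the path remains defined up to ``t_max``.
    """
    N = rates.N
    if not 0 <= n0 <= N:
        raise ValueError(f"n0 = {n0} outside [0, {N}]")
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    rng = _rng_for(seed)
    B = rates.birth
    D = rates.death
    t = 0.0
    n = int(n0)
    times = [0.0]
    states = [n]
    while True:
        b, d = B[n], D[n]
        tot = b + d
        if tot <= 0.0:
            logger.info("absorbing state n = %d reached at t = %.6g; trajectory ends early", n, t)
            break
        t += rng.exponential(1.0 / tot)
        if t >= t_max:
            break
        n = n + 1 if rng.random() * tot < b else n - 1
        times.append(t)
        states.append(n)
    return Trajectory(times=np.array(times), states=np.array(states),
                      t_max=float(t_max), seed=seed, rates=rates)


def sample_on_grid(traj: Trajectory, grid) -> np.ndarray:
    """State at each grid time: the value at the most recent event <= t."""
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > traj.t_max):
        raise ValueError(f"grid times must lie within [0, {traj.t_max}]")
    idx = np.searchsorted(traj.times, grid, side="right") - 1
    return traj.states[idx]


def ensemble(rates: RateTable, n0: int, grid, n_traj: int, seed) -> EnsembleSummary:
    """Independent SSA trajectories summarised on a common time grid."""
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    grid = np.asarray(grid, dtype=float)
    t_max = float(grid.max()) if grid.size else 0.0
    t_max = max(t_max, np.finfo(float).tiny)
    N = rates.N
    counts = np.zeros((grid.shape[0], N + 1), dtype=np.int64)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for k in range(n_traj):
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(k,))
        traj = ssa_trajectory(rates, n0, t_max * (1 + 1e-12) if t_max > 0 else 1.0,
                              np.random.default_rng(child))
        samples = sample_on_grid(traj, grid)
        counts[np.arange(grid.shape[0]), samples] += 1
    dists = counts / float(n_traj)
    support = np.arange(N + 1)
    mean = dists @ support
    second = dists @ support**2
    return EnsembleSummary(grid=grid, distributions=dists, mean=mean,
                           variance=second - mean**2, n_traj=n_traj)
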