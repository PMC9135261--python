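"""Likelihood-based calibration of (F, J, gamma) from observed trajectories.

The composite likelihood of a data set ``{n(t_i)}`` is the product of the
one-time marginals ``P_theta(n(t_i), t_i | n0, 0)`` computed from the exact
transient solution, conditioning every point on the known initial state.
Because ``beta`` multiplies ``F`` and ``beta (1 + alpha)`` multiplies ``J``
in the gain, only the products ``beta F`` and ``beta (1 + alpha) J`` are
identifiable; calibration therefore fixes ``beta = 1``, ``alpha = 0`` and
infers ``theta = {F, J, gamma}``, searching ``J`` and ``gamma`` in log space
inside the box ``F in [-2, 2]``, ``J in [e^-2, e^2]``, ``gamma in
[e^-1, e^1]`` with seeded differential evolution.  The optimiser returns a
good local minimum of the negative log likelihood, not a certified global
one.

Error metrics: ``E_tot`` is the sum of relative errors over the three
parameters; ``f`` is the relative error of the ratio ``F / J``, which
measures whether exogenous and endogenous influences were disentangled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .model import ModelParams, propensities
from .simulate import ensemble, sample_on_grid, ssa_trajectory
from .spectral import TransientSolution

__all__ = [
    "ParameterBox",
    "OptimiserSettings",
    "CalibrationProblem",
    "CalibrationResult",
    "ExperimentConfig",
    "negative_log_likelihood",
    "calibrate",
    "calibration_errors",
    "experiment_data_requirements",
]

logger = logging.getLogger(__name__)

#: probabilities are floored at this value before taking logs, so that
#: Monte-Carlo-rare observations give a large but finite penalty
PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class ParameterBox:
    """Search region for (F, ln J, ln gamma)."""

    F: tuple[float, float] = (-2.0, 2.0)
    logJ: tuple[float, float] = (-2.0, 2.0)
    logGamma: tuple[float, float] = (-1.0, 1.0)

    def contains(self, theta) -> bool:
        F, J, gamma = theta
        return (self.F[0] <= F <= self.F[1]
                and self.logJ[0] <= np.log(J) <= self.logJ[1] + 1e-12
                and self.logGamma[0] <= np.log(gamma) <= self.logGamma[1] + 1e-12)


@dataclass(frozen=True)
class OptimiserSettings:
    """Differential-evolution budget (desk scale, far below the full study)."""

    population: int = 50      # individuals
    generations: int = 150
    tol: float = 0.01
    seed: int = 0
    polish: bool = True


@dataclass
class CalibrationProblem:
    """Observed trajectories plus everything needed to score a parameter set.

    ``datasets`` is a list of ``(times, states)`` pairs; ``n0`` is the known
    initial state.  When ``n0`` is None, a dataset whose first observation is
    at t = 0 supplies it (that observation then contributes probability 1).
    """

    datasets: list[tuple[np.ndarray, np.ndarray]]
    N: int
    n0: int | None = None
    box: ParameterBox = field(default_factory=ParameterBox)
    beta: float = 1.0
    alpha: float = 0.0
    optimiser: OptimiserSettings = field(default_factory=OptimiserSettings)

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("at least one dataset is required")
        clean = []
        for times, states in self.datasets:
            times = np.asarray(times, dtype=float)
            states = np.asarray(states)
            if times.size == 0:
                raise ValueError("empty observation grid")
            if np.any((states < 0) | (states > self.N)):
                raise ValueError(f"observations outside [0, {self.N}]")
            if np.any(states != states.astype(int)):
                raise ValueError("observations must be integer state counts")
            clean.append((times, states.astype(int)))
        self.datasets = clean

    def resolve_n0(self) -> int:
        if self.n0 is not None:
            return int(self.n0)
        times, states = self.datasets[0]
        if times[0] == 0.0:
            return int(states[0])
        raise ValueError("n0 not given and first observation is not at t = 0")


@dataclass(frozen=True)
class CalibrationResult:
    theta_star: tuple[float, float, float]   # (F*, J*, gamma*)
    nll_star: float
    E_tot: float | None
    f: float | None
    n_evaluations: int
    converged: bool


def _observation_counts(problem: CalibrationProblem, n0: int):
    """Pool all observations into counts per (unique time, state).

    The composite likelihood only depends on these counts, so the cost of an
    evaluation is independent of the number of trajectories.  Observations at
    t = 0 equal to the known initial state contribute probability 1 and are
    dropped; an observation at t = 0 different from n0 is impossible under
    the point initial condition and is rejected.
    """
    times_all, states_all = [], []
    for times, states in problem.datasets:
        keep = times > 0.0
        bad = (~keep) & (states != n0)
        if np.any(bad):
            raise ValueError("observation at t = 0 conflicts with the known initial state")
        times_all.append(times[keep])
        states_all.append(states[keep])
    times_cat = np.concatenate(times_all)
    states_cat = np.concatenate(states_all)
    uniq, inv = np.unique(times_cat, return_inverse=True)
    counts = np.zeros((uniq.shape[0], problem.N + 1))
    np.add.at(counts, (inv, states_cat), 1.0)
    return uniq, counts


def _nll_from_counts(theta, N: int, n0: int, beta: float, alpha: float,
                     uniq_times: np.ndarray, counts: np.ndarray) -> float:
    F, J, gamma = theta
    try:
        params = ModelParams(F=F, J=J, alpha=alpha, beta=beta, gamma=gamma, N=N)
        sol = TransientSolution(propensities(params), n0)
        P = sol.probabilities_at_times(uniq_times)
    except (ValueError, ArithmeticError) as err:
        logger.debug("likelihood evaluation failed at theta=%s: %s", theta, err)
        return np.inf
    P = np.maximum(P, PROB_FLOOR)
    return float(-(counts * np.log(P)).sum())


def negative_log_likelihood(problem: CalibrationProblem, theta) -> float:
    """Composite negative log likelihood of theta = (F, J, gamma)."""
    F, J, gamma = theta
    if J <= 0 or gamma <= 0:
        raise ValueError("J and gamma must be positive")
    n0 = problem.resolve_n0()
    uniq, counts = _observation_counts(problem, n0)
    return _nll_from_counts((F, J, gamma), problem.N, n0, problem.beta,
                            problem.alpha, uniq, counts)


def calibrate(problem: CalibrationProblem,
              theta_true: tuple[float, float, float] | None = None) -> CalibrationResult:
    """Seeded differential-evolution search for theta* inside the box.

    The search runs over ``(F, ln J, ln gamma)``; the best-found parameter
    set is returned together with the calibration errors when the true
    parameters are known (synthetic-data experiments).
    """
    opt = problem.optimiser
    if opt.generations < 1 or opt.population < 4:
        raise ValueError("optimiser budget too small (need >= 4 individuals, >= 1 generation)")
    n0 = problem.resolve_n0()
    uniq, counts = _observation_counts(problem, n0)
    n_eval = 0

    def objective(x):
        nonlocal n_eval
        n_eval += 1
        theta = (x[0], np.exp(x[1]), np.exp(x[2]))
        return _nll_from_counts(theta, problem.N, n0, problem.beta,
                                problem.alpha, uniq, counts)

    bounds = [problem.box.F, problem.box.logJ, problem.box.logGamma]
    popsize = max(4, int(np.ceil(opt.population / len(bounds))))
    res = differential_evolution(
        objective, bounds,
        popsize=popsize, maxiter=opt.generations, tol=opt.tol,
        seed=opt.seed, polish=opt.polish, updating="deferred", init="sobol",
    )
    theta_star = (float(res.x[0]), float(np.exp(res.x[1])), float(np.exp(res.x[2])))
    E_tot = f = None
    if theta_true is not None:
        E_tot, f = calibration_errors(theta_true, theta_star)
    return CalibrationResult(theta_star=theta_star, nll_star=float(res.fun),
                             E_tot=E_tot, f=f, n_evaluations=n_eval,
                             converged=bool(res.success))


def calibration_errors(theta_true, theta_star) -> tuple[float, float]:
    """Total relative error E_tot and field-to-coupling ratio error f."""
    theta_true = np.asarray(theta_true, dtype=float)
    theta_star = np.asarray(theta_star, dtype=float)
    if np.any(theta_true == 0.0):
        raise ValueError("relative errors need non-zero true parameters")
    E_tot = float(np.abs((theta_true - theta_star) / theta_true).sum())
    r_true = theta_true[0] / theta_true[1]
    r_star = theta_star[0] / theta_star[1]
    f = float(abs((r_true - r_star) / r_true))
    return E_tot, f


# ---------------------------------------------------------------------------
# data-requirement experiments
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Study conditions for the data-requirement experiments.

    Defaults follow the bimodal reference parameter set (F = 0.025, J = 1.5,
    gamma = 1, N = 50, start at N/2) observed at 100 equally spaced points on
    [0, 2000].  ``horizon_fractions`` sets the calibration-time sweep for the
    single-trajectory protocols; ``point_counts`` the grid-thinning sweep;
    ``realisation_counts`` the multiple-trajectory sweep.
    """

    theta_true: tuple[float, float, float] = (0.025, 1.5, 1.0)
    N: int = 50
    n0: int = 25
    t_max: float = 2000.0
    n_points: int = 100
    horizon_fractions: tuple[float, ...] = (0.125, 0.25, 0.5, 1.0)
    point_counts: tuple[int, ...] = (10, 100, 1001)
    realisation_counts: tuple[int, ...] = (1, 11, 101)
    seed: int = 0
    optimiser: OptimiserSettings = field(default_factory=OptimiserSettings)

    def params(self) -> ModelParams:
        F, J, gamma = self.theta_true
        return ModelParams(F=F, J=J, alpha=0.0, beta=1.0, gamma=gamma, N=self.N)


def _crosses(states: np.ndarray, struct) -> bool:
    """True when the sampled path visits the core of both basins."""
    left_core = 0.5 * (struct.n_minus + struct.n_u)
    right_core = 0.5 * (struct.n_u + struct.n_plus)
    return bool(states.min() <= left_core and states.max() >= right_core)


def _find_trajectory(config: ExperimentConfig, want_both_modes: bool, struct,
                     max_tries: int = 200):
    """Simulate until a trajectory does (or does not) explore both basins."""
    rates = propensities(config.params())
    grid = np.linspace(0.0, config.t_max, config.n_points)
    root = np.random.SeedSequence(config.seed)
    for k in range(max_tries):
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(1000 + k,))
        traj = ssa_trajectory(rates, config.n0, config.t_max * (1 + 1e-12),
                              np.random.default_rng(child))
        states = sample_on_grid(traj, grid)
        if _crosses(states, struct) == want_both_modes:
            return traj, grid, states
    raise RuntimeError("no trajectory with the requested mode coverage found")


def experiment_data_requirements(config: ExperimentConfig | None = None) -> pd.DataFrame:
    """Run the three calibration data-requirement protocols.

    (i) one trajectory confined to a single mode, increasing calibration
    horizon; (ii) one trajectory that explores both modes, increasing horizon
    and, separately, varying number of observation points; (iii) increasing
    numbers of independent realisations.  Returns a tidy table with columns
    protocol, condition, E_tot, f, nll_star, seed.
    """
    if config is None:
        config = ExperimentConfig()
    params = config.params()
    rates = propensities(params)
    from .passage import find_unstable_point
    from .spectral import steady_state
    struct = find_unstable_point(steady_state(rates))
    rows = []

    def run(datasets, protocol, condition):
        problem = CalibrationProblem(datasets=datasets, N=config.N, n0=config.n0,
                                     optimiser=config.optimiser)
        result = calibrate(problem, theta_true=config.theta_true)
        rows.append({"protocol": protocol, "condition": condition,
                     "E_tot": result.E_tot, "f": result.f,
                     "nll_star": result.nll_star, "seed": config.optimiser.seed})

    # (i) single trajectory, one mode only, varying horizon
    _, grid, states = _find_trajectory(config, want_both_modes=False, struct=struct)
    for frac in config.horizon_fractions:
        keep = grid <= frac * config.t_max
        run([(grid[keep], states[keep])], "single_one_mode", f"horizon={frac:g}")

    # (ii) single trajectory exploring both modes: horizon sweep, then point sweep
    traj2, grid2, states2 = _find_trajectory(config, want_both_modes=True, struct=struct)
    for frac in config.horizon_fractions:
        keep = grid2 <= frac * config.t_max
        run([(grid2[keep], states2[keep])], "single_both_modes", f"horizon={frac:g}")
    # re-sample the same underlying event path at different observation densities
    for n_pts in config.point_counts:
        grid_p = np.linspace(0.0, config.t_max, n_pts)
        run([(grid_p, sample_on_grid(traj2, grid_p))],
            "single_both_modes_points", f"points={n_pts}")

    # (iii) multiple realisations
    grid3 = np.linspace(0.0, config.t_max, config.n_points)
    max_count = max(config.realisation_counts)
    root = np.random.SeedSequence(config.seed)
    all_sets = []
    for k in range(max_count):
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(k,))
        traj = ssa_trajectory(rates, config.n0, config.t_max * (1 + 1e-12),
                              np.random.default_rng(child))
        all_sets.append((grid3, sample_on_grid(traj, grid3)))
    for count in config.realisation_counts:
        run(all_sets[:count], "multiple_realisations", f"realisations={count}")

    return pd.DataFrame(rows)
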