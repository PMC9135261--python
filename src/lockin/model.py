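"""Mean-field binary decision model: parameters, decision rules and propensities.

A population of ``N`` agents each holds one of two opinions (spin ``S_i = -1``
for *left*, ``+1`` for *right*).  In the mean-field approximation the state of
the system is fully described by the number ``n`` of right-deciding agents, or
equivalently by the order parameter ``m(n) = (2n - N)/N`` in ``[-1, 1]``.
Every agent feels the same *influence* ``I(n) = F + J m(n)``: an exogenous
field ``F`` (the zeitgeist, e.g. a cost difference between two technologies)
plus a conformity term proportional to the average opinion with interaction
strength ``J``.

Agents flip their decision stochastically.  The flip rate depends on the
*gain* ``G``, a generalised utility change that interpolates between purely
selfish agents (``alpha = 0``, the gain is the agent's own utility change) and
fully altruistic agents (``alpha = 1``, the gain is the change in total
population utility).  With the logit (Glauber) rule the per-agent flip rate is
``gamma / (1 + exp(-beta * G))``, where ``beta`` plays the role of an inverse
temperature: ``beta -> 0`` gives random switching at rate ``gamma / 2`` and
``beta -> infinity`` gives deterministic utility-following.

Aggregated over the population the dynamics is a one-step birth-death process
on ``n = 0 .. N`` with propensities ``birth[n] = (N - n) r(n)`` and
``death[n] = n l(n)``; this :class:`RateTable` is the object every other
module of the package consumes.  Kirman's ant-recruitment model is supported
as an alternative rate family with spontaneous switching rate ``epsilon`` and
pairwise recruitment rate ``mu``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ModelParams",
    "KirmanParams",
    "RateTable",
    "FixedPoint",
    "Direction",
    "RateRule",
    "order_parameter",
    "influence",
    "gain",
    "transition_rate",
    "propensities",
    "hamiltonian",
    "critical_beta",
    "mean_field_fixed_points",
]

Direction = Literal["left_to_right", "right_to_left"]
RateRule = Literal["logit", "arrhenius"]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the mean-field binary decision model.

    Attributes
    ----------
    F : float
        Exogenous field (zeitgeist) biasing all agents equally.
    J : float
        Agent-to-agent interaction (conformity) strength, ``>= 0``.
    alpha : float
        Altruism weight in ``[0, 1]``; 0 = selfish, 1 = fully altruistic.
    beta : float
        Agent rationality (inverse temperature), ``>= 0``.
    gamma : float
        Overall decision time-scale rate, ``> 0``.
    N : int
        Number of agents, ``>= 1``.
    include_self_interaction : bool
        Keep the ``2 (1 + alpha) J / N`` term in the gain, which accounts for
        the flipping agent's own contribution to ``m(n)``.  On by default.
    """

    F: float
    J: float
    alpha: float = 0.0
    beta: float = 1.0
    gamma: float = 1.0
    N: int = 50
    include_self_interaction: bool = True

    def __post_init__(self) -> None:
        if self.J < 0:
            raise ValueError(f"J must be >= 0, got {self.J}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"N must be an integer >= 1, got {self.N}")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class KirmanParams:
    """Parameters of Kirman's ant-recruitment model.

    ``epsilon`` is the rate of spontaneous switching per ant, ``mu`` the rate
    of recruitment per pair of ants at different food sources.  The
    proportionality constant of the propensities is taken as 1, with any
    overall time scale absorbed into ``epsilon`` and ``mu``.
    """

    epsilon: float
    mu: float
    N: int

    def __post_init__(self) -> None:
        if self.epsilon < 0 or self.mu < 0:
            raise ValueError("epsilon and mu must be >= 0")
        if self.epsilon == 0 and self.mu == 0:
            raise ValueError("at least one of epsilon, mu must be positive")
        if int(self.N) != self.N or self.N < 2:
            raise ValueError(f"N must be an integer >= 2, got {self.N}")


@dataclass(frozen=True)
class RateTable:
    """Aggregate birth/death propensities of the one-step chain on 0..N.

    ``birth[n]`` is the rate of the transition ``n -> n + 1`` and ``death[n]``
    of ``n -> n - 1``.  The boundaries satisfy ``birth[N] = 0`` and
    ``death[0] = 0`` so the chain never leaves ``[0, N]``.
    """

    birth: np.ndarray
    death: np.ndarray

    def __post_init__(self) -> None:
        birth = np.asarray(self.birth, dtype=float)
        death = np.asarray(self.death, dtype=float)
        object.__setattr__(self, "birth", birth)
        object.__setattr__(self, "death", death)
        if birth.ndim != 1 or birth.shape != death.shape:
            raise ValueError("birth and death must be 1-D arrays of equal length")
        if birth.shape[0] < 2:
            raise ValueError("need at least two states (N >= 1)")
        if np.any(birth < 0) or np.any(death < 0):
            raise ValueError("propensities must be non-negative")
        if birth[-1] != 0 or death[0] != 0:
            raise ValueError("boundary propensities birth[N] and death[0] must vanish")

    @property
    def N(self) -> int:
        return self.birth.shape[0] - 1

    @property
    def n_states(self) -> int:
        return self.birth.shape[0]

    def is_irreducible(self) -> bool:
        """True when every interior transition has a strictly positive rate."""
        return bool(np.all(self.birth[:-1] > 0) and np.all(self.death[1:] > 0))


@dataclass(frozen=True)
class FixedPoint:
    """A root of the mean-field self-consistency map, tagged by stability."""

    m: float
    stable: bool


def order_parameter(n, N: int):
    """Average opinion ``m(n) = (2n - N)/N``."""
    return (2.0 * np.asarray(n) - N) / N


def _check_state(n, N: int) -> None:
    n = np.asarray(n)
    if np.any(n < 0) or np.any(n > N):
        raise ValueError(f"state count n must lie in [0, {N}]")


def influence(n, params: ModelParams):
    """Shared information field ``I(n) = F + J m(n)`` felt by every agent."""
    _check_state(n, params.N)
    return params.F + params.J * order_parameter(n, params.N)


def gain(direction: Direction, n, params: ModelParams):
    """Generalised utility change for one agent flipping at state ``n``.

    ``G = -2 S (F + J m(n) (1 + alpha)) + 2 (1 + alpha) J / N`` where
    ``S = -1`` for a left agent flipping to the right and ``S = +1`` for a
    right agent flipping to the left.  The last (self-interaction) term is
    dropped when the parameter flag says so.
    """
    N = params.N
    _check_state(n, N)
    n = np.asarray(n)
    if direction == "left_to_right":
        S = -1.0
        if np.any(n >= N):
            raise ValueError("no left-deciding agent available to flip at n = N")
    elif direction == "right_to_left":
        S = 1.0
        if np.any(n <= 0):
            raise ValueError("no right-deciding agent available to flip at n = 0")
    else:
        raise ValueError(f"unknown direction {direction!r}")
    m = order_parameter(n, N)
    G = -2.0 * S * (params.F + params.J * m * (1.0 + params.alpha))
    if params.include_self_interaction:
        G = G + 2.0 * (1.0 + params.alpha) * params.J / N
    return G


def transition_rate(gain_value, params: ModelParams, rule: RateRule = "logit"):
    """Per-agent flip rate for a given gain.

    logit (Glauber): ``gamma / (1 + exp(-beta * G))``, the rule satisfying
    detailed balance with respect to the Boltzmann weight ``exp(beta * H)``.

    arrhenius: ``gamma * exp(beta * U_post)`` where the caller supplies the
    post-flip utility as the ``gain_value`` argument.  Detailed balance holds,
    but the gain/Hamiltonian identity of the logit rule does not apply.
    """
    g = np.asarray(gain_value, dtype=float)
    if rule == "logit":
        # exp saturates cleanly for large |beta * g|; no overflow for g < 0
        with np.errstate(over="ignore"):
            return params.gamma / (1.0 + np.exp(-params.beta * g))
    if rule == "arrhenius":
        return params.gamma * np.exp(params.beta * g)
    raise ValueError(f"unknown rate rule {rule!r}")


def _per_agent_rates(params: ModelParams, rule: RateRule):
    """Per-agent flip rates r(n) (left->right) and l(n) (right->left)."""
    N = params.N
    n = np.arange(N + 1)
    m = order_parameter(n, N)
    si = 2.0 * (1.0 + params.alpha) * params.J / N if params.include_self_interaction else 0.0
    drive = 2.0 * (params.F + params.J * m * (1.0 + params.alpha))
    if rule == "logit":
        r = transition_rate(drive + si, params, "logit")
        l = transition_rate(-drive + si, params, "logit")
    elif rule == "arrhenius":
        # post-flip utility U' = S' I(n') for the flipping agent
        n_after_lr = n + 1  # left agent flips: S' = +1, n -> n + 1
        n_after_rl = n - 1  # right agent flips: S' = -1, n -> n - 1
        u_lr = +(params.F + params.J * order_parameter(np.clip(n_after_lr, 0, N), N))
        u_rl = -(params.F + params.J * order_parameter(np.clip(n_after_rl, 0, N), N))
        r = transition_rate(u_lr, params, "arrhenius")
        l = transition_rate(u_rl, params, "arrhenius")
    else:
        raise ValueError(f"unknown rate rule {rule!r}")
    return r, l


def propensities(params: ModelParams | KirmanParams, rule: RateRule = "logit") -> RateTable:
    """Aggregate mass-action propensity table of the birth-death chain.

    Decision model: ``birth[n] = (N - n) r(n)``, ``death[n] = n l(n)``.
    Kirman: ``birth[n] = (N - n) eps + mu (N - n) n / (N - 1)`` and
    ``death[n] = n eps + mu (N - n) n / (N - 1)`` (the ``rule`` argument is
    ignored for Kirman parameters).
    """
    if isinstance(params, KirmanParams):
        N = params.N
        n = np.arange(N + 1, dtype=float)
        pair = params.mu * (N - n) * n / (N - 1)
        birth = (N - n) * params.epsilon + pair
        death = n * params.epsilon + pair
        return RateTable(birth=birth, death=death)
    N = params.N
    n = np.arange(N + 1, dtype=float)
    r, l = _per_agent_rates(params, rule)
    return RateTable(birth=(N - n) * r, death=n * l)


def hamiltonian(n, params: ModelParams):
    """Energy-like state function ``H(n) = N m (F + (1/2)(alpha + 1) J m)``.

    Its discrete gradient equals the gain of the logit rule when the
    self-interaction term is kept: ``H(n + 1) - H(n) = G(left_to_right, n)``,
    so the chain is in detailed balance with ``P_eq(n) prop C(N, n)
    exp(beta H(n))``.
    """
    _check_state(n, params.N)
    m = order_parameter(n, params.N)
    return params.N * m * (params.F + 0.5 * (params.alpha + 1.0) * params.J * m)


def critical_beta(params: ModelParams) -> float:
    """Critical rationality ``beta_c = 1 / (J (1 + alpha))`` (at F = 0).

    For ``beta > beta_c`` the population spontaneously polarises and the
    stationary distribution is bimodal; below it there is a single mode at
    ``m = 0``.
    """
    if params.J <= 0:
        raise ValueError("critical rationality requires J > 0")
    return 1.0 / (params.J * (1.0 + params.alpha))


def mean_field_fixed_points(params: ModelParams) -> list[FixedPoint]:
    """All real roots of the self-consistency map ``m = tanh(beta (F + J (alpha + 1) m))``.

    Roots are located by a dense scan of ``[-1, 1]`` (step 1e-4) followed by
    bisection refinement to 1e-10; the map is smooth with at most three
    roots.  A root is stable iff the slope of the map there is below one.
    """
    b, F, Jeff = params.beta, params.F, params.J * (1.0 + params.alpha)

    def g(m):
        return np.tanh(b * (F + Jeff * m)) - m

    grid = np.linspace(-1.0, 1.0, 20001)
    vals = g(grid)
    roots: list[float] = []

    def add(root: float) -> None:
        if not any(abs(root - r) < 1e-7 for r in roots):
            roots.append(root)

    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            add(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            add(brentq(g, grid[i], grid[i + 1], xtol=1e-10))
    if vals[-1] == 0.0:
        add(grid[-1])

    out = []
    for m in sorted(roots):
        slope = b * Jeff * (1.0 - np.tanh(b * (F + Jeff * m)) ** 2)
        out.append(FixedPoint(m=float(m), stable=bool(slope < 1.0)))
    return out
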