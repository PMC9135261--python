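"""Metastability: first-passage times, splitting probability, two-state reduction.

When conformity dominates the exogenous field (``beta > beta_c`` and ``|F| <
J (alpha + 1)``) the stationary distribution of the chain is bimodal and the
dynamics exhibits lock-ins: the population coalesces on one decision — not
necessarily the optimal one — and stays there for a time exponential in N.
On time scales longer than ``1/|lambda_3|`` the chain reduces to a two-state
process hopping between the left and right modes.  The ingredients are:

* the interior minimum ``n_u`` of the stationary distribution (the unstable
  equilibrium separating the basins),
* exact mean first-passage times ``tau_n`` to reach ``n_u`` from every state,
  from closed-form nested sums (evaluated in log space) that are validated
  against the normative tridiagonal linear system,
* mode-escape times ``tau_lr``, ``tau_rl`` as steady-state-conditional
  averages of ``tau_n`` over each basin,
* the splitting probability ``phi_R`` that a system started at ``n_u``
  coalesces on the right mode before the left one,
* the relaxation rate approximation
  ``lambda_2 = phi_R / tau_lr + (1 - phi_R) / tau_rl``,

which together give a closed-form approximation to the full distribution in
the metastable regime, ``P(n, t) ~ P_s(n) + exp(-lambda_2 t) Phi_2(n)``,
without computing any eigenvalues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import logsumexp

from .model import ModelParams, RateTable, order_parameter
from .spectral import DistributionOnStates, steady_state

__all__ = [
    "NotBistableError",
    "MetastableStructure",
    "PassageResult",
    "TwoStateSolution",
    "find_unstable_point",
    "mfpt_exact",
    "mfpt_linear_solve",
    "splitting_probability",
    "splitting_probability_linear_solve",
    "mode_escape_times",
    "initial_left_mass",
    "relaxation_rate",
    "two_state_reduction",
    "metastable_distribution",
    "mfpt_asymptotic_exponent",
    "passage_analysis",
]

logger = logging.getLogger(__name__)


class NotBistableError(ValueError):
    """The stationary distribution has no two interior-separated modes."""


@dataclass(frozen=True)
class MetastableStructure:
    """Left mode, interior unstable point and right mode of a bimodal P_s."""

    n_minus: int
    n_u: int
    n_plus: int
    N: int

    def __post_init__(self) -> None:
        if not self.n_minus < self.n_u < self.n_plus:
            raise ValueError("modes must satisfy n_minus < n_u < n_plus")

    @property
    def m_minus(self) -> float:
        return float(order_parameter(self.n_minus, self.N))

    @property
    def m_u(self) -> float:
        return float(order_parameter(self.n_u, self.N))

    @property
    def m_plus(self) -> float:
        return float(order_parameter(self.n_plus, self.N))


@dataclass(frozen=True)
class TwoStateSolution:
    """Closed-form solution of the two-state mode-hopping reduction.

    ``pi_L(t) = pi_L_s + (pi_L(0) - pi_L_s) exp(-lambda_2 t)`` with
    ``pi_L_s / pi_R_s = tau_lr (1 - phi_R) / (tau_rl phi_R)``.
    """

    phi_R: float
    tau_lr: float
    tau_rl: float
    piL0: float

    @property
    def lambda2(self) -> float:
        return self.phi_R / self.tau_lr + (1.0 - self.phi_R) / self.tau_rl

    @property
    def pi_L_s(self) -> float:
        k_rl = (1.0 - self.phi_R) / self.tau_rl  # right -> left transfer rate
        return k_rl / self.lambda2

    @property
    def pi_R_s(self) -> float:
        return 1.0 - self.pi_L_s

    @property
    def stationary_ratio(self) -> float:
        """pi_L_s / pi_R_s."""
        return self.tau_lr * (1.0 - self.phi_R) / (self.tau_rl * self.phi_R)

    def pi_L(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.pi_L_s + (self.piL0 - self.pi_L_s) * np.exp(-self.lambda2 * t)

    def pi_R(self, t) -> np.ndarray:
        return 1.0 - self.pi_L(t)


@dataclass(frozen=True)
class PassageResult:
    """Full first-passage report for a bistable chain."""

    structure: MetastableStructure
    tau: np.ndarray            # mean first-passage time to n_u from each state
    tau_lr: float
    tau_rl: float
    phi_R: float
    lambda2_approx: float
    pi_L_s: float
    pi_R_s: float

    @property
    def relaxation_time(self) -> float:
        return 1.0 / self.lambda2_approx


def find_unstable_point(Ps: DistributionOnStates) -> MetastableStructure:
    """Locate the two modes and the interior minimum of a bimodal P_s.

    The two largest local maxima become ``n_minus`` / ``n_plus`` and ``n_u``
    is the argmin strictly between them, ties broken toward the midpoint.
    Raises :class:`NotBistableError` for a monomodal distribution.
    """
    p = Ps.probs
    K = p.shape[0]
    maxima = []
    for i in range(K):
        left_ok = i == 0 or p[i] > p[i - 1]
        right_ok = i == K - 1 or p[i] >= p[i + 1]
        if left_ok and right_ok:
            maxima.append(i)
    if len(maxima) < 2:
        raise NotBistableError(
            "steady state is not bimodal: fewer than two separated local maxima"
        )
    top_two = sorted(sorted(maxima, key=lambda i: -p[i])[:2])
    n_minus, n_plus = top_two
    interior = np.arange(n_minus + 1, n_plus)
    if interior.size == 0:
        raise NotBistableError("modes are adjacent; no interior minimum exists")
    pmin = p[interior].min()
    candidates = interior[p[interior] == pmin]
    midpoint = 0.5 * (n_minus + n_plus)
    n_u = int(candidates[np.argmin(np.abs(candidates - midpoint))])
    if p[n_u] >= min(p[n_minus], p[n_plus]):
        raise NotBistableError("interior minimum is not below both modes")
    return MetastableStructure(n_minus=n_minus, n_u=int(n_u), n_plus=n_plus, N=Ps.N)


def _log_eta_below(B: np.ndarray, D: np.ndarray, n_u: int) -> np.ndarray:
    """log |eta_i| for i = 1..n_u, eta_i = tau_i - tau_{i-1} on the left side.

    eta_i = -sum_{j=1}^{i} (1/B[j-1]) prod_{k=j}^{i-1} D[k]/B[k]; returned is
    the log of the (positive) magnitude, evaluated with log-sum-exp.
    """
    logB = np.log(B[:n_u])            # B[0..n_u-1], all > 0 for irreducible
    c = np.zeros(n_u)                 # c[k] = log D[k] - log B[k], k = 1..n_u-1
    if n_u > 1:
        c[1:] = np.log(D[1:n_u]) - np.log(B[1:n_u])
    S = np.cumsum(c)                  # S[k] = sum_{j<=k} c[j], S[0] = 0
    # term(j, i) = -logB[j-1] + sum_{k=j}^{i-1} c[k] = -logB[j-1] + S[i-1] - S[j-1]
    base = -logB - S                  # index j-1 = 0..n_u-1 -> -logB[j-1] - S[j-1]
    out = np.empty(n_u)
    for i in range(1, n_u + 1):
        out[i - 1] = S[i - 1] + logsumexp(base[:i])
    return out


def mfpt_exact(rates: RateTable, n_u: int) -> np.ndarray:
    """Exact mean first-passage times to ``n_u`` from every state.

    Closed-form nested-sum/product expressions evaluated in log space: below
    ``n_u`` the chain reflects at 0, above it reflects at N (obtained by
    mirroring the chain).  ``tau[n_u] = 0``.
    """
    N = rates.N
    if not 0 < n_u < N:
        raise ValueError("n_u must be an interior state")
    B, D = rates.birth, rates.death
    tau = np.zeros(N + 1)
    # below: tau_n = sum_{i=n+1}^{n_u} |eta_i|
    log_eta = _log_eta_below(B, D, n_u)
    mags = np.exp(log_eta)
    tau[:n_u] = np.cumsum(mags[::-1])[::-1]
    # above: mirror n -> N - n swaps the roles of birth and death
    Bm, Dm = D[::-1], B[::-1]
    log_eta_m = _log_eta_below(Bm, Dm, N - n_u)
    mags_m = np.exp(log_eta_m)
    tau_m = np.cumsum(mags_m[::-1])[::-1]      # times for mirrored states 0..N-n_u-1
    tau[n_u + 1:] = tau_m[::-1]
    return tau


def mfpt_linear_solve(rates: RateTable, n_u: int) -> np.ndarray:
    """Mean first-passage times from the tridiagonal backward linear system.

    ``B[i] tau_{i+1} + D[i] tau_{i-1} - (B[i] + D[i]) tau_i = -1`` with
    ``tau_{n_u} = 0`` and reflection at the outer boundaries.  This is the
    normative definition; the closed forms of :func:`mfpt_exact` are an
    equivalent fast path.
    """
    N = rates.N
    if not 0 < n_u < N:
        raise ValueError("n_u must be an interior state")
    B, D = rates.birth, rates.death
    tau = np.zeros(N + 1)

    def solve_block(states: np.ndarray) -> np.ndarray:
        k = states.shape[0]
        ab = np.zeros((3, k))
        rhs = -np.ones(k)
        for idx, i in enumerate(states):
            ab[1, idx] = -(B[i] + D[i])
            if idx > 0:
                ab[2, idx - 1] = D[i]          # sub-diagonal: coupling to i-1
            if idx < k - 1:
                ab[0, idx + 1] = B[i]          # super-diagonal: coupling to i+1
        return solve_banded((1, 1), ab, rhs)

    if n_u > 0:
        tau[:n_u] = solve_block(np.arange(n_u))
    if n_u < N:
        tau[n_u + 1:] = solve_block(np.arange(n_u + 1, N + 1))
    return tau


def splitting_probability(rates: RateTable, struct: MetastableStructure) -> float:
    """Probability phi_R of reaching the right mode before the left one from n_u.

    Solves the discrete harmonic problem ``h(n_minus) = 0``, ``h(n_plus) = 1``
    with ``B[n](h(n+1) - h(n)) = D[n](h(n) - h(n-1))`` via the standard
    product-ratio summation in log space and returns ``h(n_u)``.
    """
    B, D = rates.birth, rates.death
    a, u, b = struct.n_minus, struct.n_u, struct.n_plus
    # increment Delta_k = h(k+1) - h(k) prop prod_{j=a+1}^{k} D[j]/B[j], k = a..b-1
    logratio = np.concatenate([[0.0], np.cumsum(np.log(D[a + 1:b]) - np.log(B[a + 1:b]))])
    num = logsumexp(logratio[: u - a])     # increments k = a .. u-1
    den = logsumexp(logratio)              # increments k = a .. b-1
    return float(np.exp(num - den))


def splitting_probability_linear_solve(rates: RateTable, struct: MetastableStructure) -> float:
    """phi_R from a direct tridiagonal solve with absorbing modes (oracle)."""
    B, D = rates.birth, rates.death
    a, b, u = struct.n_minus, struct.n_plus, struct.n_u
    states = np.arange(a + 1, b)
    k = states.shape[0]
    ab = np.zeros((3, k))
    rhs = np.zeros(k)
    for idx, i in enumerate(states):
        ab[1, idx] = -(B[i] + D[i])
        if idx > 0:
            ab[2, idx - 1] = D[i]
        if idx < k - 1:
            ab[0, idx + 1] = B[i]
        else:
            rhs[idx] -= B[i]              # absorption at n_plus with h = 1
    h = solve_banded((1, 1), ab, rhs)
    return float(h[u - (a + 1)])


def mode_escape_times(rates: RateTable, Ps: DistributionOnStates,
                      struct: MetastableStructure,
                      tau: np.ndarray) -> tuple[float, float]:
    """Mode-escape times as conditional steady-state averages of tau_n.

    ``tau_lr`` weights the left basin ``n < n_u`` by ``rho_l(n) = P_s(n) /
    sum_{n < n_u} P_s`` and likewise ``tau_rl`` for the right basin.
    """
    p = Ps.probs
    u = struct.n_u
    wl = p[:u] / p[:u].sum()
    wr = p[u + 1:] / p[u + 1:].sum()
    return float(wl @ tau[:u]), float(wr @ tau[u + 1:])


def relaxation_rate(phi_R: float, tau_lr: float, tau_rl: float) -> float:
    """First-passage approximation of the relaxation rate lambda_2."""
    if tau_lr <= 0 or tau_rl <= 0 or not 0.0 <= phi_R <= 1.0:
        raise ValueError("escape times must be positive and phi_R in [0, 1]")
    return phi_R / tau_lr + (1.0 - phi_R) / tau_rl


def two_state_reduction(phi_R: float, tau_lr: float, tau_rl: float,
                        piL0: float) -> TwoStateSolution:
    """Closed-form two-state mode-hopping dynamics pi_L(t), pi_R(t)."""
    if not 0.0 <= piL0 <= 1.0:
        raise ValueError("piL0 must be a probability")
    return TwoStateSolution(phi_R=phi_R, tau_lr=tau_lr, tau_rl=tau_rl, piL0=piL0)


def metastable_distribution(Ps: DistributionOnStates, struct: MetastableStructure,
                            lambda2: float, piL0: float, t: float) -> DistributionOnStates:
    """Closed-form distribution in the metastable regime (t >> 1/|lambda_3|).

    ``P(n, t) = P_s(n) + exp(-lambda_2 t) Phi_2(n)`` with the slow eigenvector
    approximated by the signed difference of the basin-conditional modes,
    ``Phi_2(n) = (piL0 - pi_L_s)(rho_l(n) 1[n < n_u] - rho_r(n) 1[n > n_u])``,
    which sums to zero.  Raises if ``t`` is too small for the approximation
    to yield a valid distribution.
    """
    p = Ps.probs
    u = struct.n_u
    pi_L_s = float(p[:u].sum())
    phi2 = np.zeros_like(p)
    phi2[:u] = p[:u] / p[:u].sum()
    phi2[u + 1:] = -p[u + 1:] / p[u + 1:].sum()
    phi2 *= (piL0 - pi_L_s)
    out = p + np.exp(-lambda2 * t) * phi2
    if out.min() < -1e-12:
        raise ValueError(
            "metastable approximation produced negative probabilities; "
            "t is below the validity threshold — use the full spectral solution"
        )
    return DistributionOnStates(out)


def initial_left_mass(rates: RateTable, struct: MetastableStructure, n0: int,
                      phi_R: float | None = None) -> float:
    """Default pi_L(0) for the metastable approximation.

    A start exactly at the unstable point splits with probability
    ``1 - phi_R`` into the left basin; any other start is propagated with the
    full solution to ``t = 10 / |Re lambda_3|`` (by when the fast modes have
    decayed) and its left-basin mass is read off.
    """
    if n0 == struct.n_u:
        if phi_R is None:
            phi_R = splitting_probability(rates, struct)
        return 1.0 - phi_R
    from .spectral import TransientSolution, build_operator, spectrum as _spectrum

    lam3 = _spectrum(build_operator(rates)).lambda3
    t_star = 10.0 / abs(lam3.real)
    P = TransientSolution(rates, n0).at(t_star).probs
    return float(P[: struct.n_u].sum())


def mfpt_asymptotic_exponent(params: ModelParams) -> tuple[float, float]:
    """Large-N exponents of the mode-escape times.

    In the diffusion (Fokker-Planck) limit the escape times grow as
    ``tau_lr prop exp(N (1 - F / (J (1 + alpha))))`` and
    ``tau_rl prop exp(N (1 + F / (J (1 + alpha))))``: switching times are
    exponential in the number of agents, with the optimal mode (same sign as
    F) exponentially harder to leave.
    """
    ratio = params.F / (params.J * (1.0 + params.alpha))
    return params.N * (1.0 - ratio), params.N * (1.0 + ratio)


def passage_analysis(rates: RateTable, Ps: DistributionOnStates | None = None) -> PassageResult:
    """Run the full first-passage pipeline on a bistable chain."""
    if Ps is None:
        Ps = steady_state(rates)
    struct = find_unstable_point(Ps)
    tau = mfpt_exact(rates, struct.n_u)
    tau_lr, tau_rl = mode_escape_times(rates, Ps, struct, tau)
    phi_R = splitting_probability(rates, struct)
    lam2 = relaxation_rate(phi_R, tau_lr, tau_rl)
    reduction = two_state_reduction(phi_R, tau_lr, tau_rl, piL0=1.0 - phi_R)
    return PassageResult(structure=struct, tau=tau, tau_lr=tau_lr, tau_rl=tau_rl,
                         phi_R=phi_R, lambda2_approx=lam2,
                         pi_L_s=reduction.pi_L_s, pi_R_s=reduction.pi_R_s)
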