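"""Master operator, spectrum and exact time-dependent distributions.

The probability vector ``P(t) = (P(0,t), ..., P(N,t))`` of the birth-death
chain obeys the master (forward Kolmogorov) equation ``dP/dt = A P`` with a
tridiagonal generator ``A`` whose columns sum to zero.  By Perron-Frobenius
the largest eigenvalue is ``lambda_1 = 0`` (its eigenvector is the stationary
distribution) and all other eigenvalues have negative real part; ``1 /
|Re lambda_2|`` is the relaxation time to stationarity.

The transient solution from a point initial condition is evaluated in closed
form as a sum of residues of the resolvent ``(y I - A)^{-1}``: for each
eigenvalue the residue factorises into products of rates between the source
and target states and two families of orthogonal polynomials (determinants of
leading/trailing principal minors of ``y I - A``) evaluated by three-term
recursions.  No eigenvectors are computed.  Since the individual factors span
hundreds of orders of magnitude, every recursion carries a separate
log-magnitude and the terms are combined in complex log space.

Finite-precision eigenvalues of these operators are a *pseudospectrum*: they
may come in complex-conjugate pairs even though the true spectrum is real,
and in deeply bistable regimes pairs become numerically degenerate, which
makes the residue denominators ``prod(lambda_i - lambda_j)`` ill-conditioned.
The solver detects this (eigenvalue-gap precheck plus normalisation,
negativity and imaginary-residue postchecks) and falls back to a direct
matrix-exponential evaluation ``expm(A t) @ delta_n0``.

The stationary distribution itself is computed from the Kirchhoff
product-of-rates formula in log space, which is exact for any irreducible
one-step chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import eigvals as dense_eigvals
from scipy.linalg import expm
from scipy.special import logsumexp

from .model import RateTable, order_parameter

__all__ = [
    "MasterOperator",
    "Spectrum",
    "DistributionOnStates",
    "TransientSolution",
    "build_operator",
    "spectrum",
    "transient_solution",
    "transient_distribution",
    "transient_from_mixture",
    "steady_state",
]

logger = logging.getLogger(__name__)

#: default relative eigenvalue-gap tolerance below which the residue formula
#: is considered ill-conditioned and the matrix-exponential path is used
DEGENERACY_TOL = 1e-8
#: tolerated deviation of a computed distribution from exact normalisation
NORMALISATION_TOL = 1e-8
#: tolerated imaginary residue when complex-conjugate eigenvalue pairs are summed
IMAG_TOL = 1e-8
#: probabilities in (-CLIP_TOL, 0) are clipped to zero; anything more negative errors
CLIP_TOL = 1e-12


@dataclass(frozen=True)
class MasterOperator:
    """Tridiagonal generator of the chain; columns sum to zero."""

    matrix: np.ndarray
    rates: RateTable

    @property
    def dimension(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class Spectrum:
    """Eigenvalues of a master operator, sorted by descending real part.

    ``lambda1`` is snapped to exactly zero.  ``degenerate`` flags a pair of
    eigenvalues closer (relative to the spectral radius) than the tolerance
    used at construction; transient evaluation then falls back to the matrix
    exponential.
    """

    eigenvalues: np.ndarray
    degenerate: bool
    degeneracy_tol: float

    @property
    def lambda1(self) -> complex:
        return complex(self.eigenvalues[0])

    @property
    def lambda2(self) -> complex:
        return complex(self.eigenvalues[1])

    @property
    def lambda3(self) -> complex:
        return complex(self.eigenvalues[2])

    @property
    def relaxation_time(self) -> float:
        """``1 / |Re lambda_2|``, the time scale to reach stationarity."""
        return 1.0 / abs(self.lambda2.real)

    def min_gap(self) -> float:
        lam = self.eigenvalues
        diffs = np.abs(lam[:, None] - lam[None, :])
        np.fill_diagonal(diffs, np.inf)
        return float(diffs.min())


@dataclass(frozen=True)
class DistributionOnStates:
    """Probability vector over n = 0..N with an order-parameter view."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 1:
            raise ValueError("probs must be a 1-D vector")
        if probs.min() < -CLIP_TOL:
            raise ValueError(
                f"distribution has entry {probs.min():.3e} below -{CLIP_TOL:.0e}"
            )
        probs = np.clip(probs, 0.0, None)
        total = probs.sum()
        if abs(total - 1.0) > NORMALISATION_TOL:
            raise ValueError(f"distribution sums to {total!r}, not 1")
        object.__setattr__(self, "probs", probs / total)

    @property
    def N(self) -> int:
        return self.probs.shape[0] - 1

    @property
    def m(self) -> np.ndarray:
        """Order-parameter grid m(n) = (2n - N)/N matching ``probs``."""
        return order_parameter(np.arange(self.N + 1), self.N)

    def mean_n(self) -> float:
        return float(np.arange(self.N + 1) @ self.probs)

    def mean_m(self) -> float:
        return float(self.m @ self.probs)

    @staticmethod
    def point_mass(n0: int, N: int) -> "DistributionOnStates":
        p = np.zeros(N + 1)
        p[n0] = 1.0
        return DistributionOnStates(p)

    @staticmethod
    def total_variation(a: "DistributionOnStates", b: "DistributionOnStates") -> float:
        return 0.5 * float(np.abs(a.probs - b.probs).sum())


def build_operator(rates: RateTable) -> MasterOperator:
    """Assemble the (N+1) x (N+1) tridiagonal generator from a rate table."""
    B, D = rates.birth, rates.death
    K = rates.n_states
    A = np.zeros((K, K))
    idx = np.arange(K)
    A[idx, idx] = -(B + D)
    A[idx[1:], idx[:-1]] = B[:-1]
    A[idx[:-1], idx[1:]] = D[1:]
    return MasterOperator(matrix=A, rates=rates)


def spectrum(op: MasterOperator | RateTable, degeneracy_tol: float = DEGENERACY_TOL) -> Spectrum:
    """Eigenvalues of the generator, sorted by descending real part.

    lambda_1 is snapped to exactly 0 (Perron-Frobenius); complex-conjugate
    pseudospectrum pairs are retained.  A pair closer than
    ``degeneracy_tol * spectral_radius`` marks the spectrum degenerate.
    """
    if isinstance(op, RateTable):
        op = build_operator(op)
    if not op.rates.is_irreducible():
        raise ValueError("spectrum requires an irreducible chain (positive interior rates)")
    lam = dense_eigvals(op.matrix)
    lam = lam[np.argsort(-lam.real, kind="stable")]
    scale = max(float(np.abs(lam).max()), 1.0)
    if abs(lam[0]) > NORMALISATION_TOL * scale:
        raise ArithmeticError(
            f"largest eigenvalue {lam[0]!r} is not numerically zero"
        )
    lam[0] = 0.0
    diffs = np.abs(lam[:, None] - lam[None, :])
    np.fill_diagonal(diffs, np.inf)
    degenerate = bool(diffs.min() < degeneracy_tol * scale)
    return Spectrum(eigenvalues=lam, degenerate=degenerate, degeneracy_tol=degeneracy_tol)


def _scaled_minor_recursions(B: np.ndarray, D: np.ndarray, y: complex):
    """Leading (theta) and trailing (phi) principal minors of (y I - A).

    Values are returned as unit-magnitude complex numbers with separate log
    magnitudes, since the determinants overflow double precision for moderate
    N.  ``theta[k]`` covers states 0..k, ``phi[k]`` covers states k..N.
    """
    K = B.shape[0]
    diag = y + B + D
    theta = np.empty(K, dtype=complex)
    ltheta = np.empty(K)
    v2, e2 = 1.0 + 0j, 0.0
    v1, e1 = 1.0 + 0j, 0.0
    for k in range(K):
        if k == 0:
            v = diag[k] * v1
            e = e1
        else:
            v = diag[k] * v1 - B[k - 1] * D[k] * v2 * np.exp(e2 - e1)
            e = e1
        mag = abs(v)
        if mag > 0.0:
            e += np.log(mag)
            v /= mag
        theta[k], ltheta[k] = v, e
        v2, e2, v1, e1 = v1, e1, v, e
    phi = np.empty(K, dtype=complex)
    lphi = np.empty(K)
    v2, e2 = 1.0 + 0j, 0.0
    v1, e1 = 1.0 + 0j, 0.0
    for k in range(K - 1, -1, -1):
        if k == K - 1:
            v = diag[k] * v1
            e = e1
        else:
            v = diag[k] * v1 - B[k] * D[k + 1] * v2 * np.exp(e2 - e1)
            e = e1
        mag = abs(v)
        if mag > 0.0:
            e += np.log(mag)
            v /= mag
        phi[k], lphi[k] = v, e
        v2, e2, v1, e1 = v1, e1, v, e
    return theta, ltheta, phi, lphi


class TransientSolution:
    """Time-dependent solution P(n, t | n0, 0) of the master equation.

    Prefers the closed-form residue evaluation (one set of eigenvalues, no
    eigenvectors); automatically falls back to ``expm(A t)`` when the
    spectrum is numerically degenerate or a postcheck fails.  The instance is
    reusable across arbitrarily many times ``t``, which is what makes
    likelihood evaluation cheap.
    """

    def __init__(self, rates: RateTable, n0: int,
                 degeneracy_tol: float = DEGENERACY_TOL) -> None:
        if not 0 <= n0 <= rates.N:
            raise ValueError(f"initial state n0 = {n0} outside [0, {rates.N}]")
        self.rates = rates
        self.n0 = int(n0)
        self.operator = build_operator(rates)
        self.spectrum = spectrum(self.operator, degeneracy_tol)
        self.used_fallback = False
        self._coeff = None
        if self.spectrum.degenerate:
            logger.info(
                "near-degenerate spectrum (min gap %.3e): using matrix-exponential evaluation",
                self.spectrum.min_gap(),
            )
            self.used_fallback = True
        else:
            self._coeff = self._residue_coefficients()

    # -- closed-form path ---------------------------------------------------
    def _residue_coefficients(self) -> np.ndarray | None:
        """Complex matrix C[n, i] with P(n, t) = sum_i C[n, i] exp(lambda_i t)."""
        B, D = self.rates.birth, self.rates.death
        K = self.rates.n_states
        n0 = self.n0
        lam = self.spectrum.eigenvalues
        # boundary rates B[N] = D[0] = 0 never enter a prefactor product,
        # so they are replaced by 1 before taking logs
        logB = np.log(np.where(B > 0, B, 1.0))
        logD = np.log(np.where(D > 0, D, 1.0))
        cumB = np.concatenate([[0.0], np.cumsum(logB)])
        cumD = np.concatenate([[0.0], np.cumsum(logD)])
        n = np.arange(K)
        lpre = np.where(
            n >= n0,
            cumB[n] - cumB[n0],          # B[n0] ... B[n-1]
            cumD[n0 + 1] - cumD[n + 1],  # D[n+1] ... D[n0]
        )
        C = np.zeros((K, K), dtype=complex)
        for i in range(K):
            y = lam[i]
            diff = (y - np.delete(lam, i)).astype(complex)
            logden = complex(np.sum(np.log(diff)))
            theta, ltheta, phi, lphi = _scaled_minor_recursions(B, D, y)
            lo = np.minimum(n, n0)
            hi = np.maximum(n, n0)
            lt = np.where(lo >= 1, ltheta[np.maximum(lo - 1, 0)], 0.0)
            vt = np.where(lo >= 1, theta[np.maximum(lo - 1, 0)], 1.0 + 0j)
            lp = np.where(hi + 1 <= K - 1, lphi[np.minimum(hi + 1, K - 1)], 0.0)
            vp = np.where(hi + 1 <= K - 1, phi[np.minimum(hi + 1, K - 1)], 1.0 + 0j)
            logmag = lpre + lt + lp - logden.real
            if np.any(logmag > 700.0):
                return None  # residue amplitudes overflow: ill-conditioned
            C[:, i] = vt * vp * np.exp(logmag - 1j * logden.imag)
        return C

    def _evaluate_residues(self, ts: np.ndarray) -> np.ndarray | None:
        lam = self.spectrum.eigenvalues
        with np.errstate(over="ignore", invalid="ignore"):
            E = np.exp(np.outer(lam, ts))
            P = (self._coeff @ E).T  # (n_times, n_states), complex
        if not np.all(np.isfinite(P)):
            return None
        if np.abs(P.imag).max() > IMAG_TOL:
            return None
        out = P.real
        if np.abs(out.sum(axis=1) - 1.0).max() > NORMALISATION_TOL:
            return None
        if out.min() < -CLIP_TOL:
            return None
        return out

    # -- fallback path ------------------------------------------------------
    def _evaluate_expm(self, ts: np.ndarray) -> np.ndarray:
        A = self.operator.matrix
        delta = np.zeros(A.shape[0])
        delta[self.n0] = 1.0
        out = np.empty((ts.shape[0], A.shape[0]))
        for k, t in enumerate(ts):
            row = expm(A * float(t)) @ delta
            # scaling-and-squaring loses ~eps * t * ||A|| of probability mass
            # at extreme horizons; renormalise within an engineering tolerance
            total = row.sum()
            if abs(total - 1.0) > 1e-6:
                raise ArithmeticError(
                    f"matrix-exponential propagation lost probability mass "
                    f"(sum = {total!r} at t = {t!r})"
                )
            out[k] = row / total
        return out

    # -- public API ---------------------------------------------------------
    def at_times(self, ts: Sequence[float]) -> list[DistributionOnStates]:
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("times must be >= 0")
        rows = None
        if self._coeff is not None and not self.used_fallback:
            rows = self._evaluate_residues(ts)
            if rows is None:
                logger.info(
                    "residue evaluation failed a consistency check; "
                    "falling back to matrix-exponential evaluation"
                )
        if rows is None:
            self.used_fallback = True
            rows = self._evaluate_expm(ts)
        return [DistributionOnStates(row) for row in rows]

    def at(self, t: float) -> DistributionOnStates:
        return self.at_times([t])[0]

    def probabilities_at_times(self, ts: Sequence[float]) -> np.ndarray:
        """(n_times, N+1) array of marginals; same engine as :meth:`at_times`."""
        return np.array([d.probs for d in self.at_times(ts)])


def transient_solution(rates: RateTable, n0: int,
                       degeneracy_tol: float = DEGENERACY_TOL) -> TransientSolution:
    """Prepare a reusable time-dependent solution from a point initial state."""
    return TransientSolution(rates, n0, degeneracy_tol)


def transient_distribution(rates: RateTable, n0: int, t: float,
                           degeneracy_tol: float = DEGENERACY_TOL) -> DistributionOnStates:
    """P(., t | n0, 0) at a single time (convenience wrapper)."""
    return TransientSolution(rates, n0, degeneracy_tol).at(t)


def transient_from_mixture(rates: RateTable, Q: DistributionOnStates | np.ndarray,
                           t: float) -> DistributionOnStates:
    """Time evolution from a distributed initial condition.

    By linearity of the master equation this is the Q-weighted mixture of the
    point-initial-condition solutions.
    """
    if not isinstance(Q, DistributionOnStates):
        Q = DistributionOnStates(np.asarray(Q, dtype=float))
    if Q.N != rates.N:
        raise ValueError("initial distribution size does not match the rate table")
    out = np.zeros(rates.n_states)
    for n0, w in enumerate(Q.probs):
        if w == 0.0:
            continue
        out += w * TransientSolution(rates, n0).at(t).probs
    return DistributionOnStates(out)


def steady_state(rates: RateTable) -> DistributionOnStates:
    """Stationary distribution from the Kirchhoff product formula.

    ``P_s(n)`` is proportional to the product of all birth rates below ``n``
    times all death rates above ``n``; the products are accumulated in log
    space and normalised with log-sum-exp.  Independent of any initial
    condition, even in deeply metastable regimes.
    """
    if not rates.is_irreducible():
        raise ValueError("steady state requires an irreducible chain")
    B, D = rates.birth, rates.death
    K = rates.n_states
    logw = np.empty(K)
    cumB = np.concatenate([[0.0], np.cumsum(np.log(B[:-1]))])
    cumD = np.concatenate([[0.0], np.cumsum(np.log(D[1:][::-1]))])[::-1]
    #  logw[n] = sum_{k<n} log B[k] + sum_{k>n} log D[k]
    logw = cumB + cumD
    return DistributionOnStates(np.exp(logw - logsumexp(logw)))
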