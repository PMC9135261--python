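# Methods

This note records the mathematical model behind `lockin`, the numerical
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Model and assumptions

A population of `N` agents holds binary opinions `S_i = ±1`.  The mean-field
assumption — every agent responds to the population average `m(n) =
(2n − N)/N` rather than to named neighbours — collapses the `2^N` spin
configurations onto the integer lattice `n = 0…N`, where `n` counts
right-deciders.  The shared influence is `I(n) = F + J m(n)`: `F` (the
zeitgeist) is an exogenous bias with the units of a utility, `J ≥ 0` an
intensive conformity strength (the raw coupling is rescaled by `1/N`).
Agents are kinetically heterogeneous (they decide at different times) but
share one rationality `β` and one attempt rate `γ`.

A flip changes the flipping agent's utility, and — through `m` — everyone
else's.  The *gain* blends the two with the altruism weight `α ∈ [0, 1]`:

```
G = −2 S (F + J m(n)(1 + α)) + 2(1 + α) J / N .
```

The last term is the agent's interaction with its own contribution to `m`;
it is `O(1/N)` and can be disabled (`include_self_interaction=False`), but
it is kept by default because with it the discrete gradient identity
`H(n+1) − H(n) = G(left→right, n)` holds *exactly* for the Hamiltonian
`H(n) = N m (F + ½(α+1) J m)`, which in turn makes the stationary law
exactly Boltzmann, `P_s(n) ∝ C(N,n) e^{βH(n)}`.  All quantitative results
in the test-suite are computed with the term on.

Rate families:

* **logit (default)**: `W = γ/(1 + e^{−βG})`.  Satisfies detailed balance
  with the Boltzmann weight for every `α`; `β → 0` gives opinion noise at
  rate `γ/2`, `β → ∞` deterministic utility-following.
* **Arrhenius**: `W = γ e^{β U_post}`, with `U_post` the flipping agent's
  own post-flip utility.  Detailed balance holds in the selfish case
  (`α = 0`, verified in the tests); the gain/Hamiltonian identity of the
  logit rule does not apply, so the Boltzmann identity test is restricted
  to the logit family.
* **Kirman**: `birth[n] = (N−n)ε + μ(N−n)n/(N−1)` and mirrored death rates
  — spontaneous switching plus pairwise recruitment.  The proportionality
  constant is taken as 1; any overall time scale is absorbed into `ε, μ`.

Aggregate propensities follow mass action: `birth[n] = (N−n) r(n)`,
`death[n] = n l(n)`.

## Exact transient solution

`dP/dt = A P` with `A` tridiagonal.  The solution from a point initial
condition is evaluated as a sum over eigenvalues of residues of the
resolvent `(yI − A)^{-1}`.  For a tridiagonal matrix the resolvent entry
`(n, n₀)` factorises into (i) the product of the chain's rates between
`n₀` and `n`, (ii) the determinant of the leading principal minor covering
states below `min(n, n₀)`, (iii) the determinant of the trailing minor
above `max(n, n₀)`, and (iv) `1/∏_{j≠i}(λ_i − λ_j)`.  The minors obey
three-term recursions; only eigenvalues — no eigenvectors — are needed,
which is what makes re-evaluation at many times cheap (`O(N²)` setup, one
complex matrix product per batch of times).

Numerical choices:

* **Log-magnitude arithmetic.**  The minors and rate products overflow
  double precision already for `N ≈ 40`, so each recursion carries a
  unit-magnitude complex value plus a separate log magnitude, and each
  residue term is assembled as `sign × exp(log magnitude)` in complex log
  space.  Against a matrix-exponential oracle the evaluation is accurate to
  ~1e-14 sup-norm on random chains.
* **Pseudospectrum.**  Finite-precision eigenvalues of these
  non-symmetric operators may form complex-conjugate pairs although the
  true spectrum is real.  Pairs are kept, summed in complex arithmetic,
  and the real part is returned; an imaginary residue above 1e-8 rejects
  the evaluation.
* **Degeneracy fallback.**  In deeply bistable regimes (e.g. `F = 0,
  J = 10, N = 100`) eigenvalue pairs are *genuinely* closer than
  `eps·‖A‖`; the residue denominators are then meaningless in double
  precision.  A relative-gap precheck (tolerance 1e-8, configurable) plus
  postchecks (normalisation within 1e-8, entries ≥ −1e-12, finite,
  imaginary residue < 1e-8) route such cases to a direct `expm(A t)`
  evaluation.  No confluent-residue formula is attempted.  The
  matrix-exponential path renormalises its output and accepts a mass drift
  up to 1e-6, which scaling-and-squaring incurs at extreme horizons
  (`t‖A‖ ~ 1e12`); beyond that it raises.
* **Clipping.**  Entries in `(−1e-12, 0)` are clipped to zero and the
  vector renormalised; anything more negative is an error, never silently
  repaired.
* Mixture initial conditions use linearity: the point-condition solutions
  are combined with the weights of the initial distribution.

The stationary law is computed independently of the transient machinery
from the Kirchhoff product formula, accumulated in log space and
normalised with log-sum-exp — exact for any irreducible one-step chain and
robust to stationary probabilities spanning hundreds of orders of
magnitude.

## Metastability and first passage

For `β > β_c = 1/J(1+α)` (and `|F| < J(α+1)`) the stationary law is
bimodal.  The unstable point `n_u` is defined as the interior argmin of
`P_s` strictly between the two largest local maxima, ties broken toward
the midpoint.  Note that for an asymmetric deep well (`F = 0.1, J = 5,
N = 50`) the discrete argmin sits at `n = 24`, one state left of `N/2`;
the neighbouring stationary probabilities differ only in the second digit,
so "the barrier is at `N/2`" remains a fair informal description, but the
package reports the true argmin.

Mean first-passage times `τ_n` to `n_u` solve the backward linear system
`B[n]τ_{n+1} + D[n]τ_{n−1} − (B[n]+D[n])τ_n = −1`, `τ_{n_u} = 0`,
reflecting at the outer boundaries.  That tridiagonal solve is the
*normative* definition in this package; the closed-form nested
sum/product expressions (evaluated in log space, the upper branch by
mirroring the chain) are an equivalent fast path and are asserted equal to
1e-8 relative in the tests.  For very large `β` the closed forms may
overflow to `inf`, which is reported as such rather than clamped.

The splitting probability `φ_R` (start at `n_u`, reach the right mode
before the left) solves the discrete harmonic problem with absorbing
boundaries *at the two modes* `n_minus`, `n_plus` — not at `0` and `N` —
because "coalescing" on a technology means reaching its basin centre; the
product-ratio summation is done in log space and is cross-checked against
an absorbing-boundary linear solve and against direct SSA absorption
statistics.

The two-state reduction hops between the basins with rates
`k_LR = φ_R/τ_lr` and `k_RL = (1−φ_R)/τ_rl`, where the escape times are
conditional stationary averages of `τ_n` over each basin.  Its relaxation
rate `λ₂ = k_LR + k_RL` approximates the spectral `|Re λ₂|` from below
(it ignores the `O(1/|λ₃|)` relaxation *into* the modes); in the shallow
bimodal regime the two agree to 0.7%.  In deep-well regimes the spectral
`λ₂` is below `eps·‖A‖` and cannot be resolved by any dense eigensolver
in double precision — there the first-passage value is the *only*
meaningful estimate, which is why the 5% agreement test runs on the
shallow regime alone.

The metastable closed form `P(n,t) ≈ P_s(n) + e^{−λ₂t} Φ₂(n)` uses
`Φ₂ = (π_L(0) − π_L^s)(ρ_l − ρ_r)`, which sums to zero by construction.
`π_L(0)` defaults to `1 − φ_R` for a start exactly at `n_u`; for any other
start the full solution is propagated to `t = 10/|Re λ₃|` and its
left-basin mass is read off.  If the approximation would produce negative
probabilities the time is below its validity threshold and an error
directs the caller to the full solution.

## Stochastic simulation

Two-channel Gillespie: exponential waiting time with total propensity
`B[n] + D[n]`, channel chosen proportionally.  Grid sampling is
left-continuous (state at the most recent event ≤ the query time), the
natural reading of a càdlàg counting process at observation times.
Ensembles derive child seed `k` as `SeedSequence(entropy=master,
spawn_key=(k,))` — counter-based, so results are reproducible and
independent of evaluation order; the ensemble of the first `k`
trajectories is a prefix of any larger ensemble with the same master seed.
The implementation is a plain-Python event loop; at the study conditions
used here (200 trajectories on `[0, 2000]` at `N = 50`) it costs ~3 s,
so no JIT machinery is warranted.

A note on validation tolerances: the expected total-variation distance
between a 2500-sample empirical law and its generating distribution over
~100 states is itself ≈ 0.05 (multinomial noise, `∝ 1/√M`).  A fixed TV
threshold at 0.05 therefore sits *at the noise floor* of that sample
size; the suite instead bounds TV by three times the multinomial noise
expectation computed from the analytic law, and separately checks means
within three standard errors.  Unbiasedness was verified by the `1/√M`
scaling of TV up to 25 000 trajectories.

## Likelihood and calibration

The likelihood of a trajectory sampled at `t_1 < … < t_L` is the product
of one-time marginals `P_θ(n(t_i), t_i | n₀, 0)` — a *composite*
likelihood conditioning every observation on the known initial state, not
a Markov transition-product likelihood.  Observations at `t = 0` equal to
`n₀` contribute probability 1; an observation at `t = 0` different from
`n₀` is rejected.  Probabilities are floored at 1e-300 before the log, so
Monte-Carlo-rare observations penalise heavily but never produce `−inf`.

Because `β` multiplies `F` and `β(1+α)` multiplies `J` in the gain, only
`βF` and `β(1+α)J` are identifiable; the likelihood is *exactly* constant
along that scaling direction (asserted to 1e-10 in the tests).
Calibration therefore fixes `β = 1`, `α = 0` and searches
`θ = (F, ln J, ln γ)` in the box `F ∈ [−2, 2]`, `J ∈ [e^{−2}, e^{2}]`,
`γ ∈ [e^{−1}, e^{1}]` with seeded differential evolution
(`scipy.optimize.differential_evolution`, Sobol initialisation, deferred
updating, final local polish).  The default budget — 51 individuals, up
to 150 generations, convergence tolerance 0.01 — is a desk-scale choice;
pooled observation counts make one evaluation independent of the number
of trajectories (~20 ms at `N = 50` with 100 observation times), and one
calibration takes ~20 s.  The optimiser returns a good local minimum, not
a certified global one.

Error metrics: `E_tot = Σ_i |(θ_true,i − θ*_i)/θ_true,i|` over
`{F, J, γ}`, and `f`, the relative error of `F/J` — the quantity that
decides whether exogenous and endogenous influences were disentangled.

## Synthetic data

The generator produces SSA trajectories of the model itself, sampled on
uniform grids — by construction the data match the model family, the
initial state is known exactly, all realisations share one parameter set,
and observations are noiseless integer counts.  Real adoption data would
violate every one of these: measurement noise and bias, drifting `F(t)`,
heterogeneous coupling, unknown `n₀` and unknown `N`.  Passing calibration
tests therefore demonstrate the *estimator* works when the model is true;
they say nothing about model misspecification.  Fixture presets pin the
reference regimes: symmetric deep well (`F=0, J=10, N=100`, 2500
trajectories), asymmetric deep well (`F=0.1, J=5, N=50`), shallow bimodal
(`F=0.025, J=1.5, N=50`) and the calibration ensemble (200 trajectories,
100 points on `[0, 2000]` — the grid for the data-requirement experiments,
chosen to span ~1.5 relaxation times so a realistic fraction of
trajectories explores both modes).  The deep-well ensemble grid covers
`[0, 2]`, the window in which that regime's transient is probed.

## Known limitations

* Time-dependent `F(t)` is out of scope (the propensities would become
  explicitly time-dependent); the model layer is the extension hook.
* Heterogeneous fields `f_i`, network couplings `J_ij` and
  neighbourhoods are not representable — the state space is `n` alone.
* The residue path requires simple, well-separated eigenvalues; deep
  double wells always use the matrix-exponential fallback, which costs
  `O(N³)` per time point.
* Higher first-passage moments, diffusion approximations and
  likelihood-free (ABC) calibration are not implemented.
* Calibration assumes a shared, constant parameter set across
  realisations and a known `N`.
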