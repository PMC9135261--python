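# lockin

**Birth–death master-equation toolkit for collective binary decisions:
exact transient solutions, metastability analysis and likelihood
calibration.**

`lockin` studies populations of `N` interacting agents that each hold one of
two opinions — two competing technologies, two candidates, two food sources.
It is aimed at researchers in socio- and econophysics, opinion dynamics and
stochastic modelling who need *time-dependent* (not just equilibrium)
answers: how fast does a population coalesce on one choice, how long does a
technology lock-in last, and can the driving parameters be inferred from
observed adoption data?

## The model

In the mean-field binary decision model every agent `i` carries a spin
`S_i = ±1` and feels the same influence

```
I(n) = F + J m(n),        m(n) = (2n − N)/N,
```

where `n` counts right-deciding agents, `F` is an exogenous field (the
*zeitgeist*, e.g. a cost difference), and `J ≥ 0` is the conformity
strength.  An agent flips with the logit (Glauber) rate
`W = γ / (1 + e^{−β G})`, where the gain `G` interpolates between selfish
(`α = 0`) and altruistic (`α = 1`) utility changes and `β` is the agents'
rationality (an inverse temperature).  Aggregated over the population this
is a one-step birth–death process on `n = 0…N` with master equation
`dP/dt = A P` for a tridiagonal generator `A`.  The package provides:

* **model** — parameters, decision-rule families (logit / Arrhenius /
  Kirman's ant model), gains, the Hamiltonian `H(n) = N m (F + ½(α+1)J m)`
  and the propensity table;
* **spectral** — the generator, its (pseudo)spectrum, the exact closed-form
  transient solution `P(n, t | n₀)` via resolvent residues (with an
  automatic matrix-exponential fallback for numerically degenerate
  spectra), and the Kirchhoff steady state;
* **simulate** — exact Gillespie (SSA) trajectories and reproducible
  ensembles;
* **passage** — unstable point, exact mean first-passage times, splitting
  probability `φ_R`, mode-escape times, the two-state reduction and the
  relaxation-rate approximation `λ₂ = φ_R/τ_lr + (1−φ_R)/τ_rl`;
* **inference** — composite likelihood over trajectory data, seeded
  differential-evolution calibration of `θ = {F, J, γ}` and the
  data-requirement experiments;
* **io_cli** — CSV/YAML readers and writers, fixture presets and the
  `lockin` command-line tool.

## Worked example

The shallow bimodal regime (`F = 0.025`, `J = 1.5`, `α = 0`, `β = 1`,
`γ = 1`, `N = 50`) is bistable — `β` exceeds the critical rationality
`β_c = 1/J(1+α) = 2/3` — and its relaxation to the stationary law is slow:

```python
import lockin

params = lockin.ModelParams(F=0.025, J=1.5, alpha=0.0, beta=1.0, gamma=1.0, N=50)
rates = lockin.propensities(params)

spec = lockin.spectrum(lockin.build_operator(rates))
print(f"spectral relaxation time 1/|Re λ2| = {spec.relaxation_time:.1f}")

res = lockin.passage_analysis(rates)
print(f"unstable point n_u = {res.structure.n_u}, phi_R = {res.phi_R:.4f}")
print(f"tau_lr = {res.tau_lr:.1f}, tau_rl = {res.tau_rl:.1f}")
print(f"first-passage relaxation time 1/λ2 = {res.relaxation_time:.1f}")
```

prints

```
spectral relaxation time 1/|Re λ2| = 1288.8
unstable point n_u = 24, phi_R = 0.5342
tau_lr = 767.4, tau_rl = 5464.6
first-passage relaxation time 1/λ2 = 1279.8
```

The spectral value is the exact time scale on which `P(n, t)` approaches
the steady state.  The first-passage pipeline — escape times out of each
mode weighted by the conditional stationary law, combined with the
splitting probability at the barrier — reproduces it to better than 1%
while using no eigenvalues at all, and slightly underestimates it because
it ignores the initial relaxation *into* the metastable modes.  Since
`F > 0` the optimal (right) mode is roughly seven times harder to escape
than the sub-optimal one: a population locked into the wrong technology
stays there for hundreds of time units.

The same regime from the shell:

```sh
lockin spectrum --config examples/shallow_bimodal.yaml
lockin passage  --config examples/shallow_bimodal.yaml
lockin fixtures --preset calibration --seed 1 --out data/
```

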