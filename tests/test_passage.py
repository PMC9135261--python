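"""First-passage times, splitting probability and the two-state reduction."""

import numpy as np
import numpy.testing as npt
import pytest

from lockin import (
    DistributionOnStates,
    ModelParams,
    NotBistableError,
    TransientSolution,
    build_operator,
    find_unstable_point,
    initial_left_mass,
    metastable_distribution,
    mfpt_asymptotic_exponent,
    mfpt_exact,
    mfpt_linear_solve,
    mode_escape_times,
    passage_analysis,
    propensities,
    relaxation_rate,
    spectrum,
    splitting_probability,
    splitting_probability_linear_solve,
    ssa_trajectory,
    steady_state,
    two_state_reduction,
)


class TestUnstablePoint:
    def test_symmetric_barrier_at_midpoint(self):
        p = ModelParams(F=0.0, J=1.5, beta=1.0, N=50)  # beta > beta_c = 2/3
        struct = find_unstable_point(steady_state(propensities(p)))
        assert struct.n_u == 25
        assert struct.n_minus < 25 < struct.n_plus

    def test_asymmetric_deep_well_barrier_near_midpoint(self, asymmetric_deep_rates):
        # the interior minimum sits within one state of N/2
        struct = find_unstable_point(steady_state(asymmetric_deep_rates))
        assert abs(struct.n_u - 25) <= 1
        assert (struct.n_minus, struct.n_plus) == (0, 50)

    def test_subcritical_distribution_is_not_bistable(self):
        p = ModelParams(F=0.0, J=1.5, beta=0.5, N=50)  # beta < beta_c
        with pytest.raises(NotBistableError):
            find_unstable_point(steady_state(propensities(p)))


class TestMeanFirstPassage:
    def test_zero_at_target_and_first_step_identity(self, shallow_bimodal_rates):
        struct = find_unstable_point(steady_state(shallow_bimodal_rates))
        tau = mfpt_exact(shallow_bimodal_rates, struct.n_u)
        assert tau[struct.n_u] == 0.0
        # from the empty state the only move is up, at mean time 1/birth[0]
        assert tau[1] - tau[0] == pytest.approx(-1.0 / shallow_bimodal_rates.birth[0],
                                                rel=1e-10)

    def test_closed_form_matches_linear_system(self, shallow_bimodal_rates):
        struct = find_unstable_point(steady_state(shallow_bimodal_rates))
        tau = mfpt_exact(shallow_bimodal_rates, struct.n_u)
        tau_ref = mfpt_linear_solve(shallow_bimodal_rates, struct.n_u)
        mask = np.arange(tau.size) != struct.n_u
        npt.assert_allclose(tau[mask], tau_ref[mask], rtol=1e-8)

    def test_closed_form_matches_linear_system_random_chains(self):
        from conftest import random_rate_table

        rng = np.random.default_rng(14)
        for _ in range(10):
            rates = random_rate_table(rng)
            n_u = int(rng.integers(1, rates.N))
            tau = mfpt_exact(rates, n_u)
            tau_ref = mfpt_linear_solve(rates, n_u)
            mask = np.arange(tau.size) != n_u
            npt.assert_allclose(tau[mask], tau_ref[mask], rtol=1e-8)

    def test_boundary_target_rejected(self, shallow_bimodal_rates):
        with pytest.raises(ValueError):
            mfpt_exact(shallow_bimodal_rates, 0)


class TestSplittingProbability:
    def test_symmetric_chain_splits_evenly(self):
        p = ModelParams(F=0.0, J=1.5, beta=1.0, N=50)
        rates = propensities(p)
        struct = find_unstable_point(steady_state(rates))
        assert splitting_probability(rates, struct) == pytest.approx(0.5, abs=1e-12)

    def test_matches_absorbing_linear_solve(self, shallow_bimodal_rates):
        struct = find_unstable_point(steady_state(shallow_bimodal_rates))
        phi = splitting_probability(shallow_bimodal_rates, struct)
        phi_ref = splitting_probability_linear_solve(shallow_bimodal_rates, struct)
        assert phi == pytest.approx(phi_ref, abs=1e-10)

    def test_matches_ssa_first_absorption(self, shallow_bimodal_rates):
        struct = find_unstable_point(steady_state(shallow_bimodal_rates))
        phi = splitting_probability(shallow_bimodal_rates, struct)
        rng_root = np.random.SeedSequence(15)
        hits_right = 0
        runs = 2000
        B, D = shallow_bimodal_rates.birth, shallow_bimodal_rates.death
        for k in range(runs):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=rng_root.entropy, spawn_key=(k,)))
            n = struct.n_u
            while struct.n_minus < n < struct.n_plus:
                tot = B[n] + D[n]
                n = n + 1 if rng.random() * tot < B[n] else n - 1
            hits_right += n == struct.n_plus
        p_hat = hits_right / runs
        se = np.sqrt(phi * (1 - phi) / runs)
        assert abs(p_hat - phi) < 3 * se

    def test_monotone_in_field(self):
        phis = []
        for F in (0.0, 0.025, 0.05, 0.1):
            p = ModelParams(F=F, J=1.5, beta=1.0, N=50)
            rates = propensities(p)
            struct = find_unstable_point(steady_state(rates))
            phis.append(splitting_probability(rates, struct))
        assert np.all(np.diff(phis) > 0)


class TestModeEscapeAndRelaxation:
    def test_symmetric_escape_times_equal(self):
        p = ModelParams(F=0.0, J=1.5, beta=1.0, N=50)
        rates = propensities(p)
        res = passage_analysis(rates)
        assert res.tau_lr == pytest.approx(res.tau_rl, rel=1e-9)

    def test_optimal_mode_is_harder_to_leave(self, shallow_bimodal_rates):
        res = passage_analysis(shallow_bimodal_rates)
        assert res.tau_rl > res.tau_lr  # F > 0 favours the right mode

    def test_escape_times_are_convex_combinations(self, shallow_bimodal_rates):
        Ps = steady_state(shallow_bimodal_rates)
        struct = find_unstable_point(Ps)
        tau = mfpt_exact(shallow_bimodal_rates, struct.n_u)
        tau_lr, tau_rl = mode_escape_times(shallow_bimodal_rates, Ps, struct, tau)
        assert tau[:struct.n_u].min() <= tau_lr <= tau[:struct.n_u].max()
        assert tau[struct.n_u + 1:].min() <= tau_rl <= tau[struct.n_u + 1:].max()

    def test_symmetric_two_state_rate(self):
        assert relaxation_rate(0.5, 10.0, 10.0) == pytest.approx(0.1)

    def test_approximation_close_to_and_below_spectral_rate(self, shallow_bimodal_rates):
        # valid whenever the spectral gap is wide: |lambda2/lambda3| << 1
        spec = spectrum(build_operator(shallow_bimodal_rates))
        assert abs(spec.lambda2.real / spec.lambda3.real) < 0.05
        res = passage_analysis(shallow_bimodal_rates)
        spectral_time = spec.relaxation_time
        assert res.relaxation_time <= spectral_time
        assert res.relaxation_time == pytest.approx(spectral_time, rel=0.05)


class TestTwoStateReduction:
    def test_occupancies_sum_to_one(self):
        two = two_state_reduction(0.4, 5.0, 20.0, piL0=0.9)
        t = np.linspace(0, 100, 7)
        npt.assert_allclose(two.pi_L(t) + two.pi_R(t), 1.0, atol=1e-12)

    def test_stationary_initial_condition_is_constant(self):
        two = two_state_reduction(0.4, 5.0, 20.0, piL0=0.0)
        two = two_state_reduction(0.4, 5.0, 20.0, piL0=two.pi_L_s)
        npt.assert_allclose(two.pi_L([0.0, 3.0, 1e4]), two.pi_L_s, rtol=1e-12)

    def test_stationary_ratio_matches_steady_state_mass_split(self, asymmetric_deep_rates):
        Ps = steady_state(asymmetric_deep_rates)
        res = passage_analysis(asymmetric_deep_rates)
        u = res.structure.n_u
        mass_ratio = Ps.probs[:u].sum() / Ps.probs[u + 1:].sum()
        assert res.pi_L_s / res.pi_R_s == pytest.approx(mass_ratio, rel=0.1)


class TestMetastableDistribution:
    def test_slow_mode_sums_to_zero_and_decays_to_steady_state(self, shallow_bimodal_rates):
        Ps = steady_state(shallow_bimodal_rates)
        res = passage_analysis(shallow_bimodal_rates)
        P = metastable_distribution(Ps, res.structure, res.lambda2_approx, 0.7, 1.0)
        phi2 = P.probs - Ps.probs  # e^{-lambda2} ~ 1 here, so this is ~Phi_2
        assert abs(phi2.sum()) < 1e-10
        P_inf = metastable_distribution(Ps, res.structure, res.lambda2_approx, 0.7, 1e12)
        npt.assert_allclose(P_inf.probs, Ps.probs, atol=1e-12)

    def test_matches_full_solution_in_metastable_regime(self, asymmetric_deep_rates):
        Ps = steady_state(asymmetric_deep_rates)
        res = passage_analysis(asymmetric_deep_rates)
        piL0 = initial_left_mass(asymmetric_deep_rates, res.structure, 25,
                                 phi_R=res.phi_R)
        approx = metastable_distribution(Ps, res.structure, res.lambda2_approx,
                                         piL0, 10.0)
        full = TransientSolution(asymmetric_deep_rates, 25).at(10.0)
        assert np.abs(approx.probs - full.probs).max() < 0.02


class TestAsymptoticExponents:
    def test_symmetric_field_free_exponents(self):
        p = ModelParams(F=0.0, J=1.5, N=50)
        assert mfpt_asymptotic_exponent(p) == (50.0, 50.0)

    def test_weak_field_split(self):
        p = ModelParams(F=0.025, J=1.5, N=50)
        lr, rl = mfpt_asymptotic_exponent(p)
        assert lr == pytest.approx(49.1666, rel=1e-4)
        assert rl == pytest.approx(50.8333, rel=1e-4)

    def test_escape_time_asymmetry_grows_linearly_in_population(self):
        # log tau_rl - log tau_lr vs N: monotone and close to linear
        Ns = np.array([20, 30, 40, 50, 60])
        gaps = []
        for N in Ns:
            p = ModelParams(F=0.025, J=1.5, beta=4.0, N=int(N))
            res = passage_analysis(propensities(p))
            gaps.append(np.log(res.tau_rl) - np.log(res.tau_lr))
        gaps = np.array(gaps)
        assert np.all(np.diff(gaps) > 0)
        slope, intercept = np.polyfit(Ns, gaps, 1)
        fit = slope * Ns + intercept
        resid = gaps - fit
        assert np.abs(resid).max() < 0.05 * gaps.max()


class TestAltruismSweep:
    def test_relaxation_time_grows_near_exponentially_with_altruism(
            self, shallow_bimodal_params):
        alphas = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        times = []
        for a in alphas:
            rates = propensities(shallow_bimodal_params.with_(alpha=float(a)))
            times.append(passage_analysis(rates).relaxation_time)
        times = np.array(times)
        assert np.all(np.diff(times) > 0)
        logt = np.log(times)
        slope, intercept = np.polyfit(alphas, logt, 1)
        r2 = 1 - np.sum((logt - (slope * alphas + intercept)) ** 2) / \
            np.sum((logt - logt.mean()) ** 2)
        assert r2 > 0.98
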