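import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wolkdr.fitness_cost import (
    CostPosterior,
    ExtinctionError,
    GenotypeState,
    IntrogressionEvent,
    MonteCarloConfig,
    SelectionParams,
    gamete_frequency,
    introgress_males,
    next_generation,
    run_rejection,
    sample_initial_state,
    simulate_trajectory,
    summarize_posterior,
)

# ---------------------------------------------------------------------------
# Independent oracle: the same recursion written a second time, scalar-only,
# as dicts of genotype masses. Used to cross-check simulate_trajectory and the
# vectorized path inside run_rejection.
# ---------------------------------------------------------------------------


def oracle_trajectory(f_RR0, c, d=0.9, n_gen=17, event_gens=(10, 15),
                      male_ratio=0.1, donor=1.0, migrants_selected=True):
    geno = {"RR": f_RR0, "RS": 2 * (0.6 - f_RR0), "SS": 1 - f_RR0 - 2 * (0.6 - f_RR0)}
    fitness = {"RR": 1 - c, "RS": 1 - d * c, "SS": 1.0}
    freqs = [geno["RR"] + geno["RS"] / 2]

    def gamete_p(pool):
        wbar = sum(pool[k] * fitness[k] for k in pool)
        return (pool["RR"] * fitness["RR"] + 0.5 * pool["RS"] * fitness["RS"]) / wbar

    for gen in range(1, n_gen + 1):
        p_f = gamete_p(geno)
        if gen in event_gens:
            if migrants_selected:
                w = male_ratio / (1 + male_ratio)
                male_pool = {
                    "RR": (1 - w) * geno["RR"] + w * donor * donor,
                    "RS": (1 - w) * geno["RS"] + w * 2 * donor * (1 - donor),
                    "SS": (1 - w) * geno["SS"] + w * (1 - donor) ** 2,
                }
                p_m = gamete_p(male_pool)
            else:
                p_m = (p_f + male_ratio * donor) / (1 + male_ratio)
        else:
            p_m = p_f
        geno = {
            "RR": p_f * p_m,
            "RS": p_f * (1 - p_m) + (1 - p_f) * p_m,
            "SS": (1 - p_f) * (1 - p_m),
        }
        freqs.append(geno["RR"] + geno["RS"] / 2)
    return freqs


class TestSampleInitialState:
    def test_midpoint_of_prior(self):
        state = sample_initial_state(0.5, MonteCarloConfig())
        assert state.f_RR == pytest.approx(0.55)
        assert state.f_RS == pytest.approx(0.10)
        assert state.f_SS == pytest.approx(0.35)
        assert state.allele_freq == pytest.approx(0.60, abs=1e-15)

    def test_upper_boundary(self):
        state = sample_initial_state(1.0, MonteCarloConfig())
        assert (state.f_RR, state.f_RS, state.f_SS) == pytest.approx((0.60, 0.0, 0.40))

    def test_lower_boundary(self):
        state = sample_initial_state(0.0, MonteCarloConfig())
        assert (state.f_RR, state.f_RS, state.f_SS) == pytest.approx((0.50, 0.20, 0.30))

    def test_infeasible_prior_guard(self):
        cfg = MonteCarloConfig(f_RR_prior=(0.9, 0.95), initial_allele_freq=0.6)
        with pytest.raises(ValueError, match="incompatible"):
            sample_initial_state(0.5, cfg)


class TestGameteFrequency:
    def test_neutrality_conserves_frequency(self):
        state = GenotypeState(0.2, 0.5, 0.3)
        p = gamete_frequency(state, SelectionParams(c=0.0))
        assert p == pytest.approx(state.allele_freq, abs=1e-15)

    def test_hand_evaluated_closed_form(self):
        state = GenotypeState(0.36, 0.48, 0.16)
        p = gamete_frequency(state, SelectionParams(c=0.34, d=0.9))
        assert p == pytest.approx(0.40416 / 0.73072, abs=1e-12)

    def test_fixed_allele_stays_fixed(self):
        state = GenotypeState(1.0, 0.0, 0.0)
        assert gamete_frequency(state, SelectionParams(c=0.5)) == pytest.approx(1.0)

    def test_extinction_raises(self):
        state = GenotypeState(1.0, 0.0, 0.0)
        with pytest.raises(ExtinctionError):
            gamete_frequency(state, SelectionParams(c=1.0, d=1.0))

    @given(
        p=st.floats(0.01, 0.99),
        c=st.floats(0.0, 0.95),
        d=st.floats(0.0, 1.0),
    )
    @settings(max_examples=1000, deadline=None)
    def test_marginal_fitness_identity_on_hwe_states(self, p, c, d):
        # p * (p*w_RR + q*w_RS) / wbar is the textbook marginal-fitness form
        state = GenotypeState(p * p, 2 * p * (1 - p), (1 - p) ** 2)
        params = SelectionParams(c=c, d=d)
        w_RR, w_RS, w_SS = params.fitnesses
        q = 1 - p
        wbar = p * p * w_RR + 2 * p * q * w_RS + q * q * w_SS
        expected = p * (p * w_RR + q * w_RS) / wbar
        assert gamete_frequency(state, params) == pytest.approx(expected, abs=1e-12)


class TestIntrogressMales:
    def test_arithmetic(self):
        assert introgress_males(0.14, IntrogressionEvent(10)) == pytest.approx(0.24 / 1.1)

    def test_zero_ratio_is_identity(self):
        ev = IntrogressionEvent(10, male_ratio=0.0)
        assert introgress_males(0.37, ev) == pytest.approx(0.37)

    def test_identical_donor_pool_is_identity(self):
        ev = IntrogressionEvent(10, donor_allele_freq=0.42)
        assert introgress_males(0.42, ev) == pytest.approx(0.42)


class TestNextGeneration:
    def test_hwe_from_half(self):
        s = next_generation(0.5, 0.5)
        assert (s.f_RR, s.f_RS, s.f_SS) == pytest.approx((0.25, 0.50, 0.25))

    def test_square_of_gamete_frequency(self):
        p = 0.40416 / 0.73072
        s = next_generation(p, p)
        assert s.f_RR == pytest.approx(p * p, abs=1e-12)
        assert s.f_RR == pytest.approx(0.3059, abs=5e-4)

    def test_opposite_fixed_pools_give_all_heterozygotes(self):
        s = next_generation(0.0, 1.0)
        assert (s.f_RR, s.f_RS, s.f_SS) == (0.0, 1.0, 0.0)


class TestSimulateTrajectory:
    def test_neutral_frequency_invariant(self):
        init = sample_initial_state(0.3, MonteCarloConfig())
        traj = simulate_trajectory(init, SelectionParams(c=0.0), n_generations=17)
        assert len(traj) == 18
        for state in traj:
            assert state.allele_freq == pytest.approx(init.allele_freq, abs=1e-12)

    def test_generation_labels_advance_f1_to_f18(self):
        init = sample_initial_state(0.5, MonteCarloConfig())
        traj = simulate_trajectory(init, SelectionParams(c=0.2), n_generations=17)
        assert [s.generation for s in traj] == list(range(1, 19))

    def test_strict_monotone_decline_under_cost(self):
        init = sample_initial_state(0.5, MonteCarloConfig())
        traj = simulate_trajectory(init, SelectionParams(c=0.3, d=0.9), n_generations=25)
        freqs = [s.allele_freq for s in traj]
        for a, b in zip(freqs, freqs[1:]):
            if 0 < a < 1:
                assert b < a

    @pytest.mark.parametrize("migrants_selected", [True, False])
    def test_matches_independent_oracle(self, migrants_selected):
        events = (IntrogressionEvent(10), IntrogressionEvent(15))
        for f_RR0, c in [(0.55, 0.34), (0.50, 0.10), (0.60, 0.80)]:
            init = GenotypeState(f_RR0, 2 * (0.6 - f_RR0), 1 - f_RR0 - 2 * (0.6 - f_RR0))
            traj = simulate_trajectory(
                init, SelectionParams(c=c, d=0.9), events=events,
                n_generations=17, migrants_selected=migrants_selected,
            )
            expected = oracle_trajectory(f_RR0, c, migrants_selected=migrants_selected)
            for state, want in zip(traj, expected):
                assert state.allele_freq == pytest.approx(want, abs=1e-12)

    def test_swamping_limit(self):
        # introgression every generation with an enormous male ratio fixes R
        events = tuple(IntrogressionEvent(g, male_ratio=1e6) for g in range(1, 18))
        init = sample_initial_state(0.5, MonteCarloConfig())
        traj = simulate_trajectory(init, SelectionParams(c=0.3), events=events,
                                   n_generations=17)
        assert traj[-1].allele_freq == pytest.approx(1.0, abs=1e-3)

    def test_duplicate_events_rejected(self):
        init = sample_initial_state(0.5, MonteCarloConfig())
        with pytest.raises(ValueError, match="multiple introgression"):
            simulate_trajectory(
                init, SelectionParams(c=0.1),
                events=(IntrogressionEvent(10), IntrogressionEvent(10)),
            )

    def test_drift_requires_rng_and_stays_on_simplex(self):
        init = sample_initial_state(0.5, MonteCarloConfig())
        with pytest.raises(ValueError, match="rng"):
            simulate_trajectory(init, SelectionParams(c=0.1), drift_popsize=100)
        rng = np.random.default_rng(3)
        traj = simulate_trajectory(
            init, SelectionParams(c=0.1), n_generations=10,
            drift_popsize=200, rng=rng,
        )
        for s in traj:
            assert abs(s.f_RR + s.f_RS + s.f_SS - 1) < 1e-12


class TestRunRejection:
    def test_degenerate_prior_accepts_everything(self):
        cfg = MonteCarloConfig(
            n_draws=500, cost_prior=(0.0, 0.0), events=(),
            target_freq=0.60, tolerance=0.01, seed=11,
        )
        posterior = run_rejection(cfg)
        assert posterior.n_accepted == 500
        assert posterior.mean_cost == 0.0

    def test_no_acceptances_raises_with_advice(self):
        cfg = MonteCarloConfig(
            n_draws=200, cost_prior=(0.0, 0.0), events=(),
            target_freq=0.03, tolerance=0.001, seed=11,
        )
        with pytest.raises(ValueError, match="tolerance"):
            run_rejection(cfg)

    def test_vectorized_path_agrees_with_scalar_trajectory(self):
        cfg = MonteCarloConfig(n_draws=200, seed=5)
        posterior = run_rejection(cfg)
        lo = cfg.target_freq - cfg.tolerance
        hi = cfg.target_freq + cfg.tolerance
        for c, f_RR in zip(posterior.accepted_costs, posterior.accepted_f_RR):
            init = GenotypeState(f_RR, 2 * (0.6 - f_RR), 1 - f_RR - 2 * (0.6 - f_RR))
            traj = simulate_trajectory(
                init, SelectionParams(float(c), cfg.het_cost_multiplier),
                events=cfg.events, n_generations=cfg.n_generations,
            )
            assert lo <= traj[-1].allele_freq <= hi

    def test_reproducible_from_seed(self):
        a = run_rejection(MonteCarloConfig(n_draws=2000, seed=42))
        b = run_rejection(MonteCarloConfig(n_draws=2000, seed=42))
        assert np.array_equal(a.accepted_costs, b.accepted_costs)

    def test_synthetic_recovery_of_known_cost(self):
        c_true = 0.30
        init = sample_initial_state(0.5, MonteCarloConfig())
        traj = simulate_trajectory(
            init, SelectionParams(c_true),
            events=(IntrogressionEvent(10), IntrogressionEvent(15)),
            n_generations=17,
        )
        cfg = MonteCarloConfig(
            n_draws=20_000, target_freq=traj[-1].allele_freq, seed=9
        )
        posterior = run_rejection(cfg)
        lo, hi = posterior.ci
        assert lo <= c_true <= hi


class TestSummarizePosterior:
    def test_small_sample_mean(self):
        p = CostPosterior(np.array([0.3, 0.4]), np.array([0.5, 0.5]), 10, 0)
        report = summarize_posterior(p)
        assert report["mean_cost"] == pytest.approx(0.35)

    def test_degenerate_ci(self):
        p = CostPosterior(np.full(50, 0.2), np.full(50, 0.5), 100, 0)
        report = summarize_posterior(p)
        assert report["ci_low"] == pytest.approx(0.2)
        assert report["ci_high"] == pytest.approx(0.2)

    def test_empty_posterior_errors(self):
        p = CostPosterior(np.array([]), np.array([]), 10, 0)
        with pytest.raises(ValueError, match="empty"):
            summarize_posterior(p)

    def test_histogram_counts_total(self):
        p = CostPosterior(np.linspace(0.1, 0.9, 33), np.full(33, 0.5), 100, 0)
        report = summarize_posterior(p, n_bins=8)
        assert sum(report["histogram"]["counts"]) == 33


class TestConfig:
    def test_round_trip_from_dict(self):
        cfg = MonteCarloConfig.from_dict(
            {
                "n_draws": 1000,
                "events": [{"generation": 10}, {"generation": 15, "male_ratio": 0.2}],
                "cost_prior": [0.0, 0.5],
                "seed": 3,
            }
        )
        assert cfg.events[1].male_ratio == 0.2
        assert cfg.cost_prior == (0.0, 0.5)

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError, match="tolerance"):
            MonteCarloConfig(tolerance=0.0)

    def test_invalid_prior(self):
        with pytest.raises(ValueError, match="cost_prior"):
            MonteCarloConfig(cost_prior=(0.5, 0.2))
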