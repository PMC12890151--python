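import numpy as np
import pytest

from coupledpk import (ConcentrationSeries, DrugRates, ObjectiveSpec,
                       ObservedPair, add_noise, aic, analytic_uncoupled,
                       bootstrap_fit, build_constraints, fit_interactions_pso,
                       fit_single_drug, hybrid_constants,
                       interaction_effect_at_time, interaction_effect_max,
                       make_scenario, objective_value, r_squared,
                       replicate_fits, simulate, NoiseSpec)
from coupledpk.estimate import AblationScheme, ablation_study, objective_components


@pytest.fixture(scope="module")
def coupled_pair():
    """Noise-free combined-administration observations at g_abs_x = 0.4."""
    system = make_scenario(g_abs_x=0.4)
    traj = simulate(system, horizon=12.6, output_step=0.01)
    return add_noise(traj, NoiseSpec(sd_frac=0.0, n_reps=1, seed=0))[0]


@pytest.fixture(scope="module")
def baseline_constraints(baseline_system, coupled_pair):
    return build_constraints(baseline_system.drug_x.rates,
                             baseline_system.drug_y.rates, 0.6, 1.0,
                             float(coupled_pair.obs_x.max()),
                             float(coupled_pair.obs_y.max()))


class TestObjective:
    def test_exact_data_scores_zero(self, baseline_system, coupled_pair):
        spec = ObjectiveSpec(lambda_=0.0, data=coupled_pair)
        w = np.zeros(8)
        w[0] = 0.4
        assert objective_value(w, baseline_system, spec) == pytest.approx(0.0, abs=1e-9)

    def test_mean_squared_residuals_by_hand(self, baseline_system):
        # two drug-X residuals of +-0.1 and exact drug-Y data: z = 0.02/2
        times = np.array([1.0, 2.0])
        traj = simulate(make_scenario(), horizon=3.0, output_step=0.01)
        model_x = traj.evaluate(times, "x", "central")
        model_y = traj.evaluate(times, "y", "central")
        pair = ObservedPair(times, model_x + np.array([0.1, -0.1]), times, model_y)
        spec = ObjectiveSpec(lambda_=0.0, data=pair)
        z = objective_value(np.zeros(8), baseline_system, spec)
        assert z == pytest.approx(0.01, rel=1e-5)

    def test_l2_is_plain_sum_of_squares(self, baseline_system):
        # data generated by W itself, lambda = 1: z equals sum of w^2
        w = np.full(8, 0.5)
        system = baseline_system.with_interactions(w)
        traj = simulate(system, horizon=12.6, output_step=0.01)
        pair = add_noise(traj, NoiseSpec(sd_frac=0.0, n_reps=1, seed=0))[0]
        spec = ObjectiveSpec(lambda_=1.0, data=pair)
        assert objective_value(w, baseline_system, spec) == pytest.approx(8 * 0.25, rel=1e-6)

    def test_decomposition_z_lambda_equals_z0_plus_penalty(self, baseline_system,
                                                           coupled_pair):
        rng = np.random.default_rng(3)
        w = rng.uniform(-0.2, 0.5, size=8)
        z0 = objective_value(w, baseline_system,
                             ObjectiveSpec(lambda_=0.0, data=coupled_pair))
        z1 = objective_value(w, baseline_system,
                             ObjectiveSpec(lambda_=0.7, data=coupled_pair))
        assert z1 == pytest.approx(z0 + 0.7 * np.sum(w ** 2), rel=1e-10)

    def test_amount_scale_rescales_sse_only(self, baseline_system, coupled_pair):
        w = np.zeros(8)
        a = objective_components(w, baseline_system,
                                 ObjectiveSpec(lambda_=0.0, data=coupled_pair))
        b = objective_components(w, baseline_system,
                                 ObjectiveSpec(lambda_=0.0, data=coupled_pair,
                                               amount_scale=1000.0))
        assert b["sse_x"] == pytest.approx(1e6 * a["sse_x"], rel=1e-9)


class TestConstraints:
    def test_reference_lower_bounds(self, baseline_constraints):
        # absorption bounds: -k_abs / partner dose
        assert baseline_constraints.lower[0] == pytest.approx(-0.5 / 1.0)
        assert baseline_constraints.lower[4] == pytest.approx(-0.6 / 0.6)

    def test_null_vector_always_feasible(self, baseline_constraints):
        assert baseline_constraints.contains(np.zeros(8))

    def test_violations_name_the_offending_bound(self, baseline_constraints):
        w = np.zeros(8)
        w[0] = -0.7
        msgs = baseline_constraints.violations(w)
        assert len(msgs) == 1 and "x_abs" in msgs[0]

    def test_nonpositive_inputs_rejected(self, baseline_system):
        with pytest.raises(ValueError, match="dose_y"):
            build_constraints(baseline_system.drug_x.rates,
                              baseline_system.drug_y.rates, 0.6, 0.0, 0.1, 0.1)


class TestStage1:
    def test_known_volume_recovers_rates_exactly(self):
        times = np.geomspace(0.1, 24, 25)
        rates = DrugRates(0.6, 0.5, 0.4, 0.3)
        conc = analytic_uncoupled(rates, 1.0, times) / 3000.0
        fit = fit_single_drug(ConcentrationSeries(times=times, values=conc,
                                                  unit="g/ml"), 1.0,
                              seed=0, v_central=3000.0)
        np.testing.assert_allclose(fit.rates.as_array(), rates.as_array(), atol=1e-4)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_free_volume_recovers_curve_and_exponent_set(self):
        # with Vc free the parameters are identified only up to the
        # absorption/disposition exchange; the exponent set and the curve
        # itself are invariant
        times = np.geomspace(0.1, 24, 25)
        rates = DrugRates(0.6, 0.5, 0.4, 0.3)
        conc = analytic_uncoupled(rates, 1.0, times) / 3000.0
        fit = fit_single_drug(ConcentrationSeries(times=times, values=conc,
                                                  unit="g/ml"), 1.0, seed=0)
        refit = analytic_uncoupled(fit.rates, 1.0, times) / fit.v_central
        np.testing.assert_allclose(refit, conc, atol=1e-10)
        got = sorted([*hybrid_constants(fit.rates), fit.rates.k_abs])
        want = sorted([*hybrid_constants(rates), rates.k_abs])
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_under_determined_data_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            fit_single_drug(ConcentrationSeries(times=[1, 2, 3],
                                                values=[0.1, 0.2, 0.1],
                                                unit="g/ml"), 1.0)


class TestStage2:
    def test_quick_single_free_parameter_recovery(self, baseline_system,
                                                  coupled_pair, baseline_constraints,
                                                  fast_pso):
        mask = np.zeros(8, dtype=bool)
        mask[0] = True
        spec = ObjectiveSpec(lambda_=0.0, data=coupled_pair)
        fit = fit_interactions_pso(spec, baseline_constraints, fast_pso,
                                   baseline_system, mask=mask)
        assert fit.w[0] == pytest.approx(0.4, abs=1e-3)
        assert np.all(fit.w[1:] == 0.0)
        assert fit.k_free == 1

    def test_seeded_determinism(self, baseline_system, coupled_pair,
                                baseline_constraints, fast_pso):
        mask = np.zeros(8, dtype=bool)
        mask[0] = True
        spec = ObjectiveSpec(lambda_=0.0, data=coupled_pair)
        a = fit_interactions_pso(spec, baseline_constraints, fast_pso,
                                 baseline_system, mask=mask)
        b = fit_interactions_pso(spec, baseline_constraints, fast_pso,
                                 baseline_system, mask=mask)
        assert np.array_equal(a.w, b.w)
        assert a.z == b.z

    def test_huge_lambda_shrinks_estimates_to_zero(self, baseline_system,
                                                   coupled_pair, baseline_constraints,
                                                   fast_pso):
        spec = ObjectiveSpec(lambda_=1e3, data=coupled_pair)
        fit = fit_interactions_pso(spec, baseline_constraints, fast_pso,
                                   baseline_system)
        assert np.max(np.abs(fit.w)) < 1e-3

    def test_estimates_respect_bounds(self, baseline_system, coupled_pair,
                                      baseline_constraints, fast_pso):
        spec = ObjectiveSpec(lambda_=0.0, data=coupled_pair)
        fit = fit_interactions_pso(spec, baseline_constraints, fast_pso,
                                   baseline_system)
        assert baseline_constraints.contains(fit.w)


class TestBootstrapAndAblation:
    def test_bootstrap_from_identical_replicates_degenerates(self, baseline_system,
                                                             coupled_pair,
                                                             baseline_constraints,
                                                             fast_pso):
        datasets = [coupled_pair, coupled_pair, coupled_pair]
        mask = np.zeros(8, dtype=bool)
        mask[0] = True
        fits = replicate_fits(datasets, baseline_system, baseline_constraints,
                              fast_pso, lambda_=0.0, mask=mask)
        with pytest.warns(UserWarning, match="degenerate"):
            table = bootstrap_fit(datasets, baseline_system, baseline_constraints,
                                  fast_pso, 0.0, n_boot=50, seed=2, fits=fits,
                                  null_values=np.zeros(8))
        # per-replicate optimizer seeds differ, so the optima agree only to
        # the polish tolerance; the interval is still effectively a point
        row = table.iloc[0]
        assert row["ci_hi"] - row["ci_lo"] == pytest.approx(0.0, abs=1e-4)
        assert "p_value" in table.columns

    def test_bootstrap_requires_replicates(self, baseline_system, coupled_pair,
                                           baseline_constraints, fast_pso):
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_fit([coupled_pair], baseline_system, baseline_constraints,
                          fast_pso, 0.0)

    def test_empty_scheme_list_gives_empty_table(self, baseline_system, coupled_pair,
                                                 baseline_constraints, fast_pso):
        spec = ObjectiveSpec(lambda_=0.0, data=coupled_pair)
        table = ablation_study(spec, baseline_constraints, fast_pso,
                               baseline_system, schemes=())
        assert table.empty

    def test_scheme_masks_touch_only_absorption_and_elimination(self):
        assert AblationScheme.FULL.pinned_indices == ()
        assert AblationScheme.NO_ABSORPTION.pinned_indices == (0, 4)
        assert AblationScheme.NO_ELIMINATION.pinned_indices == (3, 7)
        assert AblationScheme.NO_ABS_ELIM.pinned_indices == (0, 3, 4, 7)


class TestFitStatistics:
    def test_r_squared_reference_points(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0
        assert r_squared([1, 2, 3], [2, 2, 2]) == 0.0
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_r_squared_rejects_constant_observations(self):
        with pytest.raises(ValueError, match="variance"):
            r_squared([1, 1, 1], [1, 2, 3])

    def test_aic_hand_value_and_identities(self):
        assert aic(0.1, 10, 8) == pytest.approx(10 * np.log(0.01) + 16)
        assert aic(1.0, 10, 1) - aic(1.0, 10, 0) == pytest.approx(2.0)
        assert aic(1.0, 10, 3) - aic(0.5, 10, 3) == pytest.approx(10 * np.log(2.0))

    def test_interaction_effect_reference_ratios(self):
        assert interaction_effect_max(-1.270, 0.05, 0.205) == pytest.approx(-30.98, abs=0.01)
        assert interaction_effect_max(-2.354, 0.05, 0.716) == pytest.approx(-16.44, abs=0.01)
        assert interaction_effect_max(0.0, 0.05, 0.2) == 0.0

    def test_interaction_effect_time_modes(self, baseline_system):
        traj = simulate(baseline_system, horizon=12.0, output_step=0.01)
        # at t=0 the instantaneous effect equals the maximum-effect formula
        # with the initial partner gut amount (the dose)
        inst0 = interaction_effect_at_time(traj, "x", "abs", -0.3, 0.5, 0.0,
                                           mode="instantaneous")
        assert inst0 == pytest.approx(interaction_effect_max(-0.3, 1.0, 0.5))
        # the driving gut compartment drains, so the averaged effect at a
        # late time is smaller in magnitude than at an early time
        early = interaction_effect_at_time(traj, "x", "abs", -0.3, 0.5, 2.0)
        late = interaction_effect_at_time(traj, "x", "abs", -0.3, 0.5, 12.0)
        assert abs(late) < abs(early) < abs(inst0)
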