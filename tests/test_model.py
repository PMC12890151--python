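import numpy as np
import pytest

from coupledpk import (ConcentrationSeries, CoupledSystem, DrugInteractions,
                       DrugRates, DrugSpec, amount_from_concentration,
                       analytic_uncoupled, concentration_from_amount,
                       coupled_rhs, hybrid_constants, make_scenario, simulate)


def table_system(**g):
    return make_scenario(**g)


class TestCoupledRhs:
    def test_uncoupled_gut_drain_matches_hand_substitution(self, baseline_system):
        state = np.array([0.6, 0, 0, 0, 1.0, 0, 0, 0])
        d = coupled_rhs(state, baseline_system)
        assert d[0] == pytest.approx(-0.30)
        assert d[4] == pytest.approx(-0.60)

    def test_absorption_coupling_scales_with_partner_gut_amount(self):
        system = table_system(g_abs_x=0.4)
        d = coupled_rhs(np.array([0.6, 0, 0, 0, 1.0, 0, 0, 0]), system)
        assert d[0] == pytest.approx(-(0.5 + 0.4 * 1.0) * 0.6)

    def test_zero_state_gives_zero_derivative(self, baseline_system):
        assert np.all(coupled_rhs(np.zeros(8), baseline_system) == 0.0)

    def test_per_drug_components_conserve_amount(self):
        system = table_system(g_abs_x=0.4, g_el_y=-0.2)
        rng = np.random.default_rng(0)
        state = rng.uniform(0, 0.5, size=8)
        d = coupled_rhs(state, system)
        assert d[:4].sum() == pytest.approx(0.0, abs=1e-15)
        assert d[4:].sum() == pytest.approx(0.0, abs=1e-15)

    def test_non_finite_state_rejected(self, baseline_system):
        state = np.full(8, np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            coupled_rhs(state, baseline_system)


class TestAnalyticUncoupled:
    def test_hybrid_constants_of_reference_drug(self):
        lam1, lam2 = hybrid_constants(DrugRates(0.5, 0.5, 0.5, 0.5))
        assert lam1 == pytest.approx(0.190983, abs=1e-6)
        assert lam2 == pytest.approx(1.309017, abs=1e-6)

    def test_reference_curve_is_two_exponential(self):
        # k_abs = k_pc cancels the absorption exponential algebraically
        rates = DrugRates(0.5, 0.5, 0.5, 0.5)
        t = np.linspace(0, 40, 401)
        lam1, lam2 = hybrid_constants(rates)
        expected = 0.268328 * (np.exp(-lam1 * t) - np.exp(-lam2 * t))
        np.testing.assert_allclose(analytic_uncoupled(rates, 0.6, t), expected,
                                   atol=2e-6)

    def test_initial_condition_is_zero(self):
        assert analytic_uncoupled(DrugRates(1.1, 0.4, 0.2, 0.3), 2.0, [0.0])[0] == 0.0

    def test_degenerate_absorption_rate_uses_analytic_limit(self):
        # k_abs equal to a hybrid constant: limit form must agree with the
        # numerical integration of the same system
        rates0 = DrugRates(1.0, 0.5, 0.5, 0.5)
        lam1, _ = hybrid_constants(rates0)
        rates = DrugRates(lam1, 0.5, 0.5, 0.5)
        system = CoupledSystem(DrugSpec(dose=0.6, rates=rates),
                               DrugSpec(dose=0.0, rates=rates0))
        traj = simulate(system, horizon=20.0, output_step=0.05)
        np.testing.assert_allclose(analytic_uncoupled(rates, 0.6, traj.times),
                                   traj.central("x"), atol=1e-6)

    def test_repeated_hybrid_roots_rejected(self):
        with pytest.raises(ValueError, match="degenerate|repeated"):
            # k_cp -> 0 limit where the discriminant can close: construct an
            # exactly repeated-root configuration via k_pc == k_el, tiny k_cp
            hybrid_constants(DrugRates(0.5, 1e-18, 0.5, 0.5))


class TestSimulate:
    def test_matches_closed_form_when_uncoupled(self, baseline_system, uncoupled_traj):
        for drug, spec in (("x", baseline_system.drug_x), ("y", baseline_system.drug_y)):
            expected = analytic_uncoupled(spec.rates, spec.dose, uncoupled_traj.times)
            np.testing.assert_allclose(uncoupled_traj.central(drug), expected, atol=1e-6)

    def test_zero_doses_give_zero_trajectory(self, baseline_system):
        system = CoupledSystem(
            DrugSpec(dose=0.0, rates=baseline_system.drug_x.rates),
            DrugSpec(dose=0.0, rates=baseline_system.drug_y.rates))
        traj = simulate(system, horizon=5.0, output_step=0.1)
        assert np.all(traj.states == 0.0)

    def test_mass_balance_with_interactions(self):
        traj = simulate(table_system(g_abs_x=0.4, g_el_y=-0.25),
                        horizon=40.0, output_step=0.05)
        assert traj.mass_balance_error() < 1e-8

    def test_label_swap_is_exact(self):
        system = table_system(g_abs_x=0.4, g_cp_y=-0.2, g_el_x=0.3)
        a = simulate(system, horizon=20.0, output_step=0.1)
        b = simulate(system.swapped(), horizon=20.0, output_step=0.1)
        permuted = np.concatenate([b.states[:, 4:], b.states[:, :4]], axis=1)
        assert np.array_equal(a.states, permuted)

    def test_invalid_horizon_or_step(self, baseline_system):
        with pytest.raises(ValueError):
            simulate(baseline_system, horizon=-1.0)
        with pytest.raises(ValueError):
            simulate(baseline_system, output_step=0.0)


class TestConcentrationConversion:
    def test_zero_concentration_zero_amount(self):
        s = ConcentrationSeries(times=[1, 2], values=[0, 0], unit="g/ml",
                                v_central=100.0)
        assert np.all(amount_from_concentration(s) == 0.0)

    def test_direct_product_with_reference_volume(self):
        s = ConcentrationSeries(times=[1.0], values=[1e-5], unit="g/ml",
                                v_central=4163.137)
        assert amount_from_concentration(s)[0] == pytest.approx(0.04163137)

    def test_round_trip_is_identity(self):
        amounts = np.array([0.0, 0.01, 0.2, 0.6])
        series = concentration_from_amount([0, 1, 2, 3], amounts, 2000.0, "ug/ml")
        np.testing.assert_array_equal(amount_from_concentration(series), amounts)

    def test_missing_volume_and_negative_values_rejected(self):
        s = ConcentrationSeries(times=[1.0], values=[0.1], unit="g/ml")
        with pytest.raises(ValueError, match="v_central"):
            amount_from_concentration(s)
        with pytest.raises(ValueError, match="negative"):
            ConcentrationSeries(times=[1.0], values=[-0.1], unit="g/ml")

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            ConcentrationSeries(times=[1.0], values=[0.1], unit="furlongs")


class TestValidation:
    @pytest.mark.parametrize("bad", [0.0, -0.5, np.nan, np.inf])
    def test_rates_must_be_positive_finite(self, bad):
        with pytest.raises(ValueError):
            DrugRates(bad, 0.5, 0.5, 0.5)

    def test_interactions_must_be_finite_but_any_sign(self):
        DrugInteractions(-5.0, 0.0, 3.0, -0.1)  # fine
        with pytest.raises(ValueError):
            DrugInteractions(np.nan, 0, 0, 0)

    def test_with_interactions_requires_8_vector(self, baseline_system):
        with pytest.raises(ValueError):
            baseline_system.with_interactions([1.0, 2.0])
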