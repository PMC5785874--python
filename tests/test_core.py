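"""Structural model: covariate functions, ODE solver, closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fenofed import (EventSchedule, FoodType, ModelParameters, RandomEffects,
                     bateman_cascade, calorie_profile, derived_fed_parameters,
                     effective_kg, effective_kma, effective_vc,
                     food_window_indicator, ode_rhs, solve_profile)


class TestCovariateFunctions:
    @pytest.mark.parametrize("t,fed,expected", [
        (3.0, True, 1),       # inside the 6.94 h post-meal window
        (8.0, True, 0),       # beyond the window
        (3.0, False, 0),      # fasted: no food effect at any time
        (0.0, True, 1),       # window is closed at its start
        (6.94, True, 0),      # and open at its end
    ])
    def test_food_window_indicator(self, t, fed, expected):
        assert food_window_indicator(t, 0.0, 0.0, 6.94, fed) == expected

    def test_window_rejects_negative_time_and_bad_window(self):
        with pytest.raises(ValueError):
            food_window_indicator(-1.0, 0.0, 0.0, 6.94, True)
        with pytest.raises(ValueError):
            food_window_indicator(1.0, 0.0, 7.0, 6.94, True)

    def test_effective_kg_fed_matches_reported_value(self):
        # 0.0412 * 1.617 = 0.0666, reported as 0.067 1/h
        assert effective_kg(0.0412, 0.617, 1) == pytest.approx(0.0666, abs=5e-5)
        assert round(effective_kg(0.0412, 0.617, 1), 3) == 0.067
        assert effective_kg(0.0412, 0.617, 0) == 0.0412
        assert effective_kg(0.123, 0.0, 1) == 0.123

    def test_effective_kg_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            effective_kg(0.0, 0.617, 1)
        with pytest.raises(ValueError):
            effective_kg(0.0412, -1.0, 1)

    def test_effective_kma_reported_fed_values(self):
        # calories expressed in 100-kcal units
        assert effective_kma(0.198, 0.0239, 6.863) == pytest.approx(0.2305, abs=5e-5)
        assert round(effective_kma(0.198, 0.0239, 6.863), 2) == 0.23
        assert round(effective_kma(0.198, 0.0239, 9.08), 2) == 0.24
        assert effective_kma(0.198, 0.0239, 0.0) == 0.198

    def test_effective_kma_rejects_nonpositive_result(self):
        with pytest.raises(ValueError):
            effective_kma(0.198, -1.0, 2.0)

    def test_effective_vc_by_food_type(self):
        assert effective_vc(12.9, FoodType.STANDARD) == pytest.approx(7.82, abs=5e-3)
        assert effective_vc(12.9, FoodType.HIGH_FAT) == pytest.approx(6.95, abs=5e-3)
        assert effective_vc(12.9, FoodType.FASTED) == 12.9
        with pytest.raises(ValueError):
            effective_vc(12.9, 7)


class TestOdeRhs:
    def test_zero_state_gives_zero_derivative(self, params):
        sch = EventSchedule.single_dose(250.0)
        d = ode_rhs(np.zeros(5), 1.0, params, sch)
        assert np.all(d == 0)

    def test_initial_fasted_derivative(self, params):
        # only the stomach holds drug: dX1 = -kg*X1 = -0.0412*250 = -10.3
        sch = EventSchedule.single_dose(250.0)
        d = ode_rhs([250.0, 0, 0, 0, 0], 0.5, params, sch)
        assert d[0] == pytest.approx(-10.3)
        assert d[1] == pytest.approx(+10.3)
        assert np.all(d[2:] == 0)

    def test_rhs_matches_finite_difference_of_solution(self, params):
        sch = EventSchedule.single_dose(250.0, FoodType.STANDARD, 686.3)
        h = 1e-4
        t0 = 3.0   # inside the food window, away from discontinuities
        grid = np.array([t0 - h, t0, t0 + h])
        prof = solve_profile(params, sch, t_grid=grid, rtol=1e-10, atol=1e-12)
        fd = (prof.states[2] - prof.states[0]) / (2 * h)
        rhs = ode_rhs(prof.states[1], t0, params, sch)
        assert np.allclose(fd, rhs, rtol=1e-4, atol=1e-7)


class TestSolveProfile:
    def test_zero_dose_gives_zero_profile(self, params):
        sch = EventSchedule(meal_events=((0.0, 686.3, FoodType.STANDARD),))
        prof = solve_profile(params, sch, t_grid=np.linspace(0, 24, 25))
        assert np.all(prof.conc == 0)

    def test_fasted_profile_matches_cascade_closed_form(self, params):
        sch = EventSchedule.single_dose(250.0)
        t = np.array([1.0, 4.0, 12.0, 24.0, 72.0])
        prof = solve_profile(params, sch, t_grid=t)
        oracle = bateman_cascade(t, 250.0, params.tv_kg, params.k_ma,
                                 params.k_el, params.vc_over_f)
        assert np.allclose(prof.conc, oracle, rtol=1e-6)

    def test_calorie_subsystem_matches_closed_form(self, params):
        sch = EventSchedule(meal_events=((0.0, 686.3, FoodType.STANDARD),))
        t = np.linspace(0, 72, 37)
        prof = solve_profile(params, sch, t_grid=t)
        x4, x5 = calorie_profile(t, 6.863, params.kg_prime, params.k_out)
        assert np.allclose(prof.states[:, 3], x4, rtol=1e-7, atol=1e-10)
        assert np.allclose(prof.states[:, 4], x5, rtol=1e-6, atol=1e-10)

    def test_calorie_closed_form_equal_rate_limit(self):
        # kg' ~= k_out: the generic formula degenerates; the limit form
        # must agree with slightly-split rates
        t = np.linspace(0, 100, 11)
        _, x5_limit = calorie_profile(t, 5.0, 0.01, 0.01 + 1e-9)
        _, x5_near = calorie_profile(t, 5.0, 0.01, 0.01 + 1e-7)
        assert np.allclose(x5_limit, x5_near, rtol=1e-4)

    def test_mass_balance_drug_and_calories(self, params):
        sch = EventSchedule.single_dose(250.0, FoodType.HIGH_FAT, 908.0)
        t = np.linspace(0, 72, 49)
        prof = solve_profile(params, sch, t_grid=t)
        drug = prof.states[:, :3].sum(axis=1) + prof.eliminated_drug
        cal = prof.states[:, 3:5].sum(axis=1) + prof.eliminated_calories
        assert np.allclose(drug, 250.0, atol=1e-6)
        assert np.allclose(cal, 9.08, atol=1e-8)

    def test_states_stay_non_negative(self, params):
        sch = EventSchedule.single_dose(250.0, FoodType.STANDARD, 686.3)
        re = RandomEffects(eta_kg=0.5, eta_kel=-1.0, eta_vc=0.3)
        prof = solve_profile(params, sch, realization=re,
                             t_grid=np.linspace(0, 72, 200))
        assert np.all(prof.states >= 0)

    def test_auc_invariant_to_absorption_covariates(self, params):
        # e_bile and e_food change the shape, never the total amount
        t = np.linspace(0, 2000, 4001)
        sch = EventSchedule.single_dose(250.0, FoodType.STANDARD, 686.3)
        base = solve_profile(params, sch, t_grid=t)
        boosted = solve_profile(
            params.replace(e_bile=0.1, e_food=2.0), sch, t_grid=t)
        auc0 = np.trapezoid(base.conc, t)
        auc1 = np.trapezoid(boosted.conc, t)
        assert auc1 == pytest.approx(auc0, rel=1e-4)
        # and Cmax is non-decreasing in the bile effect
        assert boosted.conc.max() >= base.conc.max()

    def test_concentration_scales_inversely_with_volume(self, params):
        sch = EventSchedule.single_dose(250.0)
        t = np.linspace(1, 72, 50)
        a = solve_profile(params, sch, t_grid=t)
        b = solve_profile(params.replace(vc_over_f=2 * params.vc_over_f),
                          sch, t_grid=t)
        assert np.allclose(a.conc, 2 * b.conc, rtol=1e-9)

    def test_zero_food_effect_fed_equals_fasted_drug_subsystem(self, params):
        # with e_food = 0 and no calories, a "fed" flag alone cannot alter
        # the drug profile
        p = params.replace(e_food=0.0, e_vc1=0.0)
        t = np.linspace(0, 72, 73)
        fasted = solve_profile(p, EventSchedule.single_dose(250.0), t_grid=t)
        fed = solve_profile(
            p, EventSchedule.single_dose(250.0, FoodType.STANDARD, 0.0),
            t_grid=t)
        # the two runs restart the integrator at different breakpoints, so
        # agreement is limited by the solver tolerance, not exactness
        assert np.allclose(fasted.conc, fed.conc, rtol=1e-7, atol=1e-12)

    def test_grid_must_cover_events(self, params):
        sch = EventSchedule.daily(3, 250.0)
        with pytest.raises(ValueError):
            solve_profile(params, sch, t_grid=np.linspace(0, 24, 5))


class TestDerivedFedParameters:
    def test_standard_meal_block(self, params):
        d = derived_fed_parameters(params, 686.3, FoodType.STANDARD)
        assert round(d.kg_fed, 3) == 0.067
        assert round(d.kma_fed, 2) == 0.23
        assert round(d.vc_fed, 2) == 7.82
        assert round(d.bioavailability_fold, 2) == 1.65
        assert d.kg_change_pct == pytest.approx(61.7)
        assert d.kma_change_pct == pytest.approx(16.4, abs=0.1)

    def test_high_fat_meal_block(self, params):
        d = derived_fed_parameters(params, 908.0, FoodType.HIGH_FAT)
        assert round(d.kma_fed, 2) == 0.24
        assert round(d.vc_fed, 2) == 6.95
        assert round(d.bioavailability_fold, 2) == 1.86
        assert d.kma_change_pct == pytest.approx(21.7, abs=0.1)

    def test_zero_effects_collapse_to_fasted(self, params):
        p = params.replace(e_food=0.0, e_bile=0.0, e_vc1=0.0, e_vc2=0.0)
        d = derived_fed_parameters(p, 686.3, FoodType.STANDARD)
        assert d.kg_fed == p.tv_kg
        assert d.kma_fed == p.k_ma
        assert d.vc_fed == p.vc_over_f
        assert d.bioavailability_fold == 1.0


@settings(deadline=None, max_examples=50)
@given(t=st.floats(0.0, 100.0), meal=st.floats(0.0, 48.0),
       mtime2=st.floats(0.1, 24.0))
def test_window_indicator_is_boolean_and_fasted_zero(t, meal, mtime2):
    fed = food_window_indicator(t, meal, 0.0, mtime2, True)
    assert fed in (0, 1)
    assert fed == int(meal <= t < meal + mtime2)
    assert food_window_indicator(t, meal, 0.0, mtime2, False) == 0
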