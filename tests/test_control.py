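"""Dose controller: quantisation, guideline bootstrap, PI update with
constraints, and closed-loop treatment behaviour."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catt import (
    CohortConfig,
    ControllerConfig,
    ControllerState,
    PiecewiseLinear,
    ValidationError,
    generate_cohort,
    initial_dose,
    quantize_dose,
    recommend_dose,
    run_treatment,
)
from catt.cohort import TrabPattern

CONFIG = ControllerConfig()


class TestQuantize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            (13.7, 13.75),  # nearest multiple of 1.25
            (43.2, 40.0),  # saturate at the 40 mg/day maximum
            (-2.0, 0.0),  # doses cannot be negative
            (13.125, 12.5),  # half-grid tie rounds to the lower dose
            (0.0, 0.0),
            (40.0, 40.0),
        ],
    )
    def test_examples(self, raw, expected):
        assert quantize_dose(raw, CONFIG) == expected

    @given(st.floats(min_value=-100.0, max_value=100.0))
    @settings(max_examples=200, deadline=None)
    def test_output_is_admissible_and_nearest(self, raw):
        q = quantize_dose(raw, CONFIG)
        assert 0.0 <= q <= 40.0
        steps = q / 1.25
        assert steps == pytest.approx(round(steps), abs=1e-9)
        clamped = min(max(raw, 0.0), 40.0)
        assert abs(q - clamped) <= 1.25 / 2 + 1e-9


class TestInitialDose:
    @pytest.mark.parametrize(
        "ft4,expected",
        [
            (44.5, 20.0),  # 1.93x the upper limit of normal
            (22.0, 0.0),  # below the upper limit
            (75.0, 40.0),  # more than 3x
            (30.0, 10.0),  # 1.30x
            (50.0, 30.0),  # 2.17x
        ],
    )
    def test_guideline_bands(self, ft4, expected):
        assert initial_dose(ft4, uln=23.0) == expected

    def test_non_positive_ft4_rejected(self):
        with pytest.raises(ValidationError):
            initial_dose(0.0)


class TestRecommendDose:
    def test_on_target_with_empty_state_recommends_nothing(self):
        state = ControllerState(integral=0.0, last_dose=0.0, last_day=0.0)
        dose, new = recommend_dose(CONFIG.reference, 28.0, state, CONFIG)
        assert dose == 0.0
        assert new.last_dose == 0.0

    def test_large_raw_dose_saturates_at_40(self):
        # error of 60 pmol/L with a large accumulated integral
        state = ControllerState(integral=3000.0, last_dose=40.0, last_day=0.0)
        dose, _ = recommend_dose(CONFIG.reference + 60.0, 28.0, state, CONFIG)
        assert dose == 40.0

    def test_rate_limit_binds_before_the_pi_value(self):
        # measured FT4 30 -> mid branch, |du| <= 10; craft the integral so
        # that the unconstrained PI dose is 5 while the last dose was 30
        ft4, dt = 30.0, 28.0
        e = ft4 - CONFIG.reference
        integral = (5.0 - CONFIG.kp * e) / CONFIG.ki - e * dt
        state = ControllerState(integral=integral, last_dose=30.0, last_day=0.0)
        dose, _ = recommend_dose(ft4, dt, state, CONFIG)
        assert dose == 20.0  # 30 - 10, not 5

    def test_in_range_increase_capped_at_one_quantum(self):
        ft4, dt = 20.0, 28.0  # in range
        e = ft4 - CONFIG.reference
        integral = (10.0 - CONFIG.kp * e) / CONFIG.ki - e * dt  # raw = 10
        state = ControllerState(integral=integral, last_dose=0.0, last_day=0.0)
        dose, _ = recommend_dose(ft4, dt, state, CONFIG)
        assert dose == CONFIG.rate_limit_up_in_range

    def test_non_positive_interval_rejected(self):
        state = ControllerState(integral=0.0, last_dose=0.0, last_day=28.0)
        with pytest.raises(ValidationError):
            recommend_dose(20.0, 28.0, state, CONFIG)

    def test_integral_stays_bounded_under_pinned_hyperthyroidism(self):
        # actuator saturated forever: back-calculation must keep the
        # integral from winding up
        state = ControllerState(integral=0.0, last_dose=40.0, last_day=0.0)
        history = []
        for k in range(1, 60):
            _, state = recommend_dose(80.0, 28.0 * k, state, CONFIG)
            history.append(abs(state.integral))
        assert history[-1] < 1e5
        assert abs(history[-1] - history[-10]) < 1.0  # settled, not growing


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortConfig(size=41, seed=0))


@pytest.fixture(scope="module")
def visit_days():
    return np.arange(0.0, 421.0, 28.0)


class TestClosedLoop:
    def test_disappearing_trab_patient_tapers_into_range(self, cohort, visit_days):
        patient = next(p for p in cohort if p.pattern.archetype == "disappearing")
        course = run_treatment(patient, visit_days)
        assert 9.5 <= course.ft4[-1] <= 24.0
        assert course.doses[-1] <= course.doses[0]

    def test_persistent_trab_needs_a_higher_maintenance_dose(self, cohort, visit_days):
        patient = next(p for p in cohort if p.pattern.archetype == "disappearing")
        pat = TrabPattern(
            "persistent",
            patient.pattern.amplitude,
            patient.pattern.tau,
            {"fluctuation": 0.05, "period": 120.0, "phase": 0.0},
        )
        twin = dataclasses.replace(
            patient, pattern=pat, trab=PiecewiseLinear(patient.trab.t, pat.evaluate(patient.trab.t))
        )
        c_dis = run_treatment(patient, visit_days)
        c_per = run_treatment(twin, visit_days)
        assert c_per.doses[-1] > c_dis.doses[-1]

    def test_ninety_percent_of_the_cohort_converges(self, cohort, visit_days):
        ok = 0
        for p in cohort:
            c = run_treatment(p, visit_days)
            late = c.days > 200.0
            ok += bool(np.all((c.ft4[late] >= 9.5) & (c.ft4[late] <= 24.0)))
        assert ok / len(cohort) >= 0.90

    def test_hard_dose_constraints_hold_everywhere(self, cohort, visit_days):
        config = ControllerConfig()
        for p in cohort[:15]:
            c = run_treatment(p, visit_days, config)
            assert np.all((c.doses >= 0.0) & (c.doses <= 40.0))
            steps = c.doses / config.grid
            assert np.allclose(steps, np.round(steps))
            for k in range(1, len(c.doses)):
                delta = c.doses[k] - c.doses[k - 1]
                limit = config.rate_limit(c.ft4[k])
                up = (
                    config.rate_limit_up_in_range
                    if config.b_l <= c.ft4[k] <= config.b_u
                    else limit
                )
                assert -limit - 1e-9 <= delta <= up + 1e-9

    def test_treatment_is_deterministic(self, cohort, visit_days):
        p = cohort[0]
        a = run_treatment(p, visit_days, seed=5, noise_cv=0.05)
        b = run_treatment(p, visit_days, seed=5, noise_cv=0.05)
        assert np.array_equal(a.ft4, b.ft4)
        assert np.array_equal(a.doses, b.doses)

    def test_measurement_noise_changes_readings_but_not_constraints(self, cohort, visit_days):
        p = cohort[1]
        clean = run_treatment(p, visit_days)
        noisy = run_treatment(p, visit_days, seed=7, noise_cv=0.05)
        assert not np.array_equal(clean.ft4, noisy.ft4)
        assert np.all((noisy.doses >= 0) & (noisy.doses <= 40))
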