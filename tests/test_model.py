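"""Core dynamics: right-hand side, simulation oracles, steady state,
record-derived exogenous inputs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catt import (
    DoseSchedule,
    ExogenousCourse,
    ModelState,
    ParameterBounds,
    PatientParameters,
    PatientRecord,
    PiecewiseLinear,
    ValidationError,
    exogenous_from_record,
    rhs,
    simulate,
    steady_state,
)


class TestRhs:
    def test_origin_is_an_equilibrium(self, midpoint_params):
        assert rhs((0.0, 0.0), 0.0, 0.0, 0.0, midpoint_params) == (0.0, 0.0)

    def test_mmi_mass_equilibrates_at_the_daily_dose(self, midpoint_params):
        dx1, _ = rhs((12.5, 37.0), 50.0, 1.0, 12.5, midpoint_params)
        assert dx1 == pytest.approx(0.0, abs=1e-14)

    def test_hyperthyroid_baseline_net_ft4_rate(self, midpoint_params):
        # hand arithmetic: TRAb term 15.307*108.8/(108.8 + 250.5) = 4.6352,
        # TSH term 0, degradation 0.12515*44.5 = 5.5692 -> net -0.9341
        _, dx2 = rhs((0.0, 44.5), 108.8, 0.0, 0.0, midpoint_params)
        assert dx2 == pytest.approx(-0.9341, abs=1e-3)

    @pytest.mark.parametrize("bad", [
        dict(state=(-1.0, 0.0), d1=0.0, d2=0.0, u=0.0),
        dict(state=(0.0, 0.0), d1=-5.0, d2=0.0, u=0.0),
        dict(state=(0.0, 0.0), d1=0.0, d2=0.0, u=45.0),
    ])
    def test_invalid_inputs_are_rejected(self, midpoint_params, bad):
        with pytest.raises(ValidationError):
            rhs(bad["state"], bad["d1"], bad["d2"], bad["u"], midpoint_params)

    def test_non_positive_parameters_are_rejected(self):
        with pytest.raises(ValidationError):
            PatientParameters(ka1=0.0, ka2=1, kT1=1, kT2=1, kT3=1, kf=0.1, kd=0.5, km=10)


class TestSimulate:
    def test_zero_input_ft4_decay_matches_closed_form(self, nominal_params):
        t = np.linspace(0.0, 60.0, 61)
        traj = simulate(
            nominal_params,
            DoseSchedule.constant(0.0),
            ExogenousCourse.constant(0.0, 0.0),
            ModelState(0.0, 44.5),
            t,
        )
        ref = 44.5 * np.exp(-nominal_params.kf * t)
        assert np.max(np.abs(traj.x2 - ref) / ref) < 1e-6

    def test_constant_dose_mmi_uptake_matches_closed_form(self, nominal_params):
        # x1(t) = u (1 - exp(-kd t)) with kd = ln 2: half the dose after 1 d
        traj = simulate(
            nominal_params,
            DoseSchedule.constant(10.0),
            ExogenousCourse.constant(0.0, 0.0),
            ModelState(0.0, 0.0),
            [0.0, 1.0, 30.0],
        )
        assert traj.x1[1] == pytest.approx(10.0 * (1 - np.exp(-nominal_params.kd)), rel=1e-6)
        assert traj.x1[2] == pytest.approx(10.0, rel=1e-4)

    def test_origin_is_invariant(self, midpoint_params):
        traj = simulate(
            midpoint_params,
            DoseSchedule.constant(0.0),
            ExogenousCourse.constant(0.0, 0.0),
            ModelState(0.0, 0.0),
            np.linspace(0, 100, 11),
        )
        assert np.all(traj.x1 == 0.0) and np.all(traj.x2 == 0.0)

    def test_states_stay_non_negative_and_bounded(self, bounds):
        # synthesis is capped at ka1 + kT1, so x2 <= (ka1 + kT1)/kf
        rng = np.random.default_rng(5)
        log_lo, log_hi = np.log(bounds.lower), np.log(bounds.upper)
        for _ in range(10):
            p = PatientParameters.from_array(np.exp(log_lo + rng.random(8) * (log_hi - log_lo)))
            traj = simulate(
                p,
                DoseSchedule([0.0, 50.0, 120.0], [40.0, 0.0, 20.0]),
                ExogenousCourse(
                    d1=PiecewiseLinear([0.0, 200.0], [300.0, 0.0]),
                    d2=PiecewiseLinear([0.0, 200.0], [0.0, 4.0]),
                ),
                ModelState(0.0, 100.0),
                np.linspace(0.0, 200.0, 101),
            )
            assert np.all(traj.x1 >= 0.0) and np.all(traj.x2 >= 0.0)
            assert np.all(traj.x2 <= (p.ka1 + p.kT1) / p.kf + 100.0 * np.exp(-p.kf * traj.t) + 1e-6)

    def test_dose_discontinuities_are_restart_points(self, nominal_params):
        # grid point exactly at the dose switch: values before/after consistent
        doses = DoseSchedule([0.0, 10.0], [0.0, 20.0])
        traj = simulate(
            nominal_params,
            doses,
            ExogenousCourse.constant(0.0, 0.0),
            ModelState(0.0, 30.0),
            np.linspace(0.0, 30.0, 301),
        )
        assert traj.u[traj.t < 10.0].max() == 0.0
        assert np.all(traj.u[traj.t >= 10.0] == 20.0)

    def test_grid_before_schedule_start_is_rejected(self, nominal_params):
        with pytest.raises(ValidationError):
            simulate(
                nominal_params,
                DoseSchedule.constant(0.0, t0=5.0),
                ExogenousCourse.constant(0, 0),
                ModelState(0, 0),
                [0.0, 10.0],
            )


class TestSteadyState:
    def test_trivial_zero(self, midpoint_params):
        assert steady_state(midpoint_params, 0.0, 0.0, 0.0) == (0.0, 0.0)

    def test_x1_equals_dose(self, midpoint_params):
        ss = steady_state(midpoint_params, 17.5, 80.0, 0.5)
        assert ss.x1 == 17.5

    def test_matches_long_horizon_integration(self, midpoint_params):
        ss = steady_state(midpoint_params, 0.0, 108.8, 0.0)
        assert ss.x2 == pytest.approx(37.04, abs=0.01)  # hand value ka1' / kf
        traj = simulate(
            midpoint_params,
            DoseSchedule.constant(0.0),
            ExogenousCourse.constant(108.8, 0.0),
            ModelState(0.0, 44.5),
            [0.0, 400.0],
        )
        assert traj.x2[-1] == pytest.approx(ss.x2, rel=1e-6)


class TestExogenousFromRecord:
    def _record(self, trab):
        return PatientRecord(
            days=[0.0, 10.0],
            tsh=[0.1, 0.2],
            ft4=[40.0, 35.0],
            trab=trab,
            dose=[10.0, 10.0],
        )

    def test_linear_interpolation_midpoint(self):
        exo = exogenous_from_record(self._record([100.0, 50.0]))
        assert exo.d1(5.0) == pytest.approx(75.0)

    def test_constant_extrapolation_beyond_last_visit(self):
        exo = exogenous_from_record(self._record([100.0, 50.0]))
        assert exo.d1(20.0) == pytest.approx(50.0)
        assert exo.d1(-3.0) == pytest.approx(100.0)

    def test_single_tsh_value_extends_everywhere(self):
        rec = PatientRecord([0.0], [0.5], [40.0], [np.nan], [0.0])
        exo = exogenous_from_record(rec)
        assert exo.d2(0.0) == exo.d2(100.0) == pytest.approx(0.5)

    def test_all_missing_trab_yields_zero_course_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="catt"):
            exo = exogenous_from_record(self._record([np.nan, np.nan]))
        assert exo.d1(5.0) == 0.0
        assert any("TRAb" in m for m in caplog.messages)

    def test_missing_trab_values_are_skipped_as_breakpoints(self):
        rec = PatientRecord(
            days=[0.0, 10.0, 20.0],
            tsh=[0.1, 0.1, 0.1],
            ft4=[40.0, 35.0, 30.0],
            trab=[100.0, np.nan, 60.0],
            dose=[10.0, 10.0, 10.0],
        )
        exo = exogenous_from_record(rec)
        assert exo.d1(10.0) == pytest.approx(80.0)  # linear between 0 and 20


class TestContainers:
    def test_record_validation_errors(self):
        with pytest.raises(ValidationError):
            PatientRecord([0.0, 0.0], [0, 0], [40, 40], [0, 0], [0, 0])  # duplicate days
        with pytest.raises(ValidationError):
            PatientRecord([1.0], [0], [40], [0], [0])  # first day not 0
        with pytest.raises(ValidationError):
            PatientRecord([0.0], [0], [np.nan], [0], [0])  # no FT4 at all
        with pytest.raises(ValidationError):
            PatientRecord([0.0], [0], [-1.0], [0], [0])  # negative value

    def test_dose_schedule_bounds(self):
        with pytest.raises(ValidationError):
            DoseSchedule([0.0], [41.0])
        with pytest.raises(ValidationError):
            DoseSchedule([0.0], [-1.0])

    @given(st.floats(min_value=-5.0, max_value=45.0))
    @settings(max_examples=50, deadline=None)
    def test_dose_lookup_is_piecewise_constant(self, t):
        sched = DoseSchedule([0.0, 10.0, 20.0], [5.0, 10.0, 2.5])
        expected = 5.0 if t < 10 else (10.0 if t < 20 else 2.5)
        assert sched.dose_at(t) == expected
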