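"""Discrete-time PI dose recommender and the closed-loop treatment runner.

The controller turns the FT4 tracking error at each appointment into a
daily MMI dose recommendation.  Clinical actuator constraints are built in:

* saturation — every dose lies in [0, 40] mg/day;
* quantisation — doses are integer multiples of 1.25 mg (a quarter of a
  20 mg tablet spread over up to four days), with half-grid ties rounded
  toward the *lower* dose;
* rate limiting — the change between consecutive prescriptions is bounded,
  with a larger allowance the further out of range the patient is;
* anti-windup — back-calculation: after every constraint is applied, the
  integral is nudged so that the controller's internal dose tracks the
  dose actually prescribed.  A saturated, rate-limited or quantised
  actuator therefore cannot wind the integrator up, and a stale integral
  unwinds instead of re-dosing a recovered patient.

Appointment intervals may vary; the integral term weights each error by
the actual elapsed time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import VirtualPatient, generate_tsh_course
from .model import (
    DOSE_MAX,
    DoseSchedule,
    ExogenousCourse,
    ModelState,
    PiecewiseLinear,
    Trajectory,
    ValidationError,
    simulate,
)

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "TreatmentCourse",
    "quantize_dose",
    "initial_dose",
    "recommend_dose",
    "run_treatment",
]


@dataclass(frozen=True)
class ControllerConfig:
    """Gains, constraints and scheduling defaults of the dose controller.

    ``b_l``/``b_u`` delimit the FT4 target interval (pmol/L); the tracking
    reference is their midpoint.  The rate-limit thresholds concretise
    "allow larger dose steps while the patient is far out of range":
    up to 20 mg when FT4 exceeds twice the upper bound, 10 mg when above
    the upper bound, 5 mg otherwise.
    """

    kp: float = 0.4  # mg per pmol/L of tracking error
    ki: float = 0.015  # mg per (pmol/L * day) of accumulated error
    grid: float = 1.25  # mg, dose quantum
    dose_max: float = DOSE_MAX  # mg/day
    b_l: float = 9.5  # pmol/L, lower target bound
    b_u: float = 24.0  # pmol/L, upper target bound
    uln: float = 23.0  # pmol/L, assay upper limit of normal (initial dosing)
    visit_interval: float = 28.0  # days, default appointment spacing
    rate_limit_low: float = 5.0  # mg, |du| cap while FT4 in [b_l, b_u]
    rate_limit_mid: float = 10.0  # mg, |du| cap while FT4 > b_u
    rate_limit_high: float = 20.0  # mg, |du| cap while FT4 > 2*b_u
    rate_limit_hypo: float = 15.0  # mg, |du| cap while FT4 < b_l (fast withdrawal)
    rate_limit_up_in_range: float = 1.25  # mg, max dose increase while FT4 in range
    windup_tt: float = 56.0  # days, back-calculation tracking time constant

    def __post_init__(self):
        if self.grid <= 0:
            raise ValidationError("dose grid spacing must be positive")
        if abs(self.dose_max / self.grid - round(self.dose_max / self.grid)) > 1e-9:
            raise ValidationError("dose_max must be a multiple of the grid spacing")
        if not (self.b_l < self.reference < self.b_u):
            raise ValidationError("need b_l < reference < b_u")

    @property
    def reference(self) -> float:
        """Tracking reference r = (b_u + b_l)/2, pmol/L."""
        return 0.5 * (self.b_u + self.b_l)

    def rate_limit(self, ft4: float) -> float:
        if ft4 > 2 * self.b_u:
            return self.rate_limit_high
        if ft4 > self.b_u:
            return self.rate_limit_mid
        if ft4 < self.b_l:
            return self.rate_limit_hypo
        return self.rate_limit_low

    def to_dict(self) -> dict:
        return {
            "kp": self.kp,
            "ki": self.ki,
            "grid": self.grid,
            "dose_max": self.dose_max,
            "b_l": self.b_l,
            "b_u": self.b_u,
            "uln": self.uln,
            "visit_interval": self.visit_interval,
            "rate_limit_low": self.rate_limit_low,
            "rate_limit_mid": self.rate_limit_mid,
            "rate_limit_high": self.rate_limit_high,
            "rate_limit_hypo": self.rate_limit_hypo,
            "rate_limit_up_in_range": self.rate_limit_up_in_range,
            "windup_tt": self.windup_tt,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ControllerConfig":
        return cls(**d)


@dataclass(frozen=True)
class ControllerState:
    """Carry-over between appointments."""

    integral: float  # accumulated error, (pmol/L)*day
    last_dose: float  # mg, on the admissible grid
    last_day: float  # days


@dataclass(frozen=True)
class TreatmentCourse:
    """Closed-loop record of one treated (virtual) patient."""

    patient_id: str
    days: np.ndarray  # visit days
    ft4: np.ndarray  # measured FT4 at each visit, pmol/L
    doses: np.ndarray  # recommended daily dose at each visit, mg
    tsh: np.ndarray  # simulated TSH at each visit, µU/mL
    trab: np.ndarray  # TRAb at each visit, U/L
    trajectory: Trajectory | None = None
    config: ControllerConfig = field(default_factory=ControllerConfig)
    seed: int | None = None

    def __post_init__(self):
        if self.days.size < 1 or np.any(np.diff(self.days) <= 0):
            raise ValidationError("treatment course needs >= 1 strictly increasing visits")


def quantize_dose(raw: float, config: ControllerConfig | None = None) -> float:
    """Clamp to [0, dose_max], then round to the nearest grid multiple.

    A value exactly midway between two admissible doses rounds toward the
    lower (more conservative) dose.
    """
    config = config or ControllerConfig()
    clamped = min(max(float(raw), 0.0), config.dose_max)
    steps = clamped / config.grid
    lower = np.floor(steps)
    # strict '>' keeps exact half-grid ties on the lower dose
    if steps - lower > 0.5 + 1e-9:
        lower += 1
    return float(min(lower * config.grid, config.dose_max))


def initial_dose(
    baseline_ft4: float, uln: float | None = None, config: ControllerConfig | None = None
) -> float:
    """Guideline-style starting dose from the FT4 elevation over normal.

    The ratio FT4/ULN maps to bands: below normal-limit 0 mg; 1-1.5x 10 mg;
    1.5-2x 20 mg; 2-3x 30 mg; 3x and above 40 mg.  This seeds the feedback
    loop; from the second visit on the PI law takes over.
    """
    config = config or ControllerConfig()
    if baseline_ft4 <= 0:
        raise ValidationError("baseline FT4 must be positive")
    uln = config.uln if uln is None else float(uln)
    ratio = baseline_ft4 / uln
    if ratio < 1.0:
        dose = 0.0
    elif ratio < 1.5:
        dose = 10.0
    elif ratio < 2.0:
        dose = 20.0
    elif ratio < 3.0:
        dose = 30.0
    else:
        dose = 40.0
    return quantize_dose(dose, config)


def recommend_dose(
    measured_ft4: float,
    visit_day: float,
    state: ControllerState,
    config: ControllerConfig | None = None,
) -> tuple[float, ControllerState]:
    """One PI update: error -> raw dose -> rate limit -> saturate -> quantise.

    The integral is advanced by error * elapsed-days; after the constraints
    are applied, back-calculation anti-windup pulls the integral toward
    consistency with the dose actually prescribed (tracking time constant
    ``windup_tt``), so neither saturation nor rate limiting nor the dose
    grid can wind it up.  The rate limit is selected by the FT4 just
    measured at this visit.
    """
    config = config or ControllerConfig()
    dt = visit_day - state.last_day
    if dt <= 0:
        raise ValidationError(
            f"visit day {visit_day} must come after the previous visit ({state.last_day})"
        )
    e = measured_ft4 - config.reference
    integral = state.integral + e * dt
    raw = config.kp * e + config.ki * integral

    # dose decreases may use the full severity-dependent allowance; dose
    # increases while FT4 is already in range are never urgent and are
    # capped at one quantum (protects quantum-sensitive patients)
    limit = config.rate_limit(measured_ft4)
    up = (
        config.rate_limit_up_in_range
        if config.b_l <= measured_ft4 <= config.b_u
        else limit
    )
    delta = float(np.clip(raw - state.last_dose, -limit, up))
    dose = quantize_dose(state.last_dose + delta, config)
    integral += (dose - raw) * dt / (config.ki * config.windup_tt)
    return dose, ControllerState(integral=integral, last_dose=dose, last_day=float(visit_day))


def run_treatment(
    patient: VirtualPatient,
    visit_days: Sequence[float] | None = None,
    config: ControllerConfig | None = None,
    *,
    seed: int | None = None,
    noise_cv: float = 0.0,
    keep_trajectory: bool = False,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> TreatmentCourse:
    """Simulate the full closed loop over the given appointment days.

    At the first visit the guideline band sets the starting dose; at every
    later visit FT4 is read from the simulated patient (optionally with
    multiplicative measurement noise of coefficient of variation
    ``noise_cv``) and the PI law updates the prescription, which is then
    held constant until the next appointment.  TSH is animated by the
    patient's recovery policy but never read by the controller.
    """
    config = config or ControllerConfig()
    if visit_days is None:
        visit_days = np.arange(0.0, 420.0 + config.visit_interval, config.visit_interval)
    visit_days = np.atleast_1d(np.asarray(visit_days, dtype=float))
    if visit_days.size < 1 or np.any(np.diff(visit_days) <= 0):
        raise ValidationError("visit days must be non-empty and strictly increasing")
    rng = np.random.default_rng(seed) if noise_cv > 0 else None

    def measure(x2: float) -> float:
        if rng is None:
            return float(x2)
        return float(max(x2 * (1.0 + noise_cv * rng.standard_normal()), 0.0))

    x = patient.initial_state
    tsh = 0.0  # presenting patient is hyperthyroid: TSH fully suppressed
    ft4_meas = measure(x.x2)
    dose = initial_dose(ft4_meas, config.uln, config)
    cstate = ControllerState(integral=0.0, last_dose=dose, last_day=float(visit_days[0]))

    days_out = [float(visit_days[0])]
    ft4_out = [ft4_meas]
    dose_out = [dose]
    tsh_out = [tsh]
    trab_out = [float(patient.trab(visit_days[0]))]
    traj_parts: list[Trajectory] = []

    for k in range(1, visit_days.size):
        a, b = float(visit_days[k - 1]), float(visit_days[k])
        # TSH over the interval: linear from the current value to the
        # policy's response to the last measured FT4
        tsh_next = float(
            generate_tsh_course([ft4_meas, ft4_meas], [a, b], patient.tsh_policy, tsh0=tsh)[-1]
        )
        d2 = PiecewiseLinear([a, b], [tsh, tsh_next])
        exo = ExogenousCourse(d1=patient.trab, d2=d2)
        n_sub = max(int(round(b - a)), 2)
        t_grid = np.linspace(a, b, n_sub + 1) if keep_trajectory else np.array([a, b])
        traj = simulate(
            patient.params,
            DoseSchedule.constant(dose, t0=a),
            exo,
            x,
            t_grid,
            rtol=rtol,
            atol=atol,
        )
        if keep_trajectory:
            traj_parts.append(traj)
        x = traj.final_state()
        tsh = tsh_next
        ft4_meas = measure(x.x2)
        dose, cstate = recommend_dose(ft4_meas, b, cstate, config)
        days_out.append(b)
        ft4_out.append(ft4_meas)
        dose_out.append(dose)
        tsh_out.append(tsh)
        trab_out.append(float(patient.trab(b)))

    trajectory = None
    if traj_parts:
        trajectory = Trajectory(
            t=np.concatenate([p.t[:-1] for p in traj_parts] + [traj_parts[-1].t[-1:]]),
            x1=np.concatenate([p.x1[:-1] for p in traj_parts] + [traj_parts[-1].x1[-1:]]),
            x2=np.concatenate([p.x2[:-1] for p in traj_parts] + [traj_parts[-1].x2[-1:]]),
            d1=np.concatenate([p.d1[:-1] for p in traj_parts] + [traj_parts[-1].d1[-1:]]),
            d2=np.concatenate([p.d2[:-1] for p in traj_parts] + [traj_parts[-1].d2[-1:]]),
            u=np.concatenate([p.u[:-1] for p in traj_parts] + [traj_parts[-1].u[-1:]]),
        )
    return TreatmentCourse(
        patient_id=patient.id,
        days=np.asarray(days_out),
        ft4=np.asarray(ft4_out),
        doses=np.asarray(dose_out),
        tsh=np.asarray(tsh_out),
        trab=np.asarray(trab_out),
        trajectory=trajectory,
        config=config,
        seed=seed,
    )
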