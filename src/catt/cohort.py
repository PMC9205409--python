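"""Random virtual Graves' disease patients for closed-loop treatment studies.

A virtual patient is a parameter set drawn from the admissible box, a TRAb
excitation course of one of three clinically observed archetypes, and a TSH
response policy.  The archetype frequencies follow their occurrence in real
disease courses: 10% persistent TRAb elevation, 76% disappearing, and the
remaining 14% "complex" courses (decay with a rebound flare).

Feasibility: parameters are accepted only if the *untreated* steady-state
FT4 at the patient's TRAb peak lies in a window that makes the patient
genuinely but not absurdly hyperthyroid.  The defaults [25, 120] pmol/L put
every patient above the 23-24 pmol/L upper limit of normal while excluding
runaway FT4 values that the admissible parameter set is meant to rule out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    ExogenousCourse,
    ModelState,
    ParameterBounds,
    PatientParameters,
    PiecewiseLinear,
    ValidationError,
    steady_state,
)

__all__ = [
    "TRAB_ULN",
    "TrabPattern",
    "TshPolicy",
    "VirtualPatient",
    "CohortConfig",
    "sample_parameters",
    "generate_trab_course",
    "generate_tsh_course",
    "generate_virtual_patient",
    "generate_cohort",
]

#: Assay upper limit of normal for TRAb, U/L.
TRAB_ULN = 15.0

#: Assay upper limit of normal for FT4, pmol/L (reference range 13-23).
FT4_ULN = 23.0

ARCHETYPES = ("persistent", "disappearing", "complex")


@dataclass(frozen=True)
class TrabPattern:
    """Realised TRAb excitation archetype.

    amplitude A is the initial TRAb level (U/L); tau the decay time constant
    (days); ``extras`` holds archetype-specific shape parameters
    (fluctuation amplitude/period for persistent courses, rebound bump
    centre/width/height for complex ones).
    """

    archetype: str
    amplitude: float
    tau: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValidationError(f"unknown TRAb archetype {self.archetype!r}")
        if self.amplitude < 0 or self.tau <= 0:
            raise ValidationError("amplitude must be >= 0 and tau > 0")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        A, tau = self.amplitude, self.tau
        if self.archetype == "persistent":
            eps = self.extras["fluctuation"]
            period = self.extras["period"]
            phase = self.extras["phase"]
            v = A * (1.0 + eps * np.sin(2 * np.pi * t / period + phase))
        elif self.archetype == "disappearing":
            v = A * np.exp(-t / tau)
        else:  # complex: decay plus a rebound flare
            tb = self.extras["bump_day"]
            w = self.extras["bump_width"]
            h = self.extras["bump_height"]
            v = A * np.exp(-t / tau) + h * A * np.exp(-0.5 * ((t - tb) / w) ** 2)
        return np.maximum(v, 0.0)

    def to_dict(self) -> dict:
        return {
            "archetype": self.archetype,
            "amplitude": float(self.amplitude),
            "tau": float(self.tau),
            "extras": {k: float(v) for k, v in self.extras.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrabPattern":
        return cls(d["archetype"], d["amplitude"], d["tau"], dict(d["extras"]))


@dataclass(frozen=True)
class TshPolicy:
    """First-order TSH recovery rule used to animate virtual patients.

    TSH relaxes toward a graded equilibrium that is ~``target`` while FT4
    sits below ``suppress_above`` and smoothly falls to 0 as FT4 rises past
    it (the pituitary response is continuous, not a switch).  Recovery uses
    time constant ``tau``; suppression is much faster
    (``suppression_tau``).  The dosing controller never reads TSH — this
    policy only makes the simulated charts physiologically coherent.
    """

    target: float = 1.5  # µU/mL, mid-normal TSH
    tau: float = 60.0  # days, recovery time constant
    suppress_above: float = FT4_ULN  # pmol/L, mid-point of the shut-off
    suppression_width: float = 1.5  # pmol/L, softness of the shut-off
    suppression_tau: float = 5.0  # days, decay toward 0 when hyperthyroid

    def equilibrium(self, ft4: float) -> float:
        """TSH level the axis drifts toward at a sustained FT4."""
        z = (ft4 - self.suppress_above) / self.suppression_width
        return float(self.target / (1.0 + np.exp(np.clip(z, -50, 50))))

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "tau": self.tau,
            "suppress_above": self.suppress_above,
            "suppression_width": self.suppression_width,
            "suppression_tau": self.suppression_tau,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TshPolicy":
        return cls(**d)


@dataclass(frozen=True)
class VirtualPatient:
    """A simulatable disease instance: parameters + exogenous courses."""

    id: str
    params: PatientParameters
    pattern: TrabPattern
    trab: PiecewiseLinear
    tsh_policy: TshPolicy
    initial_state: ModelState

    def exogenous(self, tsh: PiecewiseLinear | None = None) -> ExogenousCourse:
        return ExogenousCourse(
            d1=self.trab, d2=tsh if tsh is not None else PiecewiseLinear.constant(0.0)
        )

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "params": self.params.to_dict(),
            "pattern": self.pattern.to_dict(),
            "trab_breakpoints": [float(t) for t in self.trab.t],
            "trab_values": [float(v) for v in self.trab.v],
            "tsh_policy": self.tsh_policy.to_dict(),
            "initial_state": {"x1": float(self.initial_state.x1), "x2": float(self.initial_state.x2)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VirtualPatient":
        return cls(
            id=d["id"],
            params=PatientParameters(**d["params"]),
            pattern=TrabPattern.from_dict(d["pattern"]),
            trab=PiecewiseLinear(d["trab_breakpoints"], d["trab_values"]),
            tsh_policy=TshPolicy.from_dict(d["tsh_policy"]),
            initial_state=ModelState(d["initial_state"]["x1"], d["initial_state"]["x2"]),
        )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generation settings.

    The archetype probabilities default to the observed disease-course
    frequencies (persistent 10%, disappearing 76%, complex 14%); the
    feasibility window bounds the untreated steady-state FT4 at TRAb peak.
    """

    size: int = 41
    seed: int = 0
    probabilities: tuple[float, float, float] = (0.10, 0.76, 0.14)  # per ARCHETYPES order
    ft4_floor: float = 25.0  # pmol/L, ensures overt hyperthyroidism
    ft4_cap: float = 120.0  # pmol/L, excludes runaway courses
    horizon: float = 420.0  # days covered by the TRAb course
    trab_grid_days: float = 7.0  # breakpoint spacing of the realised course
    bounds: ParameterBounds = field(default_factory=ParameterBounds)

    def __post_init__(self):
        if self.size < 1:
            raise ValidationError("cohort size must be >= 1")
        if abs(sum(self.probabilities) - 1.0) > 1e-9 or min(self.probabilities) < 0:
            raise ValidationError("archetype probabilities must be non-negative and sum to 1")
        if not (self.ft4_cap > self.ft4_floor > FT4_ULN):
            raise ValidationError(
                "need ft4_cap > ft4_floor > upper normal FT4 "
                f"({FT4_ULN}); got cap={self.ft4_cap}, floor={self.ft4_floor}"
            )


#: FT4 reference range used for the recovered-state feasibility check, pmol/L.
FT4_REF_LOW = 13.0


def _grid_compatible(p: PatientParameters, d1: float) -> bool:
    """One 1.25 mg quantum above the euthyroid dose keeps FT4 >= 9.5."""
    from scipy.optimize import brentq

    def gap(u):
        return steady_state(p, u, d1, TSH_RECOVERED).x2 - 16.75

    if gap(0.0) <= 0:
        u_star = 0.0
    elif gap(40.0) > 0:  # not titratable to target at this stage
        return False
    else:
        u_star = brentq(gap, 0.0, 40.0)
    return steady_state(p, u_star + 1.25, d1, TSH_RECOVERED).x2 >= 9.5

#: Mid-normal TSH assumed for the recovered (TRAb-free, untreated) state, µU/mL.
TSH_RECOVERED = 1.5


def sample_parameters(
    rng: np.random.Generator,
    bounds: ParameterBounds | None = None,
    trab_peak: float = 108.8,
    cap: float = 120.0,
    floor: float = 25.0,
) -> PatientParameters:
    """Rejection-sample a feasible parameter set.

    Draws log-uniformly in the admissible box and accepts when the implied
    patient is clinically coherent at both ends of the disease course:

    * *presenting* — the untreated (u = 0, TSH suppressed) steady-state FT4
      at ``trab_peak`` lies in ``[floor, cap]`` pmol/L: overtly
      hyperthyroid but bounded;
    * *controllable* — at the maximal clinical dose of 40 mg/day the
      steady-state FT4 at peak TRAb lies inside the target interval
      [9.5, 16.75] pmol/L: admissible dosages can reach the target but
      cannot drive the steady state below it, so FT4 stays within the
      pre-specified interval under every reasonable dosage;
    * *recovered* — with TRAb gone, no MMI and mid-normal TSH the
      steady-state FT4 falls back into the reference range: a patient whose
      antibodies disappear becomes euthyroid rather than permanently
      hypothyroid;
    * *no hypothyroid valley* — residual sub-normal TRAb (which blocks
      TSH-driven synthesis in the model) must not render the *untreated*
      patient hypothyroid at any stage of antibody decay: remission does
      not pass through an obligatory hypothyroid phase that no non-negative
      dose could counteract;
    * *dose-grid compatible* — a single 1.25 mg dose quantum above the
      euthyroid dose must not push the steady state below the target
      interval, checked both near recovery and at residual TRAb around the
      assay upper normal: the FT4 levels reachable on the clinical dose
      ladder are dense enough to land inside the reference range at every
      disease stage.
    """
    bounds = bounds or ParameterBounds()
    if not (cap > floor > FT4_ULN):
        raise ValidationError("need cap > floor > upper normal FT4")
    log_lo, log_hi = np.log(bounds.lower), np.log(bounds.upper)
    max_draws = 100_000
    for i in range(max_draws):
        p = PatientParameters.from_array(
            np.exp(log_lo + rng.random(8) * (log_hi - log_lo))
        )
        x2_sick = steady_state(p, 0.0, trab_peak, 0.0).x2
        if not (floor <= x2_sick <= cap):
            continue
        x2_treated = steady_state(p, 40.0, trab_peak, 0.0).x2
        if not (9.5 <= x2_treated <= 16.75):  # [B_l, r]
            continue
        x2_recovered = steady_state(p, 0.0, 0.0, TSH_RECOVERED).x2
        if not (FT4_REF_LOW <= x2_recovered <= FT4_ULN):
            continue
        if any(
            steady_state(p, 0.0, d1, TSH_RECOVERED).x2 < 9.5
            for d1 in (2.5, 5.0, 10.0, TRAB_ULN)
        ):
            continue
        if _grid_compatible(p, 0.0) and _grid_compatible(p, TRAB_ULN):
            return p
    raise ValidationError(
        f"acceptance rate below 1/{max_draws} for trab_peak={trab_peak}, "
        f"window [{floor}, {cap}] — check the configuration"
    )


def generate_trab_course(
    rng: np.random.Generator,
    probabilities: Sequence[float] = (0.10, 0.76, 0.14),
    horizon: float = 420.0,
    grid_days: float = 7.0,
) -> tuple[TrabPattern, PiecewiseLinear]:
    """Draw a TRAb archetype and realise it as a piecewise-linear course.

    * ``disappearing`` — A*exp(-t/tau) with tau capped so that the course
      falls below the 15 U/L assay upper normal before the horizon.
    * ``persistent`` — A*(1 + eps*sin(...)), eps <= 0.1, never below 0.9*A.
    * ``complex`` — disappearing decay plus a Gaussian rebound flare.

    Amplitudes are log-uniform in [20, 400] U/L, bracketing the dispersion
    of baseline TRAb in overt disease (typical mean near 110 U/L with a
    similar-sized standard deviation).
    """
    if horizon <= 0:
        raise ValidationError("horizon must be positive")
    probabilities = np.asarray(probabilities, dtype=float)
    archetype = ARCHETYPES[rng.choice(3, p=probabilities / probabilities.sum())]
    A = float(np.exp(rng.uniform(np.log(20.0), np.log(400.0))))
    # tau cap guarantees A*exp(-horizon/tau) < TRAB_ULN with 10% margin
    tau_cap = 0.9 * horizon / np.log(A / TRAB_ULN)
    tau = float(min(rng.uniform(30.0, 150.0), tau_cap))
    if archetype == "persistent":
        extras = {
            "fluctuation": float(rng.uniform(0.02, 0.10)),
            "period": float(rng.uniform(60.0, 180.0)),
            "phase": float(rng.uniform(0.0, 2 * np.pi)),
        }
        tau = horizon  # unused by the shape; kept positive for the dataclass
    elif archetype == "disappearing":
        extras = {}
    else:
        extras = {
            "bump_day": float(rng.uniform(0.3, 0.7) * horizon),
            "bump_width": float(rng.uniform(20.0, 60.0)),
            "bump_height": float(rng.uniform(0.3, 0.8)),
        }
    pattern = TrabPattern(archetype, A, tau, extras)
    t = np.arange(0.0, horizon + grid_days, grid_days)
    course = PiecewiseLinear(t, pattern.evaluate(t))
    return pattern, course


def generate_tsh_course(
    ft4_values: Sequence[float],
    days: Sequence[float],
    policy: TshPolicy | None = None,
    tsh0: float = 0.0,
) -> np.ndarray:
    """TSH at the given days from the FT4 history via the recovery policy.

    Discrete first-order lag: while FT4 exceeds the suppression threshold
    TSH decays toward 0; once FT4 is in range it relaxes toward the target.
    Always non-negative, and monotone non-decreasing while FT4 stays in
    range.
    """
    policy = policy or TshPolicy()
    ft4_values = np.atleast_1d(np.asarray(ft4_values, dtype=float))
    days = np.atleast_1d(np.asarray(days, dtype=float))
    if ft4_values.size != days.size:
        raise ValidationError("ft4_values and days must have equal length")
    if np.any(np.diff(days) <= 0):
        raise ValidationError("days must be strictly increasing")
    out = np.empty_like(ft4_values)
    tsh = max(float(tsh0), 0.0)
    out[0] = tsh
    for k in range(1, days.size):
        dt = days[k] - days[k - 1]
        eq = policy.equilibrium(float(ft4_values[k]))
        tau = policy.tau if eq > tsh else policy.suppression_tau
        tsh += (eq - tsh) * (1.0 - np.exp(-dt / tau))
        out[k] = tsh
    return np.maximum(out, 0.0)


def generate_virtual_patient(
    rng: np.random.Generator, config: CohortConfig | None = None, index: int = 0
) -> VirtualPatient:
    """Compose parameters, TRAb course and TSH policy into one patient.

    The initial state is the untreated steady state at the initial TRAb
    level with suppressed TSH — the patient presents overtly hyperthyroid
    and treatment-naive.
    """
    config = config or CohortConfig()
    pattern, course = generate_trab_course(
        rng, config.probabilities, config.horizon, config.trab_grid_days
    )
    params = sample_parameters(
        rng, config.bounds, trab_peak=course.max(), cap=config.ft4_cap, floor=config.ft4_floor
    )
    init = steady_state(params, 0.0, float(course(0.0)), 0.0)
    return VirtualPatient(
        id=f"vp{index:04d}",
        params=params,
        pattern=pattern,
        trab=course,
        tsh_policy=TshPolicy(),
        initial_state=init,
    )


def synthetic_fitting_record(
    rng: np.random.Generator,
    n_visits: int = 12,
    interval: float = 30.0,
    noise_sd: float = 0.0,
    bounds: ParameterBounds | None = None,
):
    """A model-generated appointment series with known ground truth.

    Emulates the data a parameter fit sees: monthly visits, a disappearing
    TRAb course, suppressed TSH, and a tapering MMI prescription.  FT4 at
    the visits is the exact model simulation plus optional additive
    Gaussian measurement noise (``noise_sd`` pmol/L).  The record follows
    the on-treatment initial-state convention (x1(0) = first prescribed
    dose, x2(0) = first FT4), so a noiseless record can be reproduced
    exactly by the fit's forward simulation.

    Returns ``(record, params)`` with the generating parameters.
    """
    from .model import DoseSchedule, PatientRecord, simulate

    bounds = bounds or ParameterBounds()
    A = float(np.exp(rng.uniform(np.log(40.0), np.log(300.0))))
    tau = float(rng.uniform(60.0, 180.0))
    params = sample_parameters(rng, bounds, trab_peak=A)
    days = np.arange(n_visits, dtype=float) * interval
    trab = A * np.exp(-days / tau)
    tsh = np.zeros(n_visits)  # overt hyperthyroidism: TSH suppressed
    u0 = float(rng.choice([15.0, 20.0, 25.0, 30.0]))
    doses = np.maximum(u0 - 5.0 * (np.arange(n_visits) // 2), 2.5)
    x2_0 = steady_state(params, 0.0, A, 0.0).x2
    exo = ExogenousCourse(PiecewiseLinear(days, trab), PiecewiseLinear.constant(0.0))
    traj = simulate(
        params, DoseSchedule(days, doses), exo, ModelState(u0, x2_0), days
    )
    ft4 = traj.x2.copy()
    if noise_sd > 0:
        ft4 = np.maximum(ft4 + noise_sd * rng.standard_normal(n_visits), 0.1)
    record = PatientRecord(days, tsh, ft4, trab, doses)
    return record, params


def generate_cohort(config: CohortConfig | None = None) -> list[VirtualPatient]:
    """Generate the full cohort; a pure function of the configuration.

    Every patient gets an independent child generator seeded from
    ``(config.seed, index)``, so cohorts are reproducible patient-by-patient
    and extending the cohort does not reshuffle earlier patients.
    """
    config = config or CohortConfig()
    out = []
    for i in range(config.size):
        rng = np.random.default_rng([config.seed, i])
        out.append(generate_virtual_patient(rng, config, index=i))
    return out


def cohort_to_json(patients: Sequence[VirtualPatient], config: CohortConfig) -> str:
    payload = {
        "schema_version": 1,
        "seed": config.seed,
        "size": config.size,
        "probabilities": list(config.probabilities),
        "patients": [p.to_dict() for p in patients],
    }
    return json.dumps(payload, indent=1, sort_keys=True)
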