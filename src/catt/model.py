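"""Two-state pharmacokinetic/pharmacodynamic model of free thyroxine (FT4)
under methimazole (MMI) treatment of Graves' disease.

States
------
``x1``
    Total mass of MMI within the thyroid gland, mg.
``x2``
    FT4 concentration, pmol/L.

Inputs
------
``u``
    Daily MMI dose, mg/day, piecewise constant between appointments.
``d1``
    TSH-receptor antibody concentration (TRAb), U/L, piecewise linear.
``d2``
    Thyroid-stimulating hormone (TSH), µU/mL, piecewise linear.

Dynamics::

    dx1/dt = kd * (u - x1)
    dx2/dt = ka1*d1 / (d1 + ka2*(1 + x1/km))
             + kT1*d2 / (d2*(1 + d1/kT2) + kT3*(1 + x1/km))
             - kf*x2

FT4 synthesis is driven by two saturating Michaelis-Menten terms (TRAb and
TSH stimulation); intrathyroidal MMI raises the apparent half-saturation
constants of both, and TRAb competitively blunts the TSH term.  Degradation
of both states is first order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import odeint, solve_ivp

logger = logging.getLogger("catt")

__all__ = [
    "PARAM_NAMES",
    "PatientParameters",
    "ParameterBounds",
    "ModelState",
    "PiecewiseLinear",
    "ExogenousCourse",
    "DoseSchedule",
    "Trajectory",
    "PatientRecord",
    "ValidationError",
    "SimulationError",
    "InsufficientDataError",
    "rhs",
    "simulate",
    "steady_state",
    "exogenous_from_record",
    "DOSE_MAX",
]

#: Hard upper bound on the daily MMI dose, mg/day.
DOSE_MAX = 40.0

#: Canonical parameter order used throughout (arrays, bounds, JSON).
PARAM_NAMES = ("ka1", "ka2", "kT1", "kT2", "kT3", "kf", "kd", "km")


class ValidationError(ValueError):
    """Input fails a domain invariant (negative concentration, bad grid...)."""


class SimulationError(RuntimeError):
    """The ODE solver failed; carries the time at which integration stopped."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class InsufficientDataError(ValidationError):
    """A record does not carry enough FT4 measurements for the operation."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientParameters:
    """The eight patient-specific positive constants of the model.

    Units: ka1, kT1 pmol/(L*day); ka2, kT2 U/L; kT3 µU/mL; kf, kd 1/day;
    km mg.
    """

    ka1: float  # maximum FT4 synthesis speed due to TRAb
    ka2: float  # individual TRAb impact (half-saturation)
    kT1: float  # maximum FT4 synthesis speed due to TSH
    kT2: float  # TRAb blocking impact on TSH-driven synthesis
    kT3: float  # individual TSH impact (half-saturation)
    kf: float  # FT4 degradation rate
    kd: float  # intrathyroidal MMI turnover rate
    km: float  # MMI impact scaling on FT4 production

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"parameter {f.name} must be strictly positive, got {v!r}"
                )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "PatientParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (8,):
            raise ValidationError(f"expected 8 parameters, got shape {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values)))

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


# Identified admissible interval per parameter (lower, upper), in the
# canonical order of PARAM_NAMES.
_DEFAULT_BOUNDS = {
    "ka1": (2.8881, 27.7259),
    "ka2": (1.0, 500.0),
    "kT1": (2.8881, 8.6643),
    "kT2": (1.0, 500.0),
    "kT3": (0.1, 50.0),
    "kf": (0.077, 0.1733),
    "kd": (0.1386, 1.3863),
    "km": (1.0, 200.0),
}


@dataclass(frozen=True)
class ParameterBounds:
    """Box constraints for the eight model parameters.

    Defaults are the identified admissible intervals; parameter fitting and
    virtual-patient sampling both stay inside this box.
    """

    bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))

    def __post_init__(self):
        if set(self.bounds) != set(PARAM_NAMES):
            raise ValidationError(
                f"bounds must cover exactly {PARAM_NAMES}, got {sorted(self.bounds)}"
            )
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi):
                raise ValidationError(f"bad bounds for {name}: [{lo}, {hi}]")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in PARAM_NAMES])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in PARAM_NAMES])

    def contains(self, params: PatientParameters, rtol: float = 1e-9) -> bool:
        v = params.to_array()
        return bool(
            np.all(v >= self.lower * (1 - rtol)) and np.all(v <= self.upper * (1 + rtol))
        )

    def midpoint(self) -> PatientParameters:
        return PatientParameters.from_array((self.lower + self.upper) / 2.0)


class ModelState(NamedTuple):
    """Instantaneous model state: (MMI mass in thyroid mg, FT4 pmol/L)."""

    x1: float
    x2: float

    def validate(self) -> "ModelState":
        if self.x1 < 0 or self.x2 < 0:
            raise ValidationError(f"state components must be non-negative: {self}")
        return self


# ---------------------------------------------------------------------------
# Exogenous inputs
# ---------------------------------------------------------------------------


class PiecewiseLinear:
    """Piecewise-linear signal with constant extrapolation outside the knots."""

    def __init__(self, t: Sequence[float], v: Sequence[float]):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        v = np.atleast_1d(np.asarray(v, dtype=float))
        if t.size == 0 or t.size != v.size:
            raise ValidationError("breakpoints and values must be non-empty and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("breakpoint times must be strictly increasing")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValidationError("signal values must be finite and non-negative")
        self.t = t
        self.v = v

    def __call__(self, t):
        return np.interp(t, self.t, self.v)

    @classmethod
    def constant(cls, value: float, t0: float = 0.0) -> "PiecewiseLinear":
        return cls([t0], [value])

    def max(self) -> float:
        return float(self.v.max())


@dataclass(frozen=True)
class ExogenousCourse:
    """The two stimulating inputs: d1 = TRAb (U/L), d2 = TSH (µU/mL)."""

    d1: PiecewiseLinear
    d2: PiecewiseLinear

    @classmethod
    def constant(cls, d1: float = 0.0, d2: float = 0.0) -> "ExogenousCourse":
        return cls(PiecewiseLinear.constant(d1), PiecewiseLinear.constant(d2))


@dataclass(frozen=True)
class DoseSchedule:
    """Piecewise-constant daily MMI dose.

    ``start_times[i]`` opens segment i with daily dose ``doses[i]``; the last
    segment extends indefinitely.  Doses are clinical daily doses in mg and
    must satisfy 0 <= u <= 40.
    """

    start_times: np.ndarray
    doses: np.ndarray

    def __init__(self, start_times: Sequence[float], doses: Sequence[float]):
        t = np.atleast_1d(np.asarray(start_times, dtype=float))
        u = np.atleast_1d(np.asarray(doses, dtype=float))
        if t.size == 0 or t.size != u.size:
            raise ValidationError("start_times and doses must be non-empty, equal length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("dose segment start times must be strictly increasing")
        if np.any(u < 0) or np.any(u > DOSE_MAX):
            raise ValidationError(f"every daily dose must satisfy 0 <= u <= {DOSE_MAX}")
        object.__setattr__(self, "start_times", t)
        object.__setattr__(self, "doses", u)

    @classmethod
    def constant(cls, dose: float, t0: float = 0.0) -> "DoseSchedule":
        return cls([t0], [dose])

    def dose_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.start_times, t, side="right")) - 1
        return float(self.doses[max(idx, 0)])

    def breakpoints_in(self, t0: float, t1: float) -> np.ndarray:
        m = (self.start_times > t0) & (self.start_times < t1)
        return self.start_times[m]


@dataclass(frozen=True)
class Trajectory:
    """Simulated time courses of the model states and evaluated inputs."""

    t: np.ndarray  # days
    x1: np.ndarray  # mg
    x2: np.ndarray  # pmol/L
    d1: np.ndarray  # U/L
    d2: np.ndarray  # µU/mL
    u: np.ndarray  # mg/day

    def __post_init__(self):
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("trajectory time grid must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_day": self.t,
                "x1_mg": self.x1,
                "ft4_pmol_per_L": self.x2,
                "trab_U_per_L": self.d1,
                "tsh_uU_per_mL": self.d2,
                "dose_mg_per_day": self.u,
            }
        )

    def final_state(self) -> ModelState:
        return ModelState(float(self.x1[-1]), float(self.x2[-1]))


# ---------------------------------------------------------------------------
# Patient records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientRecord:
    """Appointment series of a treated patient.

    Arrays are aligned per appointment; NaN marks a missing measurement.
    ``days`` are days since the first visit (first entry 0), ``dose`` is the
    daily MMI dose prescribed at that visit and taken until the next one.
    """

    days: np.ndarray
    tsh: np.ndarray  # µU/mL
    ft4: np.ndarray  # pmol/L
    trab: np.ndarray  # U/L
    dose: np.ndarray  # mg/day

    def __init__(self, days, tsh, ft4, trab, dose):
        arrays = {}
        for name, a in [("days", days), ("tsh", tsh), ("ft4", ft4), ("trab", trab), ("dose", dose)]:
            arrays[name] = np.atleast_1d(np.asarray(a, dtype=float))
        n = arrays["days"].size
        if n == 0:
            raise ValidationError("patient record is empty")
        for name, a in arrays.items():
            if a.size != n:
                raise ValidationError(f"column {name} has {a.size} entries, expected {n}")
        d = arrays["days"]
        if d[0] != 0:
            raise ValidationError(f"first appointment day must be 0, got {d[0]}")
        if np.any(np.diff(d) <= 0):
            raise ValidationError("appointment days must be strictly increasing")
        for name in ("tsh", "ft4", "trab", "dose"):
            a = arrays[name]
            if np.any(a[~np.isnan(a)] < 0):
                raise ValidationError(f"column {name} contains negative values")
        if np.all(np.isnan(arrays["ft4"])):
            raise ValidationError("record carries no FT4 measurement")
        if np.any(np.isnan(arrays["dose"])):
            raise ValidationError("every appointment needs a prescribed dose")
        for name, a in arrays.items():
            object.__setattr__(self, name, a)

    def __len__(self) -> int:
        return int(self.days.size)

    @property
    def n_ft4(self) -> int:
        return int(np.sum(~np.isnan(self.ft4)))

    def ft4_points(self) -> tuple[np.ndarray, np.ndarray]:
        m = ~np.isnan(self.ft4)
        return self.days[m], self.ft4[m]

    def dose_schedule(self) -> DoseSchedule:
        return DoseSchedule(self.days, self.dose)

    def first_ft4(self) -> float:
        return float(self.ft4[~np.isnan(self.ft4)][0])

    def max_trab(self) -> float:
        present = self.trab[~np.isnan(self.trab)]
        return float(present.max()) if present.size else 0.0


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------


def _rhs(x1: float, x2: float, d1: float, d2: float, u: float, p: PatientParameters):
    """Unchecked right-hand side; hot path for the solver."""
    block = 1.0 + x1 / p.km
    syn_trab = p.ka1 * d1 / (d1 + p.ka2 * block)
    syn_tsh = p.kT1 * d2 / (d2 * (1.0 + d1 / p.kT2) + p.kT3 * block)
    return p.kd * (u - x1), syn_trab + syn_tsh - p.kf * x2


def rhs(
    state: ModelState | tuple,
    d1: float,
    d2: float,
    u: float,
    params: PatientParameters,
) -> tuple[float, float]:
    """Evaluate the model derivatives (dx1/dt mg/day, dx2/dt pmol/(L*day)).

    All inputs must be non-negative; parameters strictly positive (enforced
    by :class:`PatientParameters`).
    """
    x1, x2 = state
    for name, v in [("x1", x1), ("x2", x2), ("d1", d1), ("d2", d2), ("u", u)]:
        if not np.isfinite(v) or v < 0:
            raise ValidationError(f"{name} must be finite and non-negative, got {v!r}")
    if u > DOSE_MAX:
        raise ValidationError(f"daily dose {u} exceeds the {DOSE_MAX} mg maximum")
    return _rhs(x1, x2, d1, d2, u, params)


def simulate(
    params: PatientParameters,
    doses: DoseSchedule,
    exo: ExogenousCourse,
    init: ModelState | tuple,
    t_grid: Sequence[float],
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model over ``t_grid`` (days).

    The solver restarts at every dose-segment boundary so that the
    piecewise-constant input discontinuities are handled exactly; within a
    segment the adaptive stiff-capable solver controls the local error.
    Tiny negative excursions from floating-point round-off are clamped to 0.
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValidationError("t_grid must contain >= 2 strictly increasing times")
    if t_grid[0] < doses.start_times[0] - 1e-12:
        raise ValidationError(
            f"t_grid starts at {t_grid[0]} before the first dose segment "
            f"({doses.start_times[0]})"
        )
    x1_0, x2_0 = float(init[0]), float(init[1])
    if x1_0 < 0 or x2_0 < 0:
        raise ValidationError("initial state must be non-negative")

    edges = np.unique(
        np.concatenate(
            [[t_grid[0]], doses.breakpoints_in(t_grid[0], t_grid[-1]), [t_grid[-1]]]
        )
    )
    d1f, d2f = exo.d1, exo.d2

    out_t = [t_grid[0]]
    out_x = [(x1_0, x2_0)]
    x = np.array([x1_0, x2_0])
    for a, b in zip(edges[:-1], edges[1:]):
        u = doses.dose_at(0.5 * (a + b))

        def f(t, y, _u=u):
            return _rhs(y[0], y[1], float(d1f(t)), float(d2f(t)), _u, params)

        interior = t_grid[(t_grid > a) & (t_grid < b)]
        t_eval = np.concatenate([interior, [b]])
        if method == "LSODA":
            # lsoda via odeint: same adaptive stiff/non-stiff code as
            # solve_ivp(method="LSODA") with far less per-segment overhead
            ys, info = odeint(
                f,
                x,
                np.concatenate([[a], t_eval]),
                rtol=rtol,
                atol=atol,
                tfirst=True,
                full_output=True,
            )
            if info["message"] != "Integration successful.":
                t_fail = float(info["tcur"][-1]) if len(info["tcur"]) else float(a)
                raise SimulationError(
                    f"ODE solver failed at t={t_fail:.4g} d: {info['message']}", t_fail
                )
            ts, states_seg = t_eval, ys[1:]
        else:
            sol = solve_ivp(f, (a, b), x, method=method, t_eval=t_eval, rtol=rtol, atol=atol)
            if not sol.success:
                t_fail = float(sol.t[-1]) if sol.t.size else float(a)
                raise SimulationError(
                    f"ODE solver failed at t={t_fail:.4g} d: {sol.message}", t_fail
                )
            ts, states_seg = sol.t, sol.y.T
        for ti, yi in zip(ts, states_seg):
            if ti > t_grid[-1] + 1e-12:
                continue
            out_t.append(float(ti))
            out_x.append((yi[0], yi[1]))
        x = states_seg[-1]

    out_t = np.asarray(out_t)
    keep = np.isin(out_t, t_grid)
    out_t = out_t[keep]
    states = np.asarray(out_x)[keep]
    # round-off guard: the model is positively invariant, so anything below
    # zero at this point is solver noise on the scale of the tolerances
    if np.any(states < -max(1e-9, 1e3 * atol)):
        raise SimulationError(f"state went negative beyond tolerance: min={states.min():.3e}")
    states = np.maximum(states, 0.0)

    u_grid = np.array([doses.dose_at(t) for t in out_t])
    return Trajectory(
        t=out_t,
        x1=states[:, 0],
        x2=states[:, 1],
        d1=np.asarray(d1f(out_t), dtype=float),
        d2=np.asarray(d2f(out_t), dtype=float),
        u=u_grid,
    )


def steady_state(
    params: PatientParameters, u: float, d1: float, d2: float
) -> ModelState:
    """Closed-form equilibrium under constant inputs.

    x1* = u (the intrathyroidal MMI mass equilibrates at the daily dose) and
    x2* is the synthesis/degradation balance evaluated at x1 = u.
    """
    for name, v in [("u", u), ("d1", d1), ("d2", d2)]:
        if not np.isfinite(v) or v < 0:
            raise ValidationError(f"{name} must be finite and non-negative, got {v!r}")
    _, dx2 = _rhs(u, 0.0, d1, d2, u, params)
    return ModelState(float(u), float(dx2 / params.kf))


def exogenous_from_record(record: PatientRecord) -> ExogenousCourse:
    """Piecewise-linear TRAb/TSH courses through the measured appointments.

    Missing values are skipped as breakpoints; outside the first/last
    measurement the boundary value is held constant.  A record with no TRAb
    measurement at all yields d1 = 0 with a warning (the simulation then
    runs on TSH stimulation only).
    """
    m_trab = ~np.isnan(record.trab)
    m_tsh = ~np.isnan(record.tsh)
    if not np.any(m_tsh):
        raise ValidationError("record carries no TSH measurement")
    if np.any(m_trab):
        d1 = PiecewiseLinear(record.days[m_trab], record.trab[m_trab])
    else:
        logger.warning("record has no TRAb measurements; assuming d1 = 0 throughout")
        d1 = PiecewiseLinear.constant(0.0)
    d2 = PiecewiseLinear(record.days[m_tsh], record.tsh[m_tsh])
    return ExogenousCourse(d1=d1, d2=d2)
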