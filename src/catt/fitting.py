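"""Patient-specific parameter identification by box-constrained least squares.

The eight model constants are estimated from an appointment series by
minimising the sum of squared deviations between measured FT4 and the
simulated FT4 at the appointment days.  The model is practically
non-identifiable in several parameters (ka2/kT2/kT3 trade off against each
other), so the quantity the fit is judged on — and the only one the
contracts here promise — is the recovered FT4 *trajectory*, not the
parameter vector itself.

Parameters are optimised on log scale: they span up to three orders of
magnitude and the log transform makes the box roughly isotropic.
Multi-start is handled by Latin-hypercube sampling of the log box; every
start point is screened with a single objective evaluation and only the
most promising ones are polished with a bound-constrained trust-region
least-squares run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import (
    DoseSchedule,
    ExogenousCourse,
    InsufficientDataError,
    ModelState,
    ParameterBounds,
    PatientParameters,
    PatientRecord,
    SimulationError,
    ValidationError,
    exogenous_from_record,
    simulate,
    steady_state,
)

logger = logging.getLogger("catt")

__all__ = ["FitOptions", "FitResult", "FitError", "objective", "fit_parameters", "predict_ft4"]

#: Untreated steady-state FT4 above this value (pmol/L), evaluated at the
#: record's highest observed TRAb, marks a physiologically implausible fit:
#: admissible parameters must not allow runaway FT4 excursions.
FT4_PLAUSIBILITY_CAP = 150.0


class FitError(RuntimeError):
    """Every optimisation start failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class FitOptions:
    """Configuration of the multi-start least-squares identification."""

    bounds: ParameterBounds = field(default_factory=ParameterBounds)
    n_starts: int = 32  # Latin-hypercube start points in the log box
    n_refine: int = 5  # best starts polished by least_squares
    seed: int = 0
    rtol: float = 1e-6  # solver tolerances inside the fitting loop
    atol: float = 1e-8
    max_nfev: int = 80  # trust-region iteration budget per polish
    ftol: float = 1e-9
    xtol: float = 1e-9
    # the winning candidate gets one deep refinement with a generous budget
    final_max_nfev: int = 300
    final_tol: float = 1e-12
    # polishing stops once a candidate's SSR is numerically zero — further
    # starts cannot do better than an exact interpolation of the data
    early_stop_ssr: float = 1e-6
    # treatment-naive patients start with an MMI-free thyroid (x1(0) = 0);
    # patients already on MMI at entry are assumed at the pre-entry
    # intrathyroidal steady state x1(0) = first prescribed dose
    treatment_naive: bool = False

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValidationError("n_starts must be >= 1")
        if not (1 <= self.n_refine <= self.n_starts):
            raise ValidationError("need 1 <= n_refine <= n_starts")


@dataclass(frozen=True)
class FitResult:
    """Outcome of :func:`fit_parameters`."""

    params: PatientParameters
    objective: float  # sum of squared FT4 residuals, (pmol/L)^2
    residuals: np.ndarray  # measured - simulated FT4 per FT4 appointment
    converged: bool
    start_index: int  # which multi-start produced the winner
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "objective": float(self.objective),
            "residuals": [float(r) for r in self.residuals],
            "converged": bool(self.converged),
            "start_index": int(self.start_index),
            "message": self.message,
        }


def default_initial_state(record: PatientRecord, treatment_naive: bool = False) -> ModelState:
    """Initial condition convention for fitting a record.

    x2(0) is the first measured FT4.  x1(0) equals the first prescribed
    dose for a patient already on MMI at entry (assumed to have reached the
    intrathyroidal steady state x1* = u of the pre-entry regimen); a
    treatment-naive patient starts with an MMI-free thyroid, x1(0) = 0.
    """
    x1 = 0.0 if treatment_naive else float(record.dose[0])
    return ModelState(x1, record.first_ft4())


def _ft4_residuals(
    params: PatientParameters,
    record: PatientRecord,
    exo: ExogenousCourse,
    init: ModelState,
    rtol: float,
    atol: float,
) -> np.ndarray:
    days, ft4 = record.ft4_points()
    t_grid = np.unique(np.concatenate([[0.0], days]))
    traj = simulate(
        params, record.dose_schedule(), exo, init, t_grid, rtol=rtol, atol=atol
    )
    sim = np.interp(days, traj.t, traj.x2)
    return ft4 - sim


def objective(
    params: PatientParameters,
    record: PatientRecord,
    *,
    init: ModelState | None = None,
    treatment_naive: bool = False,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> float:
    """Sum of squared FT4 residuals of the simulated record, (pmol/L)^2.

    The record's prescribed doses drive the simulation; TRAb and TSH are
    linearly interpolated between their measured appointments.
    """
    if record.n_ft4 < 2:
        raise InsufficientDataError(
            f"objective needs >= 2 FT4 measurements, record has {record.n_ft4}"
        )
    if init is None:
        init = default_initial_state(record, treatment_naive)
    exo = exogenous_from_record(record)
    r = _ft4_residuals(params, record, exo, init, rtol, atol)
    return float(np.dot(r, r))


def fit_parameters(record: PatientRecord, options: FitOptions | None = None) -> FitResult:
    """Identify the eight patient constants from an appointment series.

    Latin-hypercube multi-start over the log-transformed admissible box,
    screening by objective value, polish of the best starts with
    bound-constrained least squares.  A candidate whose untreated
    steady-state FT4 at the record's highest TRAb exceeds the plausibility
    cap is rejected in favour of the best plausible one.

    Deterministic given ``(record, options.seed)``.
    """
    options = options or FitOptions()
    if record.n_ft4 < 4:
        raise InsufficientDataError(
            f"fitting 8 parameters needs >= 4 FT4 measurements, record has {record.n_ft4}"
        )
    exo = exogenous_from_record(record)
    init = default_initial_state(record, options.treatment_naive)
    lo, hi = options.bounds.lower, options.bounds.upper
    log_lo, log_hi = np.log(lo), np.log(hi)

    sampler = qmc.LatinHypercube(d=8, seed=options.seed)
    unit = sampler.random(options.n_starts)
    starts = log_lo + unit * (log_hi - log_lo)

    def residuals_log(theta: np.ndarray) -> np.ndarray:
        p = PatientParameters.from_array(np.exp(theta))
        return _ft4_residuals(p, record, exo, init, options.rtol, options.atol)

    # screening pass: one objective evaluation per start
    screen = np.full(options.n_starts, np.inf)
    for i, th in enumerate(starts):
        try:
            r = residuals_log(th)
            screen[i] = float(np.dot(r, r))
        except SimulationError:
            continue
    order = np.argsort(screen)
    if not np.isfinite(screen[order[0]]):
        raise FitError("every start point failed to simulate", diagnostics=list(screen))

    candidates = []  # (ssr, params, residuals, start_index, success)
    diagnostics = []
    for i in order[: options.n_refine]:
        if not np.isfinite(screen[i]):
            continue
        try:
            sol = least_squares(
                residuals_log,
                starts[i],
                bounds=(log_lo, log_hi),
                method="trf",
                x_scale="jac",
                max_nfev=options.max_nfev,
                ftol=options.ftol,
                xtol=options.xtol,
            )
        except SimulationError as err:
            diagnostics.append((int(i), f"simulation failure: {err}"))
            continue
        p = PatientParameters.from_array(np.exp(sol.x))
        ssr = float(2 * sol.cost)
        candidates.append((ssr, p, sol.fun.copy(), int(i), bool(sol.success)))
        diagnostics.append((int(i), f"ssr={ssr:.6g} success={sol.success}"))
        if ssr < options.early_stop_ssr:
            break
    if not candidates:
        raise FitError("all polished starts failed", diagnostics=diagnostics)

    candidates.sort(key=lambda c: c[0])

    def plausible(p: PatientParameters) -> bool:
        peak = record.max_trab()
        return steady_state(p, 0.0, peak, 0.0).x2 <= FT4_PLAUSIBILITY_CAP

    chosen = next((c for c in candidates if plausible(c[1])), None)
    if chosen is not None:
        # deep refinement of the winner: the screening polishes run on a
        # tight budget, so finish the best one off properly
        try:
            sol = least_squares(
                residuals_log,
                np.log(chosen[1].to_array()),
                bounds=(log_lo, log_hi),
                method="trf",
                max_nfev=options.final_max_nfev,
                ftol=options.final_tol,
                xtol=options.final_tol,
            )
            p2 = PatientParameters.from_array(np.exp(sol.x))
            ssr2 = float(2 * sol.cost)
            if ssr2 <= chosen[0] and plausible(p2):
                chosen = (ssr2, p2, sol.fun.copy(), chosen[3], True)
        except SimulationError:
            pass
    message = ""
    converged = True
    if chosen is None:
        chosen = candidates[0]
        converged = False
        message = (
            "no candidate satisfies the untreated steady-state FT4 plausibility "
            f"cap ({FT4_PLAUSIBILITY_CAP} pmol/L); returning best implausible fit"
        )
        warnings.warn(message)
    ssr, p, res, start_idx, success = chosen
    # measured - simulated convention for reported residuals
    res = np.asarray(res)
    if record.n_ft4 < 8:
        converged = False
        msg = f"only {record.n_ft4} FT4 points for 8 parameters; fit is under-determined"
        message = (message + "; " + msg) if message else msg
        warnings.warn(msg)
    elif not success:
        converged = False
        message = (message + "; " if message else "") + "optimizer hit its evaluation budget"
    return FitResult(
        params=p,
        objective=ssr,
        residuals=res,
        converged=converged,
        start_index=start_idx,
        message=message,
    )


def predict_ft4(
    fit: FitResult,
    record: PatientRecord,
    future_days: Sequence[float],
    future_doses: DoseSchedule,
    future_exo: ExogenousCourse,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Forward-simulate fitted parameters beyond the record, returning FT4.

    The fitted record is first re-simulated to obtain the model state at the
    last appointment; the future segment then runs under the supplied dose
    schedule and exogenous courses.
    """
    future_days = np.atleast_1d(np.asarray(future_days, dtype=float))
    t_end = float(record.days[-1])
    if np.any(future_days <= t_end):
        raise ValidationError(
            f"future days must lie after the last fitted appointment (day {t_end})"
        )
    exo = exogenous_from_record(record)
    init = default_initial_state(record)
    hist = simulate(
        fit.params, record.dose_schedule(), exo, init, record.days, rtol=rtol, atol=atol
    )
    t_grid = np.concatenate([[t_end], np.sort(future_days)])
    traj = simulate(
        fit.params, future_doses, future_exo, hist.final_state(), t_grid, rtol=rtol, atol=atol
    )
    return np.interp(future_days, traj.t, traj.x2)
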