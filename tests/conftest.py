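import numpy as np
import pytest

from catt import (
    DoseSchedule,
    ExogenousCourse,
    ModelState,
    ParameterBounds,
    PatientParameters,
    PatientRecord,
    PiecewiseLinear,
    simulate,
    steady_state,
)


@pytest.fixture(scope="session")
def bounds() -> ParameterBounds:
    return ParameterBounds()


@pytest.fixture(scope="session")
def midpoint_params(bounds) -> PatientParameters:
    """Parameters at the centre of every admissible interval."""
    return bounds.midpoint()


@pytest.fixture(scope="session")
def nominal_params() -> PatientParameters:
    """A plain, well-conditioned parameter set for generic dynamics tests."""
    return PatientParameters(
        ka1=15.0, ka2=250.0, kT1=5.7, kT2=250.0, kT3=25.0, kf=0.1155, kd=0.6931, km=100.0
    )


def make_synthetic_record(params, days, doses, trab, tsh=None, init=None):
    """Simulate a record whose FT4 column is the exact model output.

    Uses the on-treatment initial-state convention unless ``init`` is given.
    Returns (record, init_used).
    """
    days = np.asarray(days, dtype=float)
    doses = np.asarray(doses, dtype=float)
    trab = np.asarray(trab, dtype=float)
    tsh = np.zeros_like(days) if tsh is None else np.asarray(tsh, dtype=float)
    exo = ExogenousCourse(
        d1=PiecewiseLinear(days, trab),
        d2=PiecewiseLinear(days, tsh) if np.any(tsh > 0) else PiecewiseLinear.constant(0.0),
    )
    if init is None:
        x2_0 = steady_state(params, 0.0, float(trab[0]), float(tsh[0])).x2
        init = ModelState(float(doses[0]), x2_0)
    traj = simulate(params, DoseSchedule(days, doses), exo, init, days)
    record = PatientRecord(days, tsh, traj.x2.copy(), trab, doses)
    return record, init
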