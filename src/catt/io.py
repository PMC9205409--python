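"""On-disk formats: patient record CSV, trajectory CSV, cohort JSON and
treatment-course CSV + metadata JSON.

All formats are plain text, comma-separated, UTF-8, dot decimal.  Days are
floats relative to the first visit.  Every artifact written here embeds a
``schema_version`` and the seed/configuration needed to regenerate it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortConfig, VirtualPatient
from .control import ControllerConfig, TreatmentCourse
from .model import PatientRecord, Trajectory, ValidationError

logger = logging.getLogger("catt")

__all__ = [
    "SCHEMA_VERSION",
    "read_patient_record",
    "write_patient_record",
    "write_trajectory",
    "write_cohort",
    "read_cohort",
    "write_course",
    "read_course",
]

SCHEMA_VERSION = 1

RECORD_COLUMNS = ["day", "tsh_uU_per_mL", "ft4_pmol_per_L", "trab_U_per_L", "mmi_mg_per_day"]
COURSE_COLUMNS = ["day", "ft4_pmol_per_L", "dose_mg_per_day", "tsh_uU_per_mL", "trab_U_per_L"]
FLOAT_FMT = "%.12g"


def read_patient_record(path: str | Path) -> PatientRecord:
    """Read and validate an appointment-series CSV.

    Header must be exactly ``day,tsh_uU_per_mL,ft4_pmol_per_L,trab_U_per_L,
    mmi_mg_per_day``; empty cells mark missing measurements.  Errors name
    the offending data row (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != RECORD_COLUMNS:
        raise ValidationError(
            f"{path}: header must be {','.join(RECORD_COLUMNS)}, got {','.join(df.columns)}"
        )
    if df.empty:
        raise ValidationError(f"{path}: record is empty")
    days = df["day"].to_numpy(dtype=float)
    if np.isnan(days).any():
        row = int(np.flatnonzero(np.isnan(days))[0]) + 1
        raise ValidationError(f"{path}: missing day in row {row}")
    bad = np.flatnonzero(np.diff(days) <= 0)
    if bad.size:
        raise ValidationError(
            f"{path}: appointment days must be strictly increasing; row {int(bad[0]) + 2} "
            f"(day {days[bad[0] + 1]:g}) does not follow day {days[bad[0]]:g}"
        )
    for col in RECORD_COLUMNS[1:]:
        v = df[col].to_numpy(dtype=float)
        neg = np.flatnonzero(v < 0)
        if neg.size:
            raise ValidationError(f"{path}: negative {col} in row {int(neg[0]) + 1}")
    try:
        return PatientRecord(
            days=days,
            tsh=df["tsh_uU_per_mL"].to_numpy(dtype=float),
            ft4=df["ft4_pmol_per_L"].to_numpy(dtype=float),
            trab=df["trab_U_per_L"].to_numpy(dtype=float),
            dose=df["mmi_mg_per_day"].to_numpy(dtype=float),
        )
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from err


def write_patient_record(record: PatientRecord, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "day": record.days,
            "tsh_uU_per_mL": record.tsh,
            "ft4_pmol_per_L": record.ft4,
            "trab_U_per_L": record.trab,
            "mmi_mg_per_day": record.dose,
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def write_cohort(patients: Sequence[VirtualPatient], config: CohortConfig, path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "size": config.size,
        "probabilities": list(config.probabilities),
        "ft4_floor": config.ft4_floor,
        "ft4_cap": config.ft4_cap,
        "horizon": config.horizon,
        "archetype_counts": {
            a: sum(1 for p in patients if p.pattern.archetype == a)
            for a in ("persistent", "disappearing", "complex")
        },
        "patients": [p.to_dict() for p in patients],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_cohort(path: str | Path) -> list[VirtualPatient]:
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValidationError(
            f"{path}: cohort schema version {version!r} not supported (expected {SCHEMA_VERSION})"
        )
    return [VirtualPatient.from_dict(d) for d in payload["patients"]]


def write_course(course: TreatmentCourse, directory: str | Path) -> tuple[Path, Path]:
    """Write a treatment course as ``<id>.csv`` plus ``<id>.meta.json``.

    Returns the two paths.  The metadata JSON carries the controller
    configuration (gains, limits), seed and schema version, enough to
    regenerate the course from the matching virtual patient.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{course.patient_id}.csv"
    meta_path = directory / f"{course.patient_id}.meta.json"
    pd.DataFrame(
        {
            "day": course.days,
            "ft4_pmol_per_L": course.ft4,
            "dose_mg_per_day": course.doses,
            "tsh_uU_per_mL": course.tsh,
            "trab_U_per_L": course.trab,
        }
    ).to_csv(csv_path, index=False, float_format=FLOAT_FMT)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "patient_id": course.patient_id,
        "controller": course.config.to_dict(),
        "seed": course.seed,
    }
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return csv_path, meta_path


def read_course(csv_path: str | Path) -> TreatmentCourse:
    """Round-trip counterpart of :func:`write_course`."""
    csv_path = Path(csv_path)
    meta_path = csv_path.with_suffix("").with_suffix(".meta.json") if csv_path.suffix == ".csv" else None
    meta_path = csv_path.parent / f"{csv_path.stem}.meta.json"
    if not meta_path.exists():
        raise ValidationError(f"missing metadata file {meta_path}")
    meta = json.loads(meta_path.read_text())
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValidationError(
            f"{meta_path}: course schema version {version!r} not supported "
            f"(expected {SCHEMA_VERSION})"
        )
    df = pd.read_csv(csv_path)
    if list(df.columns) != COURSE_COLUMNS:
        raise ValidationError(f"{csv_path}: unexpected columns {list(df.columns)}")
    return TreatmentCourse(
        patient_id=meta["patient_id"],
        days=df["day"].to_numpy(dtype=float),
        ft4=df["ft4_pmol_per_L"].to_numpy(dtype=float),
        doses=df["dose_mg_per_day"].to_numpy(dtype=float),
        tsh=df["tsh_uU_per_mL"].to_numpy(dtype=float),
        trab=df["trab_U_per_L"].to_numpy(dtype=float),
        trajectory=None,
        config=ControllerConfig.from_dict(meta["controller"]),
        seed=meta["seed"],
    )
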