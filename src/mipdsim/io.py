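"""Plain-CSV interchange for patients, dosing histories and TDM levels.

Three tables with a JSON sidecar documenting columns, units and the time
convention (all times are real-valued hours from the regimen origin — the
start of the first infusion; calendar-time conversion is the caller's
responsibility):

- ``patients.csv``: id, age_months, weight_kg, height_cm, scr_mg_dl, sex,
  group, drug
- ``doses.csv``: patient_id, start_time_h, amount_mg, infusion_duration_h
- ``levels.csv``: patient_id, time_h, concentration_mg_L, below_loq

Row-level validation errors name the file and row so malformed inputs
fail loudly rather than propagating silently.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .forecasting import Observation
from .models import DoseEvent, PatientCovariates, Regimen

__all__ = ["write_cohort", "load_patient_data", "SCHEMA"]

SCHEMA = {
    "time_origin": "hours from the start of each patient's first infusion",
    "patients.csv": {
        "id": "patient identifier",
        "age_months": "age, months",
        "weight_kg": "body weight, kg",
        "height_cm": "height, cm (optional, may be empty)",
        "scr_mg_dl": "serum creatinine, mg/dL",
        "sex": "male | female",
        "group": "MIPD | SoC",
        "drug": "vancomycin | amikacin",
    },
    "doses.csv": {
        "patient_id": "patient identifier",
        "start_time_h": "infusion start, h",
        "amount_mg": "dose amount, mg",
        "infusion_duration_h": "infusion duration, h",
    },
    "levels.csv": {
        "patient_id": "patient identifier",
        "time_h": "sampling time, h",
        "concentration_mg_L": "measured concentration, mg/L",
        "below_loq": "True when below the limit of quantification",
    },
}

_REQUIRED = {
    "patients.csv": [
        "id", "age_months", "weight_kg", "height_cm", "scr_mg_dl", "sex", "group", "drug",
    ],
    "doses.csv": ["patient_id", "start_time_h", "amount_mg", "infusion_duration_h"],
    "levels.csv": ["patient_id", "time_h", "concentration_mg_L", "below_loq"],
}


def write_cohort(patients, out_dir: str | Path) -> None:
    """Write a list of VirtualPatient records to the three-table schema."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prow, drow, lrow = [], [], []
    for p in patients:
        c = p.covariates
        prow.append(
            {
                "id": p.id,
                "age_months": c.age_months,
                "weight_kg": c.weight_kg,
                "height_cm": c.height_cm,
                "scr_mg_dl": c.scr_mg_dl,
                "sex": c.sex,
                "group": p.group,
                "drug": p.drug,
            }
        )
        for e in p.regimen.events:
            drow.append(
                {
                    "patient_id": p.id,
                    "start_time_h": e.start_time_h,
                    "amount_mg": e.amount_mg,
                    "infusion_duration_h": e.infusion_duration_h,
                }
            )
        for o in p.observations:
            lrow.append(
                {
                    "patient_id": p.id,
                    "time_h": o.time_h,
                    "concentration_mg_L": o.concentration_mg_L,
                    "below_loq": o.below_loq,
                }
            )
    pd.DataFrame(prow).to_csv(out / "patients.csv", index=False)
    pd.DataFrame(drow).to_csv(out / "doses.csv", index=False)
    pd.DataFrame(lrow).to_csv(out / "levels.csv", index=False)
    (out / "schema.json").write_text(json.dumps(SCHEMA, indent=2) + "\n")


def _check_columns(df: pd.DataFrame, name: str) -> None:
    missing = set(_REQUIRED[name]) - set(df.columns)
    if missing:
        raise ValueError(f"{name}: missing columns {sorted(missing)}")
    unknown = set(df.columns) - set(_REQUIRED[name])
    if unknown:
        raise ValueError(f"{name}: unknown columns {sorted(unknown)}")


def load_patient_data(in_dir: str | Path):
    """Load and validate the three tables.

    Returns ``(covariates, meta, regimens, observations)`` — dicts keyed
    by patient id; ``meta`` holds group and drug labels.  Any row that
    violates a domain invariant is rejected with the file and row number.
    """
    in_dir = Path(in_dir)
    patients_df = pd.read_csv(in_dir / "patients.csv")
    doses_df = pd.read_csv(in_dir / "doses.csv")
    levels_path = in_dir / "levels.csv"
    levels_df = (
        pd.read_csv(levels_path)
        if levels_path.exists()
        else pd.DataFrame(columns=_REQUIRED["levels.csv"])
    )
    _check_columns(patients_df, "patients.csv")
    _check_columns(doses_df, "doses.csv")
    _check_columns(levels_df, "levels.csv")

    covariates: dict[str, PatientCovariates] = {}
    meta: dict[str, dict] = {}
    for i, row in patients_df.iterrows():
        try:
            height = None if pd.isna(row["height_cm"]) else float(row["height_cm"])
            covariates[str(row["id"])] = PatientCovariates(
                age_months=float(row["age_months"]),
                weight_kg=float(row["weight_kg"]),
                scr_mg_dl=float(row["scr_mg_dl"]),
                sex=str(row["sex"]),
                height_cm=height,
            )
            meta[str(row["id"])] = {"group": str(row["group"]), "drug": str(row["drug"])}
        except ValueError as exc:
            raise ValueError(f"patients.csv row {i + 2}: {exc}") from exc

    regimens: dict[str, Regimen] = {}
    for pid, sub in doses_df.groupby("patient_id"):
        pid = str(pid)
        if pid not in covariates:
            raise ValueError(f"doses.csv: unknown patient_id {pid!r}")
        events = []
        for i, row in sub.iterrows():
            try:
                events.append(
                    DoseEvent(
                        start_time_h=float(row["start_time_h"]),
                        amount_mg=float(row["amount_mg"]),
                        infusion_duration_h=float(row["infusion_duration_h"]),
                        drug=meta[pid]["drug"],
                    )
                )
            except ValueError as exc:
                raise ValueError(f"doses.csv row {i + 2}: {exc}") from exc
        try:
            regimens[pid] = Regimen(tuple(sorted(events, key=lambda e: e.start_time_h)))
        except ValueError as exc:
            raise ValueError(f"doses.csv patient {pid!r}: {exc}") from exc

    observations: dict[str, list[Observation]] = {pid: [] for pid in covariates}
    for i, row in levels_df.iterrows():
        pid = str(row["patient_id"])
        if pid not in covariates:
            raise ValueError(f"levels.csv row {i + 2}: unknown patient_id {pid!r}")
        try:
            observations[pid].append(
                Observation(
                    time_h=float(row["time_h"]),
                    concentration_mg_L=float(row["concentration_mg_L"]),
                    drug=meta[pid]["drug"],
                    below_loq=bool(row["below_loq"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"levels.csv row {i + 2}: {exc}") from exc

    return covariates, meta, regimens, observations
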