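"""Flat-file cohort ingest and export.

Five CSV tables make a cohort::

    patients.csv     patient_id,birth_date,sex,race_ethnicity,zip_code
    labs.csv         patient_id,date,analyte,value,units,fasting
    vitals.csv       patient_id,date,systolic,diastolic,height_cm
    diagnoses.csv    patient_id,date,code_system,code,setting
    medications.csv  patient_id,date,drug_name

Dates are ISO-8601 (date-only). Glucose rows carry analyte ``glucose``
plus a boolean ``fasting`` flag which is resolved at ingest into
``glucose_fasting`` / ``glucose_random``; the distinction is never
inferred downstream. Rows that fail validation are quarantined into a
rejects list (and ``rejects.csv``) with a reason — never silently
dropped: for every table, rows_in == rows_loaded + rows_rejected.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import pandas as pd

from .config import CriteriaConfig, normalize_code
from .model import (
    CANONICAL_UNITS,
    Analyte,
    CodeSystem,
    DiagnosisEvent,
    LabResult,
    LongitudinalRecord,
    MedicationOrder,
    PatientDemographics,
    Reject,
    Setting,
    Sex,
    VitalSign,
)

TABLE_FILES = {
    "patients": "patients.csv",
    "labs": "labs.csv",
    "vitals": "vitals.csv",
    "diagnoses": "diagnoses.csv",
    "medications": "medications.csv",
}

REQUIRED_COLUMNS = {
    "patients": ["patient_id", "birth_date", "sex"],
    "labs": ["patient_id", "date", "analyte", "value", "units"],
    "vitals": ["patient_id", "date"],
    "diagnoses": ["patient_id", "date", "code_system", "code", "setting"],
    "medications": ["patient_id", "date", "drug_name"],
}

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", ""}


class SchemaError(ValueError):
    """A table is missing a required column — fatal, not row-level."""


def _parse_date(raw) -> datetime.date:
    return datetime.date.fromisoformat(str(raw).strip())


def _load_table(path: Path, table: str) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"{table} table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table missing required column(s): {', '.join(missing)}")
    return df


def normalize_units(analyte: Analyte, value: float, units: str, config: CriteriaConfig) -> float:
    """Convert ``value`` from declared source units into the analyte's
    canonical unit using the configured unit map.

    Raises ``KeyError`` for a source unit absent from the map (callers
    turn this into a row-level reject).
    """
    table = config.units.conversions.get(analyte.value, {})
    units = units.strip()
    if units not in table:
        raise KeyError(f"unknown unit {units!r} for analyte {analyte.value}")
    return value * table[units]


def read_cohort(
    path: str | Path, config: CriteriaConfig | None = None
) -> tuple[dict[str, LongitudinalRecord], list[Reject]]:
    """Read the five cohort tables under ``path`` into one
    :class:`LongitudinalRecord` per distinct patient, date-sorted.

    Returns ``(records, rejects)``. Row numbering in rejects counts the
    header as line 1, so the first data row is line 2. Identical
    duplicate rows are quarantined with reason ``duplicate row``;
    same-day rows that differ in value are all kept as distinct
    observations.
    """
    config = config or CriteriaConfig()
    path = Path(path)
    rejects: list[Reject] = []
    records: dict[str, LongitudinalRecord] = {}

    pat_df = _load_table(path / TABLE_FILES["patients"], "patients")
    for idx, row in pat_df.iterrows():
        line = int(idx) + 2
        pid = str(row["patient_id"]).strip()
        if not pid:
            rejects.append(Reject("patients", line, "empty patient_id"))
            continue
        if pid in records:
            rejects.append(Reject("patients", line, f"duplicate patient_id {pid}"))
            continue
        try:
            birth = _parse_date(row["birth_date"])
        except ValueError:
            rejects.append(Reject("patients", line, f"unparseable birth_date {row['birth_date']!r}"))
            continue
        try:
            sex = Sex(str(row["sex"]).strip().lower() or "unknown")
        except ValueError:
            rejects.append(Reject("patients", line, f"unknown sex {row['sex']!r}"))
            continue
        zip_code = str(row.get("zip_code", "")).strip() or None
        race = str(row.get("race_ethnicity", "")).strip() or "unknown"
        records[pid] = LongitudinalRecord(
            demographics=PatientDemographics(
                patient_id=pid, birth_date=birth, sex=sex,
                race_ethnicity=race, zip_code=zip_code,
            )
        )

    def _common(table: str, row, line: int):
        """Validate patient linkage + date; return (record, date) or None."""
        pid = str(row["patient_id"]).strip()
        rec = records.get(pid)
        if rec is None:
            rejects.append(Reject(table, line, f"unknown patient_id {pid!r}"))
            return None
        try:
            date = _parse_date(row["date"])
        except ValueError:
            rejects.append(Reject(table, line, f"unparseable date {row['date']!r}"))
            return None
        if date < rec.demographics.birth_date:
            rejects.append(Reject(table, line, "event date precedes birth_date"))
            return None
        return rec, date

    # --- labs ---
    seen: set = set()
    for idx, row in _load_table(path / TABLE_FILES["labs"], "labs").iterrows():
        line = int(idx) + 2
        common = _common("labs", row, line)
        if common is None:
            continue
        rec, date = common
        raw_analyte = str(row["analyte"]).strip().lower()
        if raw_analyte == "glucose":
            fasting = str(row.get("fasting", "")).strip().lower()
            if fasting in _TRUTHY:
                raw_analyte = "glucose_fasting"
            elif fasting in _FALSY:
                raw_analyte = "glucose_random"
            else:
                rejects.append(Reject("labs", line, f"ambiguous fasting flag {fasting!r}"))
                continue
        try:
            analyte = Analyte(raw_analyte)
        except ValueError:
            rejects.append(Reject("labs", line, f"unknown analyte {raw_analyte!r}"))
            continue
        try:
            value = float(row["value"])
        except ValueError:
            rejects.append(Reject("labs", line, f"unparseable value {row['value']!r}"))
            continue
        if value < 0:
            rejects.append(Reject("labs", line, f"negative value {value} for {analyte.value}"))
            continue
        try:
            value = normalize_units(analyte, value, str(row["units"]), config)
        except KeyError as exc:
            rejects.append(Reject("labs", line, str(exc.args[0])))
            continue
        lab = LabResult(rec.patient_id, date, analyte, value, CANONICAL_UNITS[analyte])
        if lab.key() in seen:
            # exact duplicate observation: quarantined with a reason so that
            # rows_in == rows_loaded + rows_rejected holds per table
            rejects.append(Reject("labs", line, "duplicate row"))
            continue
        seen.add(lab.key())
        rec.labs.append(lab)

    # --- vitals ---
    seen = set()
    for idx, row in _load_table(path / TABLE_FILES["vitals"], "vitals").iterrows():
        line = int(idx) + 2
        common = _common("vitals", row, line)
        if common is None:
            continue
        rec, date = common

        def _optional_float(col: str):
            raw = str(row.get(col, "")).strip()
            if raw == "":
                return None
            return float(raw)

        try:
            sbp, dbp, height = (_optional_float(c) for c in ("systolic", "diastolic", "height_cm"))
        except ValueError:
            rejects.append(Reject("vitals", line, "unparseable numeric value"))
            continue
        if sbp is None and dbp is None and height is None:
            rejects.append(Reject("vitals", line, "empty vitals row"))
            continue
        if any(v is not None and v <= 0 for v in (sbp, dbp, height)):
            rejects.append(Reject("vitals", line, "non-positive measurement"))
            continue
        if sbp is not None and dbp is not None and sbp <= dbp:
            rejects.append(Reject("vitals", line, f"systolic {sbp} <= diastolic {dbp}"))
            continue
        vital = VitalSign(rec.patient_id, date, sbp, dbp, height)
        if vital.key() in seen:
            rejects.append(Reject("vitals", line, "duplicate row"))
            continue
        seen.add(vital.key())
        rec.vitals.append(vital)

    # --- diagnoses ---
    seen = set()
    for idx, row in _load_table(path / TABLE_FILES["diagnoses"], "diagnoses").iterrows():
        line = int(idx) + 2
        common = _common("diagnoses", row, line)
        if common is None:
            continue
        rec, date = common
        try:
            system = CodeSystem(str(row["code_system"]).strip().upper())
        except ValueError:
            rejects.append(Reject("diagnoses", line, f"unknown code_system {row['code_system']!r}"))
            continue
        code = normalize_code(str(row["code"]))
        if not code:
            rejects.append(Reject("diagnoses", line, "empty code"))
            continue
        try:
            setting = Setting(str(row["setting"]).strip().lower())
        except ValueError:
            rejects.append(Reject("diagnoses", line, f"unknown setting {row['setting']!r}"))
            continue
        dx = DiagnosisEvent(rec.patient_id, date, system, code, setting)
        if dx.key() in seen:
            rejects.append(Reject("diagnoses", line, "duplicate row"))
            continue
        seen.add(dx.key())
        rec.diagnoses.append(dx)

    # --- medications ---
    seen = set()
    for idx, row in _load_table(path / TABLE_FILES["medications"], "medications").iterrows():
        line = int(idx) + 2
        common = _common("medications", row, line)
        if common is None:
            continue
        rec, date = common
        drug = str(row["drug_name"]).strip()
        if not drug:
            rejects.append(Reject("medications", line, "empty drug_name"))
            continue
        order = MedicationOrder(rec.patient_id, date, drug)
        if order.key() in seen:
            rejects.append(Reject("medications", line, "duplicate row"))
            continue
        seen.add(order.key())
        rec.medications.append(order)

    for rec in records.values():
        rec.sort_events()
    return records, rejects


def write_cohort(records: dict[str, LongitudinalRecord], path: str | Path) -> None:
    """Write a cohort back to the five CSV tables (patients sorted by id;
    events in their stored date order)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pids = sorted(records)

    pat_rows, lab_rows, vit_rows, dx_rows, med_rows = [], [], [], [], []
    for pid in pids:
        rec = records[pid]
        d = rec.demographics
        pat_rows.append(
            dict(patient_id=pid, birth_date=d.birth_date.isoformat(), sex=d.sex.value,
                 race_ethnicity=d.race_ethnicity, zip_code=d.zip_code or "")
        )
        for lab in rec.labs:
            lab_rows.append(
                dict(patient_id=pid, date=lab.date.isoformat(), analyte=lab.analyte.value,
                     value=repr(lab.value), units=lab.units, fasting="")
            )
        for v in rec.vitals:
            vit_rows.append(
                dict(patient_id=pid, date=v.date.isoformat(),
                     systolic="" if v.systolic is None else repr(v.systolic),
                     diastolic="" if v.diastolic is None else repr(v.diastolic),
                     height_cm="" if v.height_cm is None else repr(v.height_cm))
            )
        for dx in rec.diagnoses:
            dx_rows.append(
                dict(patient_id=pid, date=dx.date.isoformat(), code_system=dx.code_system.value,
                     code=dx.code, setting=dx.setting.value)
            )
        for m in rec.medications:
            med_rows.append(dict(patient_id=pid, date=m.date.isoformat(), drug_name=m.drug_name))

    columns = {
        "patients": ["patient_id", "birth_date", "sex", "race_ethnicity", "zip_code"],
        "labs": ["patient_id", "date", "analyte", "value", "units", "fasting"],
        "vitals": ["patient_id", "date", "systolic", "diastolic", "height_cm"],
        "diagnoses": ["patient_id", "date", "code_system", "code", "setting"],
        "medications": ["patient_id", "date", "drug_name"],
    }
    for table, rows in (
        ("patients", pat_rows), ("labs", lab_rows), ("vitals", vit_rows),
        ("diagnoses", dx_rows), ("medications", med_rows),
    ):
        pd.DataFrame(rows, columns=columns[table]).to_csv(path / TABLE_FILES[table], index=False)


def write_rejects(rejects: list[Reject], path: str | Path) -> None:
    pd.DataFrame(
        [dict(table=r.table, row=r.row, reason=r.reason) for r in rejects],
        columns=["table", "row", "reason"],
    ).to_csv(path, index=False)
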