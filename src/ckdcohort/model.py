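"""Domain types for longitudinal EHR phenotyping.

Every event type is a plain dataclass keyed by an opaque ``patient_id``
and a calendar date (date-only: the qualification rules are expressed in
whole days, so time-of-day is deliberately dropped at ingest). A
:class:`LongitudinalRecord` bundles one patient's demographics with their
date-sorted lab, vital-sign, diagnosis and medication streams and is the
unit of phenotyping.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
from dataclasses import dataclass, field


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Analyte(str, enum.Enum):
    """Laboratory analytes the phenotype rules consume."""

    SERUM_CREATININE = "serum_creatinine"
    EGFR = "egfr"
    UACR = "uacr"
    UPCR = "upcr"
    HBA1C = "hba1c"
    GLUCOSE_RANDOM = "glucose_random"
    GLUCOSE_FASTING = "glucose_fasting"


#: Canonical unit per analyte; ingest normalizes everything to these.
CANONICAL_UNITS: dict[Analyte, str] = {
    Analyte.SERUM_CREATININE: "mg/dL",
    Analyte.EGFR: "mL/min/1.73m2",
    Analyte.UACR: "mg/g",
    Analyte.UPCR: "mg/g",
    Analyte.HBA1C: "%",
    Analyte.GLUCOSE_RANDOM: "mg/dL",
    Analyte.GLUCOSE_FASTING: "mg/dL",
}


class CodeSystem(str, enum.Enum):
    ICD9 = "ICD-9"
    ICD10 = "ICD-10"


class Setting(str, enum.Enum):
    """Encounter setting; the diabetes rule distinguishes the two."""

    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"


class Condition(str, enum.Enum):
    CKD = "ckd"
    HTN = "htn"
    DM = "dm"
    PREDIABETES = "prediabetes"


@dataclass
class PatientDemographics:
    patient_id: str
    birth_date: datetime.date
    sex: Sex = Sex.UNKNOWN
    race_ethnicity: str = "unknown"
    zip_code: str | None = None


@dataclass
class LabResult:
    patient_id: str
    date: datetime.date
    analyte: Analyte
    value: float
    units: str

    def key(self) -> tuple:
        return (self.patient_id, self.date, self.analyte, self.value)


@dataclass
class VitalSign:
    """One vital-sign row. Blood pressures and height are each optional so a
    height-only measurement (needed for pediatric eGFR) is representable."""

    patient_id: str
    date: datetime.date
    systolic: float | None = None
    diastolic: float | None = None
    height_cm: float | None = None

    def key(self) -> tuple:
        return (self.patient_id, self.date, self.systolic, self.diastolic, self.height_cm)


@dataclass
class DiagnosisEvent:
    patient_id: str
    date: datetime.date
    code_system: CodeSystem
    code: str  # normalized: uppercase, dots stripped
    setting: Setting

    def key(self) -> tuple:
        return (self.patient_id, self.date, self.code_system, self.code, self.setting)


@dataclass
class MedicationOrder:
    patient_id: str
    date: datetime.date
    drug_name: str
    therapeutic_class: str | None = None  # filled by classify_medication

    def key(self) -> tuple:
        return (self.patient_id, self.date, self.drug_name)


@dataclass
class LongitudinalRecord:
    """One patient's complete event stream plus demographics.

    Invariants: every event's ``patient_id`` equals
    ``demographics.patient_id`` and each event list is sorted ascending by
    date (ties keep ingest order).
    """

    demographics: PatientDemographics
    labs: list[LabResult] = field(default_factory=list)
    vitals: list[VitalSign] = field(default_factory=list)
    diagnoses: list[DiagnosisEvent] = field(default_factory=list)
    medications: list[MedicationOrder] = field(default_factory=list)

    @property
    def patient_id(self) -> str:
        return self.demographics.patient_id

    def sort_events(self) -> None:
        for stream in (self.labs, self.vitals, self.diagnoses, self.medications):
            stream.sort(key=lambda e: e.date)

    def all_events(self):
        yield from self.labs
        yield from self.vitals
        yield from self.diagnoses
        yield from self.medications


@dataclass
class CriterionResult:
    """Verdict of one condition rule with the evidence that fired it.

    ``pathways`` maps every pathway that fired to its witness-event
    references; ``pathway``/``evidence`` expose the first fired pathway in
    the rule's documented priority order. ``qualifies`` is true iff at
    least one pathway fired.
    """

    condition: str
    qualifies: bool
    pathway: str | None = None
    evidence: list[str] = field(default_factory=list)
    pathways: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.qualifies == bool(self.pathways) or not self.pathways, (
            "qualifies must reflect fired pathways"
        )


@dataclass
class ConditionFlags:
    """Per-patient membership flags. Condition flags are not mutually
    exclusive; any true condition flag implies repository membership."""

    patient_id: str
    in_repository: bool = False
    ckd: bool = False
    htn: bool = False
    dm: bool = False
    prediabetes: bool = False
    pcos_excluded_dm: bool = False

    @property
    def in_registry(self) -> bool:
        return self.ckd or self.htn or self.dm or self.prediabetes

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["in_registry"] = self.in_registry
        return d


@dataclass
class Reject:
    """A quarantined input row: never silently dropped."""

    table: str
    row: int
    reason: str
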