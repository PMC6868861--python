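"""Seeded synthetic EHR cohort generator with per-patient ground truth.

The generator emulates the data classes the phenotype rules consume —
longitudinal serum creatinine (sometimes in µmol/L to exercise unit
normalization), precomputed eGFR, UACR/UPCR, HbA1c, random/fasting
glucose, blood pressures, ICD-coded diagnoses with encounter setting,
and medication orders — and plants *patterns*: event constellations that
satisfy exactly one qualification clause (qualifying patterns), fail
exactly one clause (near-misses, e.g. the right values 89 days apart),
or exercise a special rule (the PCOS-metformin exclusion, the pediatric
Schwartz pathway). Ground truth is defined by construction, from the
clause that was planted — never by running the engine — so
label-recovery is a real test.

The first ``len(PATTERN_LIBRARY)`` patients receive the library patterns
round-robin (values and dates still randomized), guaranteeing full
clause coverage at any cohort size >= the library size for every seed;
remaining patients draw random condition mixes, near-misses or
background-only streams. All background events lie strictly inside
non-qualifying ranges. Identical (generator config, criteria config)
inputs yield byte-identical tables.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .config import CriteriaConfig, EgfrConfig
from .egfr import age_in_years, compute_egfr_ckdepi
from .model import ConditionFlags, Sex


class GeneratorConfig(BaseModel):
    n_patients: int = 1000
    seed: int = 0
    #: target fraction of randomly-assigned patients planted per condition
    prevalence: dict[str, float] = Field(
        default_factory=lambda: {"ckd": 0.12, "htn": 0.35, "dm": 0.15, "prediabetes": 0.20}
    )
    #: fraction planted with a pattern failing exactly one clause
    near_miss_rate: float = 0.15
    pcos_rate: float = 0.02
    pediatric_rate: float = 0.02
    background_events_mean: float = 2.0
    date_start: datetime.date = datetime.date(2006, 1, 1)
    date_end: datetime.date = datetime.date(2017, 12, 31)
    missing_zip_fraction: float = 0.011
    unmapped_zip_fraction: float = 0.01
    malformed_zip_fraction: float = 0.004

    @model_validator(mode="after")
    def _sane(self) -> "GeneratorConfig":
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for name, p in self.prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence[{name}] must be in [0,1]")
        if (self.date_end - self.date_start).days < 1200:
            raise ValueError("date range too short to place temporal-pair patterns")
        return self


def invert_ckdepi(
    target_egfr: float, age: float, sex: Sex, params: EgfrConfig | None = None
) -> float:
    """Serum creatinine (mg/dL) whose CKD-EPI eGFR equals ``target_egfr``,
    by bisection (the equation is strictly decreasing in creatinine)."""
    p = params or EgfrConfig()
    lo, hi = 0.05, 40.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if compute_egfr_ckdepi(mid, age, sex, params=p) > target_egfr:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# per-patient sketch: row accumulator + truth label

_BENIGN_DX = [("ICD-10", "I25"), ("ICD-10", "J45"), ("ICD-10", "M54"), ("ICD-9", "7242")]
_BENIGN_MEDS = [
    "atorvastatin 20 mg",
    "levothyroxine 50 mcg",
    "lisinopril 10 mg",
    "ibuprofen 200 mg",
    "omeprazole 20 mg",
]
_ANTI_HYPERGLYCEMICS = [
    "insulin glargine 100 unit/mL",
    "glipizide 5 mg",
    "pioglitazone 15 mg",
    "sitagliptin 100 mg",
    "dulaglutide 0.75 mg",
    "empagliflozin 10 mg",
    "metformin 500 mg",
]
_DX_SUFFIXES = ["", "0", "1", "2", "3", "9"]


@dataclass
class PatientSketch:
    """Mutable accumulator for one synthetic patient: demographic fields,
    raw table rows, and the ground-truth flag set updated by each planted
    pattern."""

    pid: str
    rng: np.random.Generator
    criteria: CriteriaConfig
    start: datetime.date
    span: int                      # usable day range
    birth_date: datetime.date = datetime.date(1960, 1, 1)
    sex: Sex = Sex.FEMALE
    race: str = "unknown"
    zip_code: str = ""
    labs: list[dict] = field(default_factory=list)
    vitals: list[dict] = field(default_factory=list)
    diagnoses: list[dict] = field(default_factory=list)
    medications: list[dict] = field(default_factory=list)
    truth: ConditionFlags = None  # type: ignore[assignment]
    patterns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.truth = ConditionFlags(patient_id=self.pid)

    # -- helpers -----------------------------------------------------------
    def date(self, day: int) -> datetime.date:
        return self.start + datetime.timedelta(days=int(day))

    def age_at(self, day: int) -> int:
        return age_in_years(self.birth_date, self.date(day))

    def anchor(self, tail: int = 900) -> int:
        """Random anchor day leaving ``tail`` days of room after it."""
        return int(self.rng.integers(0, max(1, self.span - tail)))

    def add_lab(self, day: int, analyte: str, value: str, units: str, fasting: str = "") -> None:
        self.labs.append(
            dict(patient_id=self.pid, date=self.date(day).isoformat(),
                 analyte=analyte, value=value, units=units, fasting=fasting)
        )

    def add_glucose(self, day: int, value: int, fasting: bool) -> None:
        self.add_lab(day, "glucose", str(int(value)), "mg/dL",
                     "true" if fasting else "false")

    def add_creatinine(self, day: int, scr_mgdl: float) -> None:
        """Creatinine row; ~20% arrive in µmol/L to exercise unit maps."""
        if self.rng.random() < 0.2:
            self.add_lab(day, "serum_creatinine", f"{scr_mgdl * 88.4:.1f}", "umol/L")
        else:
            self.add_lab(day, "serum_creatinine", f"{scr_mgdl:.3f}", "mg/dL")

    def add_creatinine_for_egfr(self, day: int, target_egfr: float) -> None:
        scr = invert_ckdepi(target_egfr, self.age_at(day), self.sex,
                            self.criteria.egfr)
        self.add_creatinine(day, round(scr, 3))

    def add_vital(self, day: int, sbp: int | None, dbp: int | None,
                  height_cm: float | None = None) -> None:
        self.vitals.append(
            dict(patient_id=self.pid, date=self.date(day).isoformat(),
                 systolic="" if sbp is None else str(int(sbp)),
                 diastolic="" if dbp is None else str(int(dbp)),
                 height_cm="" if height_cm is None else f"{height_cm:.1f}")
        )

    def add_dx(self, day: int, condition: str, setting: str) -> None:
        lists = getattr(self.criteria.code_lists, condition)
        system = str(self.rng.choice(sorted(lists)))
        prefix = str(self.rng.choice(lists[system]))
        code = prefix + str(self.rng.choice(_DX_SUFFIXES))
        self.diagnoses.append(
            dict(patient_id=self.pid, date=self.date(day).isoformat(),
                 code_system=system, code=code, setting=setting)
        )

    def add_med(self, day: int, drug_name: str) -> None:
        self.medications.append(
            dict(patient_id=self.pid, date=self.date(day).isoformat(), drug_name=drug_name)
        )

    def mark(self, name: str, **flag_updates: bool) -> None:
        self.patterns.append(name)
        for flag, value in flag_updates.items():
            if value:
                setattr(self.truth, flag, True)


# ---------------------------------------------------------------------------
# pattern library

def _gap(rng: np.random.Generator, lo: int, extra: int = 300) -> int:
    return int(rng.integers(lo, lo + extra))


def _p_ckd_egfr_pair(s: PatientSketch) -> None:
    a = s.anchor()
    gap = _gap(s.rng, s.criteria.windows.ckd_gap_min)
    for day in (a, a + gap):
        s.add_creatinine_for_egfr(day, float(s.rng.uniform(25, 55)))
    s.mark("ckd_egfr_pair", in_repository=True, ckd=True)


def _p_ckd_albuminuria_pair(s: PatientSketch) -> None:
    a = s.anchor()
    gap = _gap(s.rng, s.criteria.windows.ckd_gap_min)
    t = s.criteria.thresholds
    for day in (a, a + gap):
        if s.criteria.albuminuria_mixed_markers and s.rng.random() < 0.5:
            s.add_lab(day, "upcr", f"{s.rng.uniform(t.upcr_high + 10, 800):.1f}", "mg/g")
        else:
            s.add_lab(day, "uacr", f"{s.rng.uniform(t.uacr_high + 5, 300):.1f}", "mg/g")
    s.mark("ckd_albuminuria_pair", in_repository=True, ckd=True)


def _p_ckd_dx(s: PatientSketch) -> None:
    s.add_dx(s.anchor(), "ckd", str(s.rng.choice(["inpatient", "outpatient"])))
    s.mark("ckd_dx", in_repository=True, ckd=True)


def _p_ckd_pediatric_schwartz(s: PatientSketch) -> None:
    # demographics already pediatric; labs inside the first two years keep age < 18
    a = int(s.rng.integers(30, 300))
    gap = _gap(s.rng, s.criteria.windows.ckd_gap_min, 200)
    k = s.criteria.egfr.schwartz_k
    for day in (a, a + gap):
        height = float(s.rng.uniform(110, 150))
        target = float(s.rng.uniform(30, 55))
        s.add_vital(day - 10, None, None, height_cm=height)
        s.add_lab(day, "serum_creatinine", f"{k * height / target:.3f}", "mg/dL")
    s.mark("ckd_pediatric_schwartz", in_repository=True, ckd=True)


def _p_htn_bp_pair(s: PatientSketch) -> None:
    w = s.criteria.windows
    lo = w.bp_gap_min + 1 if w.bp_gap_strict else w.bp_gap_min
    a, gap = s.anchor(), _gap(s.rng, lo, 200)
    for day in (a, a + gap):
        if s.rng.random() < 0.5:  # qualify via systolic
            s.add_vital(day, int(s.rng.integers(145, 185)), int(s.rng.integers(62, 86)))
        else:                     # via diastolic
            s.add_vital(day, int(s.rng.integers(112, 136)), int(s.rng.integers(92, 110)))
    s.mark("htn_bp_pair", in_repository=True, htn=True)


def _p_htn_dx(s: PatientSketch) -> None:
    s.add_dx(s.anchor(), "htn", str(s.rng.choice(["inpatient", "outpatient"])))
    s.mark("htn_dx", in_repository=True, htn=True)


def _p_dm_hba1c(s: PatientSketch) -> None:
    s.add_lab(s.anchor(), "hba1c", f"{s.rng.uniform(6.6, 11.0):.1f}", "%")
    s.mark("dm_hba1c", in_repository=True, dm=True)


def _p_dm_glucose_random_pair(s: PatientSketch) -> None:
    a = s.anchor()
    gap = int(s.rng.integers(s.criteria.windows.glucose_gap_min, 400))
    for day in (a, a + gap):
        s.add_glucose(day, int(s.rng.integers(205, 350)), fasting=False)
    s.mark("dm_glucose_random_pair", in_repository=True, dm=True)


def _p_dm_glucose_fasting_pair(s: PatientSketch) -> None:
    a = s.anchor()
    gap = int(s.rng.integers(s.criteria.windows.glucose_gap_min, 400))
    for day in (a, a + gap):
        s.add_glucose(day, int(s.rng.integers(130, 250)), fasting=True)
    s.mark("dm_glucose_fasting_pair", in_repository=True, dm=True)


def _p_dm_medication(s: PatientSketch) -> None:
    s.add_med(s.anchor(), str(s.rng.choice(_ANTI_HYPERGLYCEMICS)))
    s.mark("dm_medication", in_repository=True, dm=True)


def _p_dm_dx_outpatient_pair(s: PatientSketch) -> None:
    a, gap = s.anchor(), _gap(s.rng, 1, 400)
    s.add_dx(a, "dm", "outpatient")
    s.add_dx(a + gap, "dm", "outpatient")
    s.mark("dm_dx_outpatient_pair", in_repository=True, dm=True)


def _p_dm_dx_inpatient(s: PatientSketch) -> None:
    s.add_dx(s.anchor(), "dm", "inpatient")
    s.mark("dm_dx_inpatient", in_repository=True, dm=True)


def _p_prediab_hba1c_band(s: PatientSketch) -> None:
    s.add_lab(s.anchor(), "hba1c", f"{s.rng.uniform(5.75, 6.35):.2f}", "%")
    s.mark("prediab_hba1c_band", in_repository=True, prediabetes=True)


def _p_prediab_glucose_random_pair(s: PatientSketch) -> None:
    a, gap = s.anchor(), _gap(s.rng, 1, 400)
    for day in (a, a + gap):
        s.add_glucose(day, int(s.rng.integers(142, 198)), fasting=False)
    s.mark("prediab_glucose_random_pair", in_repository=True, prediabetes=True)


def _p_prediab_glucose_fasting_pair(s: PatientSketch) -> None:
    a, gap = s.anchor(), _gap(s.rng, 1, 400)
    for day in (a, a + gap):
        s.add_glucose(day, int(s.rng.integers(102, 124)), fasting=True)
    s.mark("prediab_glucose_fasting_pair", in_repository=True, prediabetes=True)


def _p_prediab_dx(s: PatientSketch) -> None:
    s.add_dx(s.anchor(), "prediabetes", str(s.rng.choice(["inpatient", "outpatient"])))
    s.mark("prediab_dx", in_repository=True, prediabetes=True)


# --- near-misses: correct values, exactly one clause violated --------------

def _p_ckd_near_gap(s: PatientSketch) -> None:
    a = s.anchor()
    gap = s.criteria.windows.ckd_gap_min - 1
    for day in (a, a + gap):
        s.add_creatinine_for_egfr(day, float(s.rng.uniform(25, 55)))
    s.mark("ckd_near_gap", in_repository=True)  # single low eGFR still enters repository


def _p_ckd_near_single(s: PatientSketch) -> None:
    s.add_creatinine_for_egfr(s.anchor(), float(s.rng.uniform(25, 55)))
    s.mark("ckd_near_single", in_repository=True)


def _p_ckd_near_egfr_boundary(s: PatientSketch) -> None:
    # source-system eGFR exactly at the cut-point: < is strict, so no entry
    a = s.anchor()
    t = s.criteria.thresholds
    for day in (a, a + 120):
        s.add_lab(day, "egfr", f"{t.egfr_low:.1f}", "mL/min/1.73m2")
    s.mark("ckd_near_egfr_boundary")


def _p_ckd_near_albuminuria_gap(s: PatientSketch) -> None:
    a = s.anchor()
    t = s.criteria.thresholds
    s.add_lab(a, "uacr", f"{s.rng.uniform(t.uacr_high + 5, 300):.1f}", "mg/g")
    s.add_lab(a + s.criteria.windows.ckd_gap_min - 1, "upcr",
              f"{s.rng.uniform(t.upcr_high + 10, 800):.1f}", "mg/g")
    s.mark("ckd_near_albuminuria_gap", in_repository=True)


def _p_htn_near_gap(s: PatientSketch) -> None:
    w = s.criteria.windows
    gap = w.bp_gap_min if w.bp_gap_strict else w.bp_gap_min - 1
    a = s.anchor()
    for day in (a, a + gap):
        s.add_vital(day, int(s.rng.integers(145, 185)), int(s.rng.integers(62, 86)))
    s.mark("htn_near_gap", in_repository=True)


def _p_htn_near_single(s: PatientSketch) -> None:
    s.add_vital(s.anchor(), 160, 100)
    s.mark("htn_near_single", in_repository=True)


def _p_htn_near_boundary(s: PatientSketch) -> None:
    t = s.criteria.thresholds
    a = s.anchor()
    for day in (a, a + 30):
        s.add_vital(day, int(t.sbp_high) - 1, int(t.dbp_high) - 1)
    s.mark("htn_near_boundary")


def _p_dm_near_hba1c(s: PatientSketch) -> None:
    # top of the prediabetes band: misses DM but legitimately is prediabetes
    s.add_lab(s.anchor(), "hba1c", f"{s.criteria.thresholds.hba1c_prediab_high:.1f}", "%")
    s.mark("dm_near_hba1c", in_repository=True, prediabetes=True)


def _p_dm_near_glucose_same_day(s: PatientSketch) -> None:
    a = s.anchor()
    s.add_glucose(a, 210, fasting=False)
    s.add_glucose(a, 215, fasting=False)
    s.mark("dm_near_glucose_same_day", in_repository=True)


def _p_dm_near_glucose_window(s: PatientSketch) -> None:
    a = s.anchor()
    gap = s.criteria.windows.glucose_gap_max + 1
    s.add_glucose(a, 130, fasting=True)
    s.add_glucose(a + gap, 132, fasting=True)
    s.mark("dm_near_glucose_window", in_repository=True)


def _p_dm_near_dx_single_outpatient(s: PatientSketch) -> None:
    s.add_dx(s.anchor(), "dm", "outpatient")
    s.mark("dm_near_dx_single_outpatient", in_repository=True)


def _p_dm_near_dx_same_day(s: PatientSketch) -> None:
    a = s.anchor()
    s.add_dx(a, "dm", "outpatient")
    s.add_dx(a, "dm", "outpatient")  # same encounter date: one distinct date only
    s.mark("dm_near_dx_same_day", in_repository=True)


def _p_prediab_near_hba1c(s: PatientSketch) -> None:
    s.add_lab(s.anchor(), "hba1c", "5.6", "%")
    s.mark("prediab_near_hba1c")


def _p_prediab_near_fasting_low(s: PatientSketch) -> None:
    a = s.anchor()
    s.add_glucose(a, 99, fasting=True)
    s.add_glucose(a + 100, 98, fasting=True)
    s.mark("prediab_near_fasting_low")


def _p_prediab_near_gap0(s: PatientSketch) -> None:
    a = s.anchor()
    s.add_glucose(a, 150, fasting=False)
    s.add_glucose(a, 155, fasting=False)
    s.mark("prediab_near_gap0", in_repository=True)


def _p_pcos_metformin_only(s: PatientSketch) -> None:
    s.sex = Sex.FEMALE
    a = s.anchor()
    s.add_med(a, "metformin 500 mg")
    s.add_dx(a + int(s.rng.integers(0, 60)), "pcos", "outpatient")
    s.mark("pcos_metformin_only", in_repository=True, pcos_excluded_dm=True)


def _p_pcos_metformin_with_lab(s: PatientSketch) -> None:
    s.sex = Sex.FEMALE
    a = s.anchor()
    s.add_med(a, "metformin 500 mg")
    s.add_dx(a + int(s.rng.integers(0, 60)), "pcos", "outpatient")
    s.add_lab(a + int(s.rng.integers(0, 200)), "hba1c",
              f"{s.rng.uniform(6.6, 9.0):.1f}", "%")
    s.mark("pcos_metformin_with_lab", in_repository=True, dm=True)


def _p_pediatric_no_height(s: PatientSketch) -> None:
    # pediatric creatinine with no height in the lookback: no eGFR, no entry
    day = int(s.rng.integers(30, 300))
    s.add_lab(day, "serum_creatinine", f"{s.rng.uniform(1.5, 3.0):.3f}", "mg/dL")
    s.mark("pediatric_no_height")


QUALIFYING_PATTERNS: dict[str, callable] = {
    "ckd_egfr_pair": _p_ckd_egfr_pair,
    "ckd_albuminuria_pair": _p_ckd_albuminuria_pair,
    "ckd_dx": _p_ckd_dx,
    "ckd_pediatric_schwartz": _p_ckd_pediatric_schwartz,
    "htn_bp_pair": _p_htn_bp_pair,
    "htn_dx": _p_htn_dx,
    "dm_hba1c": _p_dm_hba1c,
    "dm_glucose_random_pair": _p_dm_glucose_random_pair,
    "dm_glucose_fasting_pair": _p_dm_glucose_fasting_pair,
    "dm_medication": _p_dm_medication,
    "dm_dx_outpatient_pair": _p_dm_dx_outpatient_pair,
    "dm_dx_inpatient": _p_dm_dx_inpatient,
    "prediab_hba1c_band": _p_prediab_hba1c_band,
    "prediab_glucose_random_pair": _p_prediab_glucose_random_pair,
    "prediab_glucose_fasting_pair": _p_prediab_glucose_fasting_pair,
    "prediab_dx": _p_prediab_dx,
}

NEAR_MISS_PATTERNS: dict[str, callable] = {
    "ckd_near_gap": _p_ckd_near_gap,
    "ckd_near_single": _p_ckd_near_single,
    "ckd_near_egfr_boundary": _p_ckd_near_egfr_boundary,
    "ckd_near_albuminuria_gap": _p_ckd_near_albuminuria_gap,
    "htn_near_gap": _p_htn_near_gap,
    "htn_near_single": _p_htn_near_single,
    "htn_near_boundary": _p_htn_near_boundary,
    "dm_near_hba1c": _p_dm_near_hba1c,
    "dm_near_glucose_same_day": _p_dm_near_glucose_same_day,
    "dm_near_glucose_window": _p_dm_near_glucose_window,
    "dm_near_dx_single_outpatient": _p_dm_near_dx_single_outpatient,
    "dm_near_dx_same_day": _p_dm_near_dx_same_day,
    "prediab_near_hba1c": _p_prediab_near_hba1c,
    "prediab_near_fasting_low": _p_prediab_near_fasting_low,
    "prediab_near_gap0": _p_prediab_near_gap0,
}

SPECIAL_PATTERNS: dict[str, callable] = {
    "pcos_metformin_only": _p_pcos_metformin_only,
    "pcos_metformin_with_lab": _p_pcos_metformin_with_lab,
    "pediatric_no_height": _p_pediatric_no_height,
}

PATTERN_LIBRARY: dict[str, callable] = {
    **QUALIFYING_PATTERNS, **NEAR_MISS_PATTERNS, **SPECIAL_PATTERNS,
}

#: patterns that require pediatric demographics
_PEDIATRIC = {"ckd_pediatric_schwartz", "pediatric_no_height"}

_CONDITION_POOLS = {
    "ckd": ["ckd_egfr_pair", "ckd_albuminuria_pair", "ckd_dx"],
    "htn": ["htn_bp_pair", "htn_dx"],
    "dm": ["dm_hba1c", "dm_glucose_random_pair", "dm_glucose_fasting_pair",
           "dm_medication", "dm_dx_outpatient_pair", "dm_dx_inpatient"],
    "prediabetes": ["prediab_hba1c_band", "prediab_glucose_random_pair",
                    "prediab_glucose_fasting_pair", "prediab_dx"],
}


def inject_pattern(sketch: PatientSketch, pattern_name: str) -> PatientSketch:
    """Plant one named pattern into a patient sketch, updating its truth
    label. Unknown pattern names are an error."""
    try:
        planter = PATTERN_LIBRARY[pattern_name]
    except KeyError:
        raise ValueError(f"unknown pattern {pattern_name!r}") from None
    planter(sketch)
    return sketch


# ---------------------------------------------------------------------------
# background (strictly non-qualifying) events

def _add_background(s: PatientSketch, mean_events: float) -> None:
    n = int(s.rng.poisson(mean_events))
    for _ in range(n):
        day = s.anchor(tail=1)
        kind = s.rng.random()
        if kind < 0.2:
            s.add_lab(day, "hba1c", f"{s.rng.uniform(4.6, 5.5):.1f}", "%")
        elif kind < 0.35:
            s.add_glucose(day, int(s.rng.integers(75, 99)), fasting=True)
        elif kind < 0.5:
            s.add_glucose(day, int(s.rng.integers(85, 139)), fasting=False)
        elif kind < 0.7:
            s.add_vital(day, int(s.rng.integers(105, 139)), int(s.rng.integers(62, 89)))
        elif kind < 0.8:
            s.add_lab(day, "egfr", f"{s.rng.uniform(75, 115):.1f}", "mL/min/1.73m2")
        elif kind < 0.9:
            s.add_med(day, str(s.rng.choice(_BENIGN_MEDS)))
        else:
            system, code = _BENIGN_DX[int(s.rng.integers(len(_BENIGN_DX)))]
            self_setting = str(s.rng.choice(["inpatient", "outpatient"]))
            s.diagnoses.append(
                dict(patient_id=s.pid, date=s.date(day).isoformat(),
                     code_system=system, code=code, setting=self_setting)
            )


# ---------------------------------------------------------------------------
# cohort assembly

def make_synthetic_crosswalk() -> pd.DataFrame:
    """Synthetic zip -> RUCA crosswalk covering every secondary RUCA code
    twice (zips 90000-90065). Synthetic stand-in: real crosswalks are
    external reference data."""
    codes = [1.0, 1.1, 2.0, 2.1, 3.0, 4.0, 4.1, 4.2, 5.0, 5.1, 5.2, 6.0, 6.1,
             7.0, 7.1, 7.2, 7.3, 7.4, 8.0, 8.1, 8.2, 8.3, 8.4, 9.0, 9.1, 9.2,
             10.0, 10.1, 10.2, 10.3, 10.4, 10.5, 10.6]
    rows = [
        dict(zip=str(90000 + i), ruca_code=codes[i % len(codes)])
        for i in range(2 * len(codes))
    ]
    return pd.DataFrame(rows, columns=["zip", "ruca_code"])


@dataclass
class SyntheticCohort:
    """Generated tables plus ground truth; ``write`` emits the CSV set."""

    tables: dict[str, pd.DataFrame]
    truth: pd.DataFrame
    crosswalk: pd.DataFrame

    def write(self, path) -> None:
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(path / f"{name}.csv", index=False)
        self.truth.to_csv(path / "truth.csv", index=False)
        self.crosswalk.to_csv(path / "crosswalk.csv", index=False)

    def truth_flags(self) -> dict[str, ConditionFlags]:
        out: dict[str, ConditionFlags] = {}
        for row in self.truth.itertuples():
            out[row.patient_id] = ConditionFlags(
                patient_id=row.patient_id,
                in_repository=bool(row.in_repository),
                ckd=bool(row.ckd), htn=bool(row.htn), dm=bool(row.dm),
                prediabetes=bool(row.prediabetes),
                pcos_excluded_dm=bool(row.pcos_excluded_dm),
            )
        return out


def _assign_patterns(rng: np.random.Generator, idx: int, g: GeneratorConfig) -> list[str]:
    library = list(PATTERN_LIBRARY)
    if idx < len(library):
        return [library[idx]]
    u = rng.random()
    if u < g.near_miss_rate:
        return [str(rng.choice(sorted(NEAR_MISS_PATTERNS)))]
    if u < g.near_miss_rate + g.pcos_rate:
        return [str(rng.choice(["pcos_metformin_only", "pcos_metformin_with_lab"]))]
    if u < g.near_miss_rate + g.pcos_rate + g.pediatric_rate:
        return [str(rng.choice(["ckd_pediatric_schwartz", "pediatric_no_height"]))]
    chosen = []
    for cond, pool in _CONDITION_POOLS.items():
        if rng.random() < g.prevalence.get(cond, 0.0):
            chosen.append(str(rng.choice(pool)))
    return chosen  # may be empty: background-only patient


def generate_cohort(
    gconfig: GeneratorConfig | None = None,
    criteria: CriteriaConfig | None = None,
) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground-truth labels.

    Deterministic in (gconfig, criteria): identical inputs produce
    byte-identical tables.
    """
    g = gconfig or GeneratorConfig()
    criteria = criteria or CriteriaConfig()
    rng = np.random.default_rng(g.seed)
    span = (g.date_end - g.date_start).days
    xw = make_synthetic_crosswalk()
    zip_pool = list(xw["zip"])

    patients, labs, vitals, diagnoses, medications, truth_rows = [], [], [], [], [], []
    for idx in range(g.n_patients):
        pid = f"P{idx:06d}"
        s = PatientSketch(pid=pid, rng=rng, criteria=criteria,
                          start=g.date_start, span=span)
        pattern_names = _assign_patterns(rng, idx, g)

        pediatric = any(p in _PEDIATRIC for p in pattern_names)
        if pediatric:
            age0 = int(rng.integers(6, 15))   # 6-14 at range start; stays < 18 for 2+ years
        else:
            age0 = int(rng.integers(25, 86))
        s.birth_date = g.date_start - datetime.timedelta(days=age0 * 365 + int(rng.integers(0, 365)))
        s.sex = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
        s.race = str(rng.choice(
            ["white", "black", "hispanic", "asian", "american indian", "other", "unknown"]
        ))
        uz = rng.random()
        if uz < g.missing_zip_fraction:
            s.zip_code = ""
        elif uz < g.missing_zip_fraction + g.unmapped_zip_fraction:
            s.zip_code = "00000"
        elif uz < g.missing_zip_fraction + g.unmapped_zip_fraction + g.malformed_zip_fraction:
            s.zip_code = "9A!"
        else:
            s.zip_code = str(rng.choice(zip_pool))

        for name in pattern_names:
            inject_pattern(s, name)
        _add_background(s, g.background_events_mean)

        patients.append(
            dict(patient_id=pid, birth_date=s.birth_date.isoformat(), sex=s.sex.value,
                 race_ethnicity=s.race, zip_code=s.zip_code)
        )
        labs.extend(s.labs)
        vitals.extend(s.vitals)
        diagnoses.extend(s.diagnoses)
        medications.extend(s.medications)
        td = s.truth
        truth_rows.append(
            dict(patient_id=pid,
                 in_repository=int(td.in_repository), ckd=int(td.ckd), htn=int(td.htn),
                 dm=int(td.dm), prediabetes=int(td.prediabetes),
                 pcos_excluded_dm=int(td.pcos_excluded_dm),
                 patterns=";".join(s.patterns))
        )

    tables = {
        "patients": pd.DataFrame(
            patients, columns=["patient_id", "birth_date", "sex", "race_ethnicity", "zip_code"]
        ),
        "labs": pd.DataFrame(
            labs, columns=["patient_id", "date", "analyte", "value", "units", "fasting"]
        ),
        "vitals": pd.DataFrame(
            vitals, columns=["patient_id", "date", "systolic", "diastolic", "height_cm"]
        ),
        "diagnoses": pd.DataFrame(
            diagnoses, columns=["patient_id", "date", "code_system", "code", "setting"]
        ),
        "medications": pd.DataFrame(
            medications, columns=["patient_id", "date", "drug_name"]
        ),
    }
    truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "in_repository", "ckd", "htn", "dm", "prediabetes",
                 "pcos_excluded_dm", "patterns"],
    )
    return SyntheticCohort(tables=tables, truth=truth, crosswalk=xw)
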