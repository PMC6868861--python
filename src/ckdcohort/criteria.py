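"""Two-tier rule engine for CKD and at-risk-for-CKD phenotypes.

The *repository* tier is permissive: any single qualifying laboratory
value, blood-pressure reading, diagnosis code for one of the four
conditions, or anti-hyperglycemic prescription admits the patient. The
*registry* tier applies strict guideline-based criteria per condition —
typically repeated measurements with a minimum temporal separation, or
diagnosis codes — and is evaluated only for repository members, so the
registry is a subset of the repository by construction (every strict
trigger implies a permissive one).

Condition flags are not mutually exclusive: a patient may qualify for
CKD, hypertension, diabetes and prediabetes simultaneously. Every
verdict carries an auditable evidence trail (which events fired which
pathway).
"""

from __future__ import annotations

import datetime

from .config import ANTI_HYPERGLYCEMIC_CLASSES, CriteriaConfig
from .egfr import materialize_egfr
from .model import (
    Analyte,
    Condition,
    ConditionFlags,
    CriterionResult,
    DiagnosisEvent,
    LabResult,
    LongitudinalRecord,
    MedicationOrder,
    Setting,
    VitalSign,
)

REPOSITORY = "repository"


# ---------------------------------------------------------------------------
# primitives

def has_qualifying_pair(
    event_days: list[int],
    min_gap: int,
    max_gap: int | None = None,
    *,
    strict_min: bool = False,
) -> tuple[int, int] | None:
    """Earliest index pair (i, j) with a qualifying day separation.

    ``event_days`` must be sorted ascending. The separation qualifies
    when ``gap >= min_gap`` (or ``> min_gap`` under ``strict_min``) and,
    if ``max_gap`` is set, ``gap <= max_gap``. Returns ``None`` when no
    pair qualifies (including the empty list).
    """
    n = len(event_days)
    for i in range(n):
        for j in range(i + 1, n):
            gap = event_days[j] - event_days[i]
            if max_gap is not None and gap > max_gap:
                break  # sorted: later j only grow the gap
            if (gap > min_gap) if strict_min else (gap >= min_gap):
                return (i, j)
    return None


def _ref(event) -> str:
    """Compact human-auditable reference to one event."""
    if isinstance(event, LabResult):
        return f"lab:{event.date}:{event.analyte.value}={event.value:g}"
    if isinstance(event, VitalSign):
        sbp = "" if event.systolic is None else f"{event.systolic:g}"
        dbp = "" if event.diastolic is None else f"{event.diastolic:g}"
        return f"vital:{event.date}:{sbp}/{dbp}"
    if isinstance(event, DiagnosisEvent):
        return f"dx:{event.date}:{event.code_system.value}:{event.code}:{event.setting.value}"
    if isinstance(event, MedicationOrder):
        return f"med:{event.date}:{event.drug_name}"
    raise TypeError(type(event))


def _pair_evidence(events, pair) -> list[str]:
    i, j = pair
    return [_ref(events[i]), _ref(events[j])]


def classify_medication(order: MedicationOrder, lexicon: dict[str, str]) -> str:
    """Assign a therapeutic class by longest ingredient-substring match;
    ``"unclassified"`` when nothing matches (a value, not an error)."""
    name = order.drug_name.lower()
    best = ""
    cls = "unclassified"
    for key, value in lexicon.items():
        if key in name and len(key) > len(best):
            best, cls = key, value
    order.therapeutic_class = cls
    return cls


def is_anti_hyperglycemic(order: MedicationOrder, config: CriteriaConfig) -> bool:
    if order.therapeutic_class is None:
        classify_medication(order, config.medication_lexicon)
    return order.therapeutic_class in ANTI_HYPERGLYCEMIC_CLASSES


def _dx_matches(dx: DiagnosisEvent, prefix_lists: dict[str, list[str]]) -> bool:
    prefixes = prefix_lists.get(dx.code_system.value, [])
    return any(dx.code.startswith(p) for p in prefixes)


def _condition_dx(record: LongitudinalRecord, condition: str, config: CriteriaConfig):
    prefix_lists = getattr(config.code_lists, condition)
    return [dx for dx in record.diagnoses if _dx_matches(dx, prefix_lists)]


def _bp_qualifies(v: VitalSign, config: CriteriaConfig) -> bool:
    t = config.thresholds
    return (v.systolic is not None and v.systolic >= t.sbp_high) or (
        v.diastolic is not None and v.diastolic >= t.dbp_high
    )


def _day(date: datetime.date) -> int:
    return date.toordinal()


def _lab_pair_pathway(
    labs: list[LabResult], min_gap: int, max_gap: int | None = None
) -> list[str] | None:
    """Evidence for the earliest qualifying pair among pre-filtered labs."""
    pair = has_qualifying_pair([_day(lab.date) for lab in labs], min_gap, max_gap)
    return None if pair is None else _pair_evidence(labs, pair)


def _result(condition: str, pathways: dict[str, list[str]]) -> CriterionResult:
    fired = {k: v for k, v in pathways.items() if v}
    if not fired:
        return CriterionResult(condition=condition, qualifies=False)
    first = next(iter(fired))
    return CriterionResult(
        condition=condition, qualifies=True,
        pathway=first, evidence=fired[first], pathways=fired,
    )


# ---------------------------------------------------------------------------
# repository tier

def qualify_repository(
    record: LongitudinalRecord,
    egfrs: list[LabResult],
    config: CriteriaConfig,
) -> CriterionResult:
    """Permissive single-measure entry: any one qualifying lab, diagnosis
    code (for any of the four conditions), blood pressure, or
    anti-hyperglycemic prescription."""
    t = config.thresholds
    lab_hits: list[str] = []
    for lab in egfrs:
        if lab.value < t.egfr_low:
            lab_hits.append(_ref(lab))
    for lab in record.labs:
        a, v = lab.analyte, lab.value
        if (
            (a == Analyte.UACR and v >= t.uacr_high)
            or (a == Analyte.UPCR and v >= t.upcr_high)
            or (a == Analyte.HBA1C and v >= t.hba1c_prediab_low)
            or (a == Analyte.GLUCOSE_RANDOM and v >= t.glucose_random_prediab_low)
            or (a == Analyte.GLUCOSE_FASTING and v >= t.glucose_fasting_prediab_low)
        ):
            lab_hits.append(_ref(lab))

    dx_hits = [
        _ref(dx)
        for cond in ("ckd", "htn", "dm", "prediabetes")
        for dx in _condition_dx(record, cond, config)
    ]
    vital_hits = [_ref(v) for v in record.vitals if _bp_qualifies(v, config)]
    med_hits = [
        _ref(m) for m in record.medications if is_anti_hyperglycemic(m, config)
    ]
    return _result(
        REPOSITORY,
        {
            "lab_single": lab_hits,
            "dx_code": dx_hits,
            "vitals_single": vital_hits,
            "medication": med_hits,
        },
    )


# ---------------------------------------------------------------------------
# registry tier, one rule per condition

def qualify_ckd(
    record: LongitudinalRecord,
    egfrs: list[LabResult],
    config: CriteriaConfig,
) -> CriterionResult:
    """CKD: two eGFR < 60 at least 90 days apart, two albuminuria-range
    labs (UACR >= 30 or UPCR >= 150) at least 90 days apart, or one CKD
    diagnosis code in any setting."""
    t, w = config.thresholds, config.windows
    low_egfr = [lab for lab in egfrs if lab.value < t.egfr_low]
    pathways: dict[str, list[str] | None] = {
        "lab_pair_egfr": _lab_pair_pathway(low_egfr, w.ckd_gap_min)
    }

    uacr = [l for l in record.labs if l.analyte == Analyte.UACR and l.value >= t.uacr_high]
    upcr = [l for l in record.labs if l.analyte == Analyte.UPCR and l.value >= t.upcr_high]
    if config.albuminuria_mixed_markers:
        alb = sorted(uacr + upcr, key=lambda lab: lab.date)
        alb_ev = _lab_pair_pathway(alb, w.ckd_gap_min)
    else:
        alb_ev = _lab_pair_pathway(uacr, w.ckd_gap_min) or _lab_pair_pathway(
            upcr, w.ckd_gap_min
        )
    pathways["lab_pair_albuminuria"] = alb_ev
    pathways["dx_code"] = [_ref(dx) for dx in _condition_dx(record, "ckd", config)] or None
    return _result(Condition.CKD.value, {k: v or [] for k, v in pathways.items()})


def qualify_htn(record: LongitudinalRecord, config: CriteriaConfig) -> CriterionResult:
    """Hypertension: two qualifying readings (SBP >= 140 or DBP >= 90)
    separated by the configured gap, or one HTN diagnosis code."""
    w = config.windows
    readings = [v for v in record.vitals if _bp_qualifies(v, config)]
    pair = has_qualifying_pair(
        [_day(v.date) for v in readings], w.bp_gap_min, strict_min=w.bp_gap_strict
    )
    return _result(
        Condition.HTN.value,
        {
            "vitals_pair": [] if pair is None else _pair_evidence(readings, pair),
            "dx_code": [_ref(dx) for dx in _condition_dx(record, "htn", config)],
        },
    )


def _glucose_pair(
    record: LongitudinalRecord,
    analyte: Analyte,
    low: float,
    high: float | None,
    config: CriteriaConfig,
) -> list[str]:
    """Qualifying glucose pair within [glucose_gap_min, glucose_gap_max].
    Random and fasting measurements are never pooled; both members must
    satisfy the same band."""
    w = config.windows
    labs = [
        lab
        for lab in record.labs
        if lab.analyte == analyte
        and lab.value >= low
        and (high is None or lab.value <= high)
    ]
    return _lab_pair_pathway(labs, w.glucose_gap_min, w.glucose_gap_max) or []


def qualify_dm(record: LongitudinalRecord, config: CriteriaConfig) -> CriterionResult:
    """Diabetes: one HbA1c >= 6.5%; a random-glucose pair >= 200 or a
    fasting pair >= 126 within [1, 730] days; any anti-hyperglycemic
    prescription; two outpatient DM codes on distinct dates; or one
    inpatient DM code. (The PCOS-metformin exclusion is applied later.)"""
    t = config.thresholds
    hba1c = [
        _ref(l) for l in record.labs
        if l.analyte == Analyte.HBA1C and l.value >= t.hba1c_dm
    ]
    meds = [_ref(m) for m in record.medications if is_anti_hyperglycemic(m, config)]

    dm_dx = _condition_dx(record, "dm", config)
    outpatient = [dx for dx in dm_dx if dx.setting == Setting.OUTPATIENT]
    out_ev: list[str] = []
    if len({dx.date for dx in outpatient}) >= 2:
        dates_seen: set = set()
        for dx in outpatient:
            if dx.date not in dates_seen:
                dates_seen.add(dx.date)
                out_ev.append(_ref(dx))
            if len(out_ev) == 2:
                break
    inpatient = [_ref(dx) for dx in dm_dx if dx.setting == Setting.INPATIENT]

    return _result(
        Condition.DM.value,
        {
            "lab_single": hba1c,
            "lab_pair_glucose_random": _glucose_pair(
                record, Analyte.GLUCOSE_RANDOM, t.glucose_random_dm, None, config
            ),
            "lab_pair_glucose_fasting": _glucose_pair(
                record, Analyte.GLUCOSE_FASTING, t.glucose_fasting_dm, None, config
            ),
            "medication": meds,
            "dx_code_pair_outpatient": out_ev,
            "dx_code_inpatient": inpatient,
        },
    )


def qualify_prediabetes(record: LongitudinalRecord, config: CriteriaConfig) -> CriterionResult:
    """Prediabetes: one HbA1c in the closed 5.7-6.4% band; a
    random-glucose pair in 140-199 or fasting pair in 100-125 within
    [1, 730] days; or any prediabetes diagnosis code."""
    t = config.thresholds
    hba1c = [
        _ref(l) for l in record.labs
        if l.analyte == Analyte.HBA1C
        and t.hba1c_prediab_low <= l.value <= t.hba1c_prediab_high
    ]
    return _result(
        Condition.PREDIABETES.value,
        {
            "lab_single": hba1c,
            "lab_pair_glucose_random": _glucose_pair(
                record, Analyte.GLUCOSE_RANDOM,
                t.glucose_random_prediab_low, t.glucose_random_prediab_high, config,
            ),
            "lab_pair_glucose_fasting": _glucose_pair(
                record, Analyte.GLUCOSE_FASTING,
                t.glucose_fasting_prediab_low, t.glucose_fasting_prediab_high, config,
            ),
            "dx_code": [_ref(dx) for dx in _condition_dx(record, "prediabetes", config)],
        },
    )


# ---------------------------------------------------------------------------
# PCOS-metformin exclusion

def apply_pcos_exclusion(
    flags: ConditionFlags,
    record: LongitudinalRecord,
    dm_result: CriterionResult,
    prediab_result: CriterionResult,
    config: CriteriaConfig,
) -> ConditionFlags:
    """Clear the DM flag for patients whose only diabetes evidence is
    metformin prescribed with a PCOS diagnosis.

    Fires only when DM qualified solely via the medication pathway, every
    anti-hyperglycemic order is metformin, a PCOS code exists, and no
    prediabetes criterion is met. Other condition flags are untouched;
    the patient stays in the registry iff another condition qualifies.
    """
    if not flags.dm:
        return flags
    if set(dm_result.pathways) != {"medication"}:
        return flags
    anti = [m for m in record.medications if is_anti_hyperglycemic(m, config)]
    if not anti or any(m.therapeutic_class != "metformin" for m in anti):
        return flags
    if not _condition_dx(record, "pcos", config):
        return flags
    if prediab_result.qualifies:
        return flags
    flags.dm = False
    flags.pcos_excluded_dm = True
    return flags


# ---------------------------------------------------------------------------
# orchestration

def phenotype_record(
    record: LongitudinalRecord, config: CriteriaConfig | None = None
) -> tuple[ConditionFlags, list[CriterionResult], list[str]]:
    """Evaluate one patient: repository tier, then (for members) the four
    registry condition rules and the PCOS exclusion."""
    cfg = config or CriteriaConfig()
    egfrs, logs = materialize_egfr(record, cfg)
    for m in record.medications:
        if m.therapeutic_class is None:
            classify_medication(m, cfg.medication_lexicon)

    repo = qualify_repository(record, egfrs, cfg)
    flags = ConditionFlags(patient_id=record.patient_id, in_repository=repo.qualifies)
    results = [repo]
    if repo.qualifies:
        ckd = qualify_ckd(record, egfrs, cfg)
        htn = qualify_htn(record, cfg)
        dm = qualify_dm(record, cfg)
        prediab = qualify_prediabetes(record, cfg)
        results += [ckd, htn, dm, prediab]
        flags.ckd, flags.htn = ckd.qualifies, htn.qualifies
        flags.dm, flags.prediabetes = dm.qualifies, prediab.qualifies
        flags = apply_pcos_exclusion(flags, record, dm, prediab, cfg)
    return flags, results, logs


def build_registry(
    records: dict[str, LongitudinalRecord], config: CriteriaConfig | None = None
) -> tuple[dict[str, ConditionFlags], dict[str, list[CriterionResult]], list[str]]:
    """Phenotype a whole cohort. Patients are processed in sorted-id order
    so outputs are bit-stable; returns per-patient flags, per-patient
    criterion results, and eGFR dispatch/discordance logs."""
    cfg = config or CriteriaConfig()
    all_flags: dict[str, ConditionFlags] = {}
    all_results: dict[str, list[CriterionResult]] = {}
    logs: list[str] = []
    for pid in sorted(records):
        flags, results, rec_logs = phenotype_record(records[pid], cfg)
        all_flags[pid] = flags
        all_results[pid] = results
        logs.extend(rec_logs)
    return all_flags, all_results, logs
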