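"""Independent brute-force evaluator of the qualification rules.

Used as the oracle against the engine on small records: every pair rule
is decided by exhaustive enumeration of all event pairs
(itertools.combinations) and the eGFR formulas are written out inline,
so the only thing shared with the implementation is the configuration
values themselves.
"""

import itertools

from ckdcohort.config import ANTI_HYPERGLYCEMIC_CLASSES, CriteriaConfig
from ckdcohort.model import ConditionFlags


def _age(birth, on):
    years = on.year - birth.year
    if (on.month, on.day) < (birth.month, birth.day):
        years -= 1
    return years


def _egfr_series(rec, cfg):
    """(date, value) list: creatinine through the formulas, plus source
    eGFR rows on dates without a computed value."""
    p = cfg.egfr
    out, computed_dates = [], set()
    female = rec.demographics.sex.value == "female"
    race = rec.demographics.race_ethnicity.lower()
    black = "black" in race or "african american" in race
    for lab in rec.labs:
        if lab.analyte.value != "serum_creatinine":
            continue
        age = _age(rec.demographics.birth_date, lab.date)
        if age >= p.pediatric_age_cutoff:
            k = p.kappa_female if female else p.kappa_male
            a = p.alpha_female if female else p.alpha_male
            r = lab.value / k
            v = (p.scale * min(r, 1.0) ** a * max(r, 1.0) ** p.creatinine_exponent
                 * p.age_base ** age)
            if female:
                v *= p.female_multiplier
            if black and p.race_coefficient_on:
                v *= p.black_multiplier
        else:
            heights = [
                (abs((vt.date - lab.date).days), i, vt.height_cm)
                for i, vt in enumerate(rec.vitals)
                if vt.height_cm is not None
                and abs((vt.date - lab.date).days) <= p.height_lookback_days
            ]
            if not heights:
                continue
            heights.sort(key=lambda t: (t[0], t[1]))
            v = p.schwartz_k * heights[0][2] / lab.value
        out.append((lab.date, v))
        computed_dates.add(lab.date)
    for lab in rec.labs:
        if lab.analyte.value == "egfr" and lab.date not in computed_dates:
            out.append((lab.date, lab.value))
    return out


def _any_pair(dates, min_gap, max_gap=None, strict=False):
    for a, b in itertools.combinations(sorted(dates), 2):
        gap = (b - a).days
        lo_ok = gap > min_gap if strict else gap >= min_gap
        if lo_ok and (max_gap is None or gap <= max_gap):
            return True
    return False


def _med_class(name, lexicon):
    name = name.lower()
    best, cls = "", "unclassified"
    for key, value in lexicon.items():
        if key in name and len(key) > len(best):
            best, cls = key, value
    return cls


def _dx_dates(rec, prefix_lists, settings=None):
    return [
        dx.date
        for dx in rec.diagnoses
        if (settings is None or dx.setting.value in settings)
        and any(dx.code.startswith(p) for p in prefix_lists.get(dx.code_system.value, []))
    ]


def oracle_flags(rec, cfg: CriteriaConfig) -> ConditionFlags:
    t, w = cfg.thresholds, cfg.windows
    egfrs = _egfr_series(rec, cfg)
    labs = rec.labs

    def lab_dates(analyte, lo=None, hi=None):
        return [
            l.date for l in labs
            if l.analyte.value == analyte
            and (lo is None or l.value >= lo)
            and (hi is None or l.value <= hi)
        ]

    anti_meds = [
        m for m in rec.medications
        if _med_class(m.drug_name, cfg.medication_lexicon) in ANTI_HYPERGLYCEMIC_CLASSES
    ]
    bp_dates = [
        v.date for v in rec.vitals
        if (v.systolic is not None and v.systolic >= t.sbp_high)
        or (v.diastolic is not None and v.diastolic >= t.dbp_high)
    ]

    repo = bool(
        [d for d, v in egfrs if v < t.egfr_low]
        or lab_dates("uacr", lo=t.uacr_high)
        or lab_dates("upcr", lo=t.upcr_high)
        or lab_dates("hba1c", lo=t.hba1c_prediab_low)
        or lab_dates("glucose_random", lo=t.glucose_random_prediab_low)
        or lab_dates("glucose_fasting", lo=t.glucose_fasting_prediab_low)
        or any(
            _dx_dates(rec, getattr(cfg.code_lists, c))
            for c in ("ckd", "htn", "dm", "prediabetes")
        )
        or bp_dates
        or anti_meds
    )
    flags = ConditionFlags(patient_id=rec.patient_id, in_repository=repo)
    if not repo:
        return flags

    # CKD
    low_egfr = sorted(d for d, v in egfrs if v < t.egfr_low)
    alb_uacr = lab_dates("uacr", lo=t.uacr_high)
    alb_upcr = lab_dates("upcr", lo=t.upcr_high)
    if cfg.albuminuria_mixed_markers:
        alb_ok = _any_pair(alb_uacr + alb_upcr, w.ckd_gap_min)
    else:
        alb_ok = _any_pair(alb_uacr, w.ckd_gap_min) or _any_pair(alb_upcr, w.ckd_gap_min)
    flags.ckd = bool(
        _any_pair(low_egfr, w.ckd_gap_min)
        or alb_ok
        or _dx_dates(rec, cfg.code_lists.ckd)
    )

    # HTN
    flags.htn = bool(
        _any_pair(bp_dates, w.bp_gap_min, strict=w.bp_gap_strict)
        or _dx_dates(rec, cfg.code_lists.htn)
    )

    # DM (before PCOS exclusion)
    dm_pathways = set()
    if lab_dates("hba1c", lo=t.hba1c_dm):
        dm_pathways.add("hba1c")
    if _any_pair(lab_dates("glucose_random", lo=t.glucose_random_dm),
                 w.glucose_gap_min, w.glucose_gap_max):
        dm_pathways.add("glucose_random")
    if _any_pair(lab_dates("glucose_fasting", lo=t.glucose_fasting_dm),
                 w.glucose_gap_min, w.glucose_gap_max):
        dm_pathways.add("glucose_fasting")
    if anti_meds:
        dm_pathways.add("medication")
    if len(set(_dx_dates(rec, cfg.code_lists.dm, settings={"outpatient"}))) >= 2:
        dm_pathways.add("dx_outpatient")
    if _dx_dates(rec, cfg.code_lists.dm, settings={"inpatient"}):
        dm_pathways.add("dx_inpatient")
    flags.dm = bool(dm_pathways)

    # prediabetes
    flags.prediabetes = bool(
        lab_dates("hba1c", lo=t.hba1c_prediab_low, hi=t.hba1c_prediab_high)
        or _any_pair(
            lab_dates("glucose_random", lo=t.glucose_random_prediab_low,
                      hi=t.glucose_random_prediab_high),
            w.glucose_gap_min, w.glucose_gap_max)
        or _any_pair(
            lab_dates("glucose_fasting", lo=t.glucose_fasting_prediab_low,
                      hi=t.glucose_fasting_prediab_high),
            w.glucose_gap_min, w.glucose_gap_max)
        or _dx_dates(rec, cfg.code_lists.prediabetes)
    )

    # PCOS-metformin exclusion
    if (
        flags.dm
        and dm_pathways == {"medication"}
        and anti_meds
        and all(_med_class(m.drug_name, cfg.medication_lexicon) == "metformin"
                for m in anti_meds)
        and _dx_dates(rec, cfg.code_lists.pcos)
        and not flags.prediabetes
    ):
        flags.dm = False
        flags.pcos_excluded_dm = True
    return flags


def random_mini_record(rng, max_events=8):
    """Boundary-heavy random mini-patient for oracle-equivalence fuzzing."""
    import datetime

    from conftest import make_record
    from ckdcohort.model import Sex

    value_pools = {
        "egfr": [55.0, 59.9, 60.0, 60.1, 70.0],
        "uacr": [25.0, 29.9, 30.0, 45.0],
        "upcr": [140.0, 149.9, 150.0, 200.0],
        "hba1c": [5.6, 5.7, 6.4, 6.5, 7.2],
        "glucose_random": [139, 140, 199, 200, 240],
        "glucose_fasting": [99, 100, 125, 126, 150],
        "serum_creatinine": [0.6, 0.7, 0.9, 1.6, 3.0],
    }
    days = [0, 1, 13, 14, 15, 89, 90, 91, 200, 729, 730, 731]
    dx_pool = [
        ("ICD-10", "N183"), ("ICD-9", "5853"),
        ("ICD-10", "I10"), ("ICD-9", "4019"),
        ("ICD-10", "E119"), ("ICD-9", "25000"),
        ("ICD-10", "R7303"), ("ICD-9", "79029"),
        ("ICD-10", "E282"), ("ICD-10", "J45"),
    ]
    med_pool = ["metformin 500 mg", "insulin glargine", "glipizide 5 mg",
                "lisinopril 10 mg", "ibuprofen 200 mg", "atorvastatin"]

    labs, vitals, dx, meds = [], [], [], []
    pediatric = rng.random() < 0.2
    for _ in range(int(rng.integers(0, max_events + 1))):
        day = int(rng.choice(days))
        kind = rng.random()
        if kind < 0.5:
            analyte = str(rng.choice(sorted(value_pools)))
            labs.append((day, analyte, float(rng.choice(value_pools[analyte]))))
        elif kind < 0.7:
            if rng.random() < 0.25:
                vitals.append((day, None, None, float(rng.choice([120.0, 140.0, 160.0]))))
            else:
                vitals.append((day, int(rng.choice([135, 139, 140, 155])),
                               int(rng.choice([80, 89, 90, 100]))))
        elif kind < 0.85:
            system, code = dx_pool[int(rng.integers(len(dx_pool)))]
            dx.append((day, system, code, str(rng.choice(["inpatient", "outpatient"]))))
        else:
            meds.append((day, str(rng.choice(med_pool))))
    return make_record(
        pid="F1",
        birth="2004-03-01" if pediatric else "1955-08-20",
        sex=Sex.FEMALE if rng.random() < 0.5 else Sex.MALE,
        race=str(rng.choice(["white", "black", "unknown"])),
        labs=labs, vitals=vitals, dx=dx, meds=meds,
    )
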