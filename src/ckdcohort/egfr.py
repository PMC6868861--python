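"""Estimated glomerular filtration rate from serum creatinine.

Adults (age >= 18 completed years at the draw) use the 2009 CKD-EPI
creatinine equation

    eGFR = 141 * min(Scr/k, 1)^alpha * max(Scr/k, 1)^-1.209
               * 0.993^age * 1.018[female] * (1.159[Black], optional)

with sex-specific knot k (0.7 female / 0.9 male) and exponent alpha
(-0.329 / -0.411). Children use the bedside Schwartz equation
eGFR = 0.413 * height(cm) / Scr(mg/dL), matching the nearest height
measurement within a configurable lookback window. The racial
coefficient is configurable and off by default; the active mode is
recorded in the run manifest.

Dispatch partitions every creatinine measurement: it routes to exactly
one equation or to one logged skip (pediatric draw with no usable
height).
"""

from __future__ import annotations

import datetime

from .config import CriteriaConfig, EgfrConfig
from .model import (
    CANONICAL_UNITS,
    Analyte,
    LabResult,
    LongitudinalRecord,
    Sex,
)


class EgfrInputError(ValueError):
    """Invalid physiology (non-positive creatinine or height)."""


class DispatchError(ValueError):
    """Measurement routed to the wrong equation for the patient's age."""


def age_in_years(birth_date: datetime.date, on: datetime.date) -> int:
    """Completed years elapsed at ``on`` (birthday convention)."""
    years = on.year - birth_date.year
    if (on.month, on.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def compute_egfr_ckdepi(
    scr: float,
    age: float,
    sex: Sex,
    *,
    black: bool = False,
    params: EgfrConfig | None = None,
) -> float:
    """Adult eGFR (mL/min/1.73 m^2) by the CKD-EPI creatinine equation.

    ``black`` only has an effect when ``params.race_coefficient_on``.
    """
    p = params or EgfrConfig()
    if scr <= 0:
        raise EgfrInputError(f"serum creatinine must be positive, got {scr}")
    if age < p.pediatric_age_cutoff:
        raise DispatchError(
            f"age {age} is pediatric; route to the Schwartz equation"
        )
    female = sex == Sex.FEMALE
    kappa = p.kappa_female if female else p.kappa_male
    alpha = p.alpha_female if female else p.alpha_male
    ratio = scr / kappa
    egfr = (
        p.scale
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** p.creatinine_exponent
        * p.age_base ** age
    )
    if female:
        egfr *= p.female_multiplier
    if black and p.race_coefficient_on:
        egfr *= p.black_multiplier
    return egfr


def compute_egfr_schwartz(
    height_cm: float, scr: float, params: EgfrConfig | None = None
) -> float:
    """Pediatric eGFR by the bedside Schwartz equation: k * height / Scr."""
    p = params or EgfrConfig()
    if height_cm <= 0:
        raise EgfrInputError(f"height must be positive, got {height_cm}")
    if scr <= 0:
        raise EgfrInputError(f"serum creatinine must be positive, got {scr}")
    return p.schwartz_k * height_cm / scr


def _nearest_height(
    record: LongitudinalRecord, on: datetime.date, lookback_days: int
) -> float | None:
    """Nearest-in-time height within +/- lookback; ties prefer the earlier."""
    best: tuple[int, int, float] | None = None
    for i, v in enumerate(record.vitals):
        if v.height_cm is None:
            continue
        gap = abs((v.date - on).days)
        if gap > lookback_days:
            continue
        cand = (gap, i, v.height_cm)
        if best is None or cand[:2] < best[:2]:
            best = cand
    return None if best is None else best[2]


def _is_black(race_ethnicity: str) -> bool:
    r = race_ethnicity.lower()
    return "black" in r or "african american" in r


def egfr_for_measurement(
    record: LongitudinalRecord,
    lab: LabResult,
    config: CriteriaConfig | None = None,
) -> tuple[LabResult | None, str | None]:
    """Derive an eGFR lab from one serum-creatinine lab.

    Returns ``(egfr_lab, log_message)``; the lab is ``None`` when a
    pediatric measurement has no height within the lookback window, in
    which case the log message explains the skip.
    """
    cfg = config or CriteriaConfig()
    p = cfg.egfr
    if lab.analyte != Analyte.SERUM_CREATININE:
        raise DispatchError(f"expected serum_creatinine lab, got {lab.analyte.value}")
    age = age_in_years(record.demographics.birth_date, lab.date)
    if age >= p.pediatric_age_cutoff:
        value = compute_egfr_ckdepi(
            lab.value, age, record.demographics.sex,
            black=_is_black(record.demographics.race_ethnicity), params=p,
        )
        return (
            LabResult(lab.patient_id, lab.date, Analyte.EGFR, value,
                      CANONICAL_UNITS[Analyte.EGFR]),
            None,
        )
    height = _nearest_height(record, lab.date, p.height_lookback_days)
    if height is None:
        return None, (
            f"{lab.patient_id}: pediatric creatinine on {lab.date} has no height "
            f"within {p.height_lookback_days} days; no eGFR emitted"
        )
    value = compute_egfr_schwartz(height, lab.value, p)
    return (
        LabResult(lab.patient_id, lab.date, Analyte.EGFR, value,
                  CANONICAL_UNITS[Analyte.EGFR]),
        None,
    )


def materialize_egfr(
    record: LongitudinalRecord, config: CriteriaConfig | None = None
) -> tuple[list[LabResult], list[str]]:
    """All usable eGFR observations for a patient, date-sorted.

    Creatinine labs are converted through the age-dispatched equations.
    Source-system eGFR rows (analyte ``egfr``) are kept only for dates
    with no computed value: when both exist on a date the computed value
    wins, and a discordance message is logged if they disagree by more
    than the configured relative tolerance.
    """
    cfg = config or CriteriaConfig()
    logs: list[str] = []
    computed: list[LabResult] = []
    for lab in record.labs:
        if lab.analyte != Analyte.SERUM_CREATININE:
            continue
        egfr_lab, msg = egfr_for_measurement(record, lab, cfg)
        if msg:
            logs.append(msg)
        if egfr_lab is not None:
            computed.append(egfr_lab)

    computed_dates = {lab.date for lab in computed}
    merged = list(computed)
    for lab in record.labs:
        if lab.analyte != Analyte.EGFR:
            continue
        if lab.date in computed_dates:
            ref = next(c for c in computed if c.date == lab.date)
            rel = abs(ref.value - lab.value) / max(ref.value, 1e-12)
            if rel > cfg.egfr.discordance_tolerance:
                logs.append(
                    f"{lab.patient_id}: source eGFR {lab.value:.1f} on {lab.date} "
                    f"discordant with computed {ref.value:.1f} (rel {rel:.2%}); "
                    "computed value used"
                )
            continue  # superseded by the computed value
        merged.append(lab)
    merged.sort(key=lambda lab: lab.date)
    return merged, logs
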