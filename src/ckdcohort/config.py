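"""Criteria configuration: the single source of tunable truth.

All clinical thresholds, temporal windows, diagnosis-code prefix lists,
the medication lexicon, eGFR equation constants and geography file
references live here. Defaults encode the guideline-based rule set the
engine implements; everything is overridable from a YAML file, and the
resolved configuration is hashed into the run manifest for
reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator


class Thresholds(BaseModel):
    """Clinical cut-points. Inequality directions are fixed by the engine:
    eGFR is strictly below; every other threshold is inclusive; the
    prediabetes bands are closed intervals."""

    egfr_low: float = 60.0           # mL/min/1.73m2, qualifying values are < this
    uacr_high: float = 30.0          # mg/g, >=
    upcr_high: float = 150.0         # mg/g, >=
    hba1c_dm: float = 6.5            # %, >=
    hba1c_prediab_low: float = 5.7   # %, closed band
    hba1c_prediab_high: float = 6.4
    glucose_random_dm: float = 200.0   # mg/dL, >=
    glucose_fasting_dm: float = 126.0  # mg/dL, >=
    glucose_random_prediab_low: float = 140.0   # closed band
    glucose_random_prediab_high: float = 199.0
    glucose_fasting_prediab_low: float = 100.0  # closed band
    glucose_fasting_prediab_high: float = 125.0
    sbp_high: float = 140.0          # mm Hg, >=
    dbp_high: float = 90.0           # mm Hg, >=

    @model_validator(mode="after")
    def _sane(self) -> "Thresholds":
        for name, v in self.model_dump().items():
            if v <= 0:
                raise ValueError(f"threshold {name} must be positive, got {v}")
        if not self.hba1c_prediab_high < self.hba1c_dm:
            raise ValueError("prediabetes HbA1c band must lie strictly below the DM threshold")
        if not self.glucose_random_prediab_high < self.glucose_random_dm:
            raise ValueError("random-glucose prediabetes band must lie below the DM threshold")
        if not self.glucose_fasting_prediab_high < self.glucose_fasting_dm:
            raise ValueError("fasting-glucose prediabetes band must lie below the DM threshold")
        return self


class Windows(BaseModel):
    """Temporal-separation rules, whole days. 'At least N apart' is
    inclusive (gap >= N); the two-year cap is 730 days, ignoring leap
    days. ``bp_gap_strict`` flips the blood-pressure pair rule from
    gap >= 14 to gap > 14 (both readings appear in guideline sources)."""

    ckd_gap_min: int = 90
    bp_gap_min: int = 14
    bp_gap_strict: bool = False
    glucose_gap_min: int = 1
    glucose_gap_max: int = 730

    @model_validator(mode="after")
    def _sane(self) -> "Windows":
        if min(self.ckd_gap_min, self.bp_gap_min, self.glucose_gap_min) < 0:
            raise ValueError("window minima must be non-negative")
        if self.glucose_gap_min >= self.glucose_gap_max:
            raise ValueError("glucose_gap_min must be < glucose_gap_max")
        return self


def normalize_code(code: str) -> str:
    """ICD codes compare dotless and uppercase."""
    return code.replace(".", "").strip().upper()


class CodeLists(BaseModel):
    """Prefix lists per condition per code system (dotless, uppercase).

    These defaults are editable configuration, not authoritative truth: a
    deployment maps its own code sets here.
    """

    ckd: dict[str, list[str]] = Field(
        default_factory=lambda: {"ICD-10": ["N18"], "ICD-9": ["585"]}
    )
    htn: dict[str, list[str]] = Field(
        default_factory=lambda: {
            "ICD-10": ["I10", "I11", "I12", "I13", "I15"],
            "ICD-9": ["401", "402", "403", "404", "405"],
        }
    )
    dm: dict[str, list[str]] = Field(
        default_factory=lambda: {
            "ICD-10": ["E08", "E09", "E10", "E11", "E12", "E13"],
            "ICD-9": ["250"],
        }
    )
    prediabetes: dict[str, list[str]] = Field(
        default_factory=lambda: {"ICD-10": ["R7303"], "ICD-9": ["79029"]}
    )
    pcos: dict[str, list[str]] = Field(
        default_factory=lambda: {"ICD-10": ["E282"], "ICD-9": ["2564"]}
    )

    @model_validator(mode="after")
    def _normalize(self) -> "CodeLists":
        for cond in ("ckd", "htn", "dm", "prediabetes", "pcos"):
            lists = getattr(self, cond)
            for system, prefixes in lists.items():
                lists[system] = [normalize_code(p) for p in prefixes]
        return self


#: The seven therapeutic classes that count as anti-hyperglycemic.
ANTI_HYPERGLYCEMIC_CLASSES = frozenset(
    {
        "insulin",
        "sulfonylurea",
        "thiazolidinedione",
        "dpp4_inhibitor",
        "glp1_agonist",
        "sglt2_inhibitor",
        "metformin",
    }
)

#: Tracked but non-qualifying classes (anti-hypertensives, nephrotoxics).
OTHER_TRACKED_CLASSES = frozenset({"acei", "arb", "antihypertensive_other", "nsaid", "ppi"})


def _default_lexicon() -> dict[str, str]:
    # ingredient substring (lowercase) -> therapeutic class
    lex: dict[str, str] = {}
    for name in ("insulin", "lispro", "aspart", "glargine", "detemir", "degludec"):
        lex[name] = "insulin"
    for name in ("glipizide", "glyburide", "glimepiride", "tolbutamide"):
        lex[name] = "sulfonylurea"
    for name in ("pioglitazone", "rosiglitazone"):
        lex[name] = "thiazolidinedione"
    for name in ("sitagliptin", "saxagliptin", "linagliptin", "alogliptin"):
        lex[name] = "dpp4_inhibitor"
    for name in ("liraglutide", "exenatide", "dulaglutide", "semaglutide", "lixisenatide"):
        lex[name] = "glp1_agonist"
    for name in ("empagliflozin", "canagliflozin", "dapagliflozin", "ertugliflozin"):
        lex[name] = "sglt2_inhibitor"
    lex["metformin"] = "metformin"
    for name in ("lisinopril", "enalapril", "ramipril", "benazepril", "captopril"):
        lex[name] = "acei"
    for name in ("losartan", "valsartan", "irbesartan", "olmesartan", "telmisartan"):
        lex[name] = "arb"
    for name in ("amlodipine", "hydrochlorothiazide", "chlorthalidone", "metoprolol", "carvedilol"):
        lex[name] = "antihypertensive_other"
    for name in ("ibuprofen", "naproxen", "diclofenac", "indomethacin", "ketorolac", "celecoxib"):
        lex[name] = "nsaid"
    for name in ("omeprazole", "pantoprazole", "esomeprazole", "lansoprazole", "rabeprazole"):
        lex[name] = "ppi"
    return lex


class EgfrConfig(BaseModel):
    """Equation constants for adult (CKD-EPI 2009 creatinine) and pediatric
    (bedside Schwartz) eGFR, plus dispatch behaviour."""

    # CKD-EPI creatinine knots/exponents
    kappa_female: float = 0.7
    kappa_male: float = 0.9
    alpha_female: float = -0.329
    alpha_male: float = -0.411
    creatinine_exponent: float = -1.209
    age_base: float = 0.993
    female_multiplier: float = 1.018
    black_multiplier: float = 1.159
    scale: float = 141.0
    race_coefficient_on: bool = False
    # bedside Schwartz (height cm, creatinine mg/dL)
    schwartz_k: float = 0.413
    pediatric_age_cutoff: int = 18          # completed years; < cutoff routes to Schwartz
    height_lookback_days: int = 365         # pediatric height matching window
    discordance_tolerance: float = 0.05     # computed vs source eGFR relative gap to flag

    @model_validator(mode="after")
    def _sane(self) -> "EgfrConfig":
        for name in ("kappa_female", "kappa_male", "age_base", "female_multiplier",
                     "black_multiplier", "scale", "schwartz_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"egfr constant {name} must be positive")
        return self


class UnitMap(BaseModel):
    """Source-unit -> canonical-unit multiplicative factors per analyte.
    A factor of 1.0 marks the canonical unit itself."""

    conversions: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "serum_creatinine": {"mg/dL": 1.0, "umol/L": 1.0 / 88.4, "µmol/L": 1.0 / 88.4},
            "egfr": {"mL/min/1.73m2": 1.0},
            "uacr": {"mg/g": 1.0, "mg/mmol": 8.84},
            "upcr": {"mg/g": 1.0, "mg/mmol": 8.84},
            "hba1c": {"%": 1.0},
            "glucose_random": {"mg/dL": 1.0, "mmol/L": 18.016},
            "glucose_fasting": {"mg/dL": 1.0, "mmol/L": 18.016},
        }
    )


class GeographyConfig(BaseModel):
    """File references for the zip->RUCA crosswalk and the RUCA
    urban/rural categorization; ``None`` falls back to the bundled
    category table and no crosswalk."""

    crosswalk_path: str | None = None
    categories_path: str | None = None


class CriteriaConfig(BaseModel):
    thresholds: Thresholds = Field(default_factory=Thresholds)
    windows: Windows = Field(default_factory=Windows)
    code_lists: CodeLists = Field(default_factory=CodeLists)
    medication_lexicon: dict[str, str] = Field(default_factory=_default_lexicon)
    egfr: EgfrConfig = Field(default_factory=EgfrConfig)
    units: UnitMap = Field(default_factory=UnitMap)
    geography: GeographyConfig = Field(default_factory=GeographyConfig)
    #: allow UACR and UPCR measurements to mix within one albuminuria pair
    albuminuria_mixed_markers: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CriteriaConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def resolved_dict(self) -> dict:
        return self.model_dump(mode="json")

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
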