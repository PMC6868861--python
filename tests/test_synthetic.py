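"""Synthetic cohort generator: determinism, pattern semantics, inversion."""

import numpy as np
import pytest

from ckdcohort.config import CriteriaConfig
from ckdcohort.criteria import build_registry
from ckdcohort.egfr import compute_egfr_ckdepi
from ckdcohort.io import read_cohort
from ckdcohort.model import Sex
from ckdcohort.synthetic import (
    GeneratorConfig,
    NEAR_MISS_PATTERNS,
    PATTERN_LIBRARY,
    PatientSketch,
    QUALIFYING_PATTERNS,
    SyntheticCohort,
    generate_cohort,
    inject_pattern,
    invert_ckdepi,
    make_synthetic_crosswalk,
)


def _engine_flags_for_sketch(sketch, criteria, tmp_path):
    import pandas as pd

    cohort = SyntheticCohort(
        tables={
            "patients": pd.DataFrame(
                [dict(patient_id=sketch.pid, birth_date=sketch.birth_date.isoformat(),
                      sex=sketch.sex.value, race_ethnicity=sketch.race, zip_code="")],
            ),
            "labs": pd.DataFrame(sketch.labs, columns=["patient_id", "date", "analyte", "value", "units", "fasting"]),
            "vitals": pd.DataFrame(sketch.vitals, columns=["patient_id", "date", "systolic", "diastolic", "height_cm"]),
            "diagnoses": pd.DataFrame(sketch.diagnoses, columns=["patient_id", "date", "code_system", "code", "setting"]),
            "medications": pd.DataFrame(sketch.medications, columns=["patient_id", "date", "drug_name"]),
        },
        truth=pd.DataFrame(), crosswalk=make_synthetic_crosswalk(),
    )
    d = tmp_path / sketch.pid
    d.mkdir(exist_ok=True)
    for name, df in cohort.tables.items():
        df.to_csv(d / f"{name}.csv", index=False)
    records, rejects = read_cohort(d, criteria)
    assert not rejects, rejects
    flags, _, _ = build_registry(records, criteria)
    return flags[sketch.pid]


def _fresh_sketch(criteria, pediatric=False, seed=7):
    import datetime

    s = PatientSketch(
        pid="PX", rng=np.random.default_rng(seed), criteria=criteria,
        start=datetime.date(2006, 1, 1), span=4382,
    )
    s.birth_date = datetime.date(1997, 6, 1) if pediatric else datetime.date(1958, 3, 2)
    s.sex = Sex.MALE
    return s


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        g = GeneratorConfig(n_patients=100, seed=1)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(g).write(d1)
        generate_cohort(g).write(d2)
        for f in d1.iterdir():
            assert f.read_bytes() == (d2 / f.name).read_bytes(), f.name

    def test_different_seeds_differ(self):
        a = generate_cohort(GeneratorConfig(n_patients=50, seed=1))
        b = generate_cohort(GeneratorConfig(n_patients=50, seed=2))
        assert not a.tables["labs"].equals(b.tables["labs"])


class TestInversion:
    @pytest.mark.parametrize("target", [25.0, 45.0, 59.9, 75.0, 110.0])
    @pytest.mark.parametrize("sex", [Sex.FEMALE, Sex.MALE])
    def test_inverted_creatinine_reproduces_target_egfr(self, target, sex):
        scr = invert_ckdepi(target, 52, sex)
        assert compute_egfr_ckdepi(scr, 52, sex) == pytest.approx(target, abs=1e-4)


class TestPatterns:
    def test_unknown_pattern_is_an_error(self, config):
        with pytest.raises(ValueError, match="unknown pattern"):
            inject_pattern(_fresh_sketch(config), "nonesuch")

    @pytest.mark.parametrize("name", sorted(QUALIFYING_PATTERNS))
    def test_each_qualifying_pattern_recovers_its_flag(self, name, config, tmp_path):
        pediatric = name == "ckd_pediatric_schwartz"
        s = inject_pattern(_fresh_sketch(config, pediatric=pediatric), name)
        flags = _engine_flags_for_sketch(s, config, tmp_path)
        t = s.truth
        assert flags.in_repository
        for cond in ("ckd", "htn", "dm", "prediabetes"):
            assert getattr(flags, cond) == getattr(t, cond), cond

    @pytest.mark.parametrize("name", sorted(NEAR_MISS_PATTERNS))
    def test_each_near_miss_fails_its_target_clause(self, name, config, tmp_path):
        s = inject_pattern(_fresh_sketch(config), name)
        flags = _engine_flags_for_sketch(s, config, tmp_path)
        t = s.truth
        for attr in ("in_repository", "ckd", "htn", "dm", "prediabetes"):
            assert getattr(flags, attr) == getattr(t, attr), attr

    def test_pcos_scenarios(self, config, tmp_path):
        only = inject_pattern(_fresh_sketch(config), "pcos_metformin_only")
        f = _engine_flags_for_sketch(only, config, tmp_path)
        assert f.in_repository and not f.dm and f.pcos_excluded_dm and not f.in_registry

        with_lab = inject_pattern(_fresh_sketch(config), "pcos_metformin_with_lab")
        f2 = _engine_flags_for_sketch(with_lab, config, tmp_path)
        assert f2.dm and not f2.pcos_excluded_dm

    def test_pediatric_without_height_yields_nothing(self, config, tmp_path):
        s = inject_pattern(_fresh_sketch(config, pediatric=True), "pediatric_no_height")
        f = _engine_flags_for_sketch(s, config, tmp_path)
        assert not f.in_repository


class TestCohortAssembly:
    def test_library_coverage_guaranteed_prefix(self):
        cohort = generate_cohort(GeneratorConfig(n_patients=len(PATTERN_LIBRARY), seed=3))
        planted = set(";".join(cohort.truth["patterns"]).split(";"))
        assert planted >= set(PATTERN_LIBRARY)

    def test_truth_row_per_patient(self):
        cohort = generate_cohort(GeneratorConfig(n_patients=75, seed=4))
        assert list(cohort.truth["patient_id"]) == sorted(cohort.truth["patient_id"])
        assert len(cohort.truth) == 75

    def test_crosswalk_covers_every_secondary_code(self):
        xw = make_synthetic_crosswalk()
        assert len(set(xw["ruca_code"])) == 33

    def test_zero_patients(self):
        cohort = generate_cohort(GeneratorConfig(n_patients=0, seed=0))
        assert len(cohort.truth) == 0 and len(cohort.tables["labs"]) == 0
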