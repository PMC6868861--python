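"""Repository and registry qualification rules."""

import pytest

from ckdcohort.config import CriteriaConfig
from ckdcohort.criteria import (
    classify_medication,
    has_qualifying_pair,
    phenotype_record,
)
from ckdcohort.model import MedicationOrder, Sex

from conftest import D0, flags_of, make_record


class TestQualifyingPair:
    @pytest.mark.parametrize(
        "days, min_gap, max_gap, expected",
        [
            ([0, 90], 90, None, (0, 1)),
            ([0, 89], 90, None, None),
            ([0, 800, 805], 1, 730, (1, 2)),
            ([], 90, None, None),
            ([5], 90, None, None),
            ([0, 0], 0, None, (0, 1)),
            ([0, 50, 130], 90, None, (0, 2)),  # earliest qualifying pair
        ],
    )
    def test_examples(self, days, min_gap, max_gap, expected):
        assert has_qualifying_pair(days, min_gap, max_gap) == expected

    def test_strict_minimum(self):
        assert has_qualifying_pair([0, 14], 14, strict_min=True) is None
        assert has_qualifying_pair([0, 15], 14, strict_min=True) == (0, 1)


class TestRepository:
    def test_single_fasting_glucose_at_floor(self):
        rec = make_record(labs=[(0, "glucose_fasting", 100)])
        assert flags_of(rec).in_repository

    def test_empty_record(self):
        assert not flags_of(make_record()).in_repository

    def test_egfr_strictly_below_sixty(self):
        assert flags_of(make_record(labs=[(0, "egfr", 59.9)])).in_repository
        assert not flags_of(make_record(labs=[(0, "egfr", 60.0)])).in_repository

    def test_single_diagnosis_code_any_condition(self):
        rec = make_record(dx=[(0, "ICD-10", "I10", "outpatient")])
        assert flags_of(rec).in_repository

    def test_single_blood_pressure(self):
        assert flags_of(make_record(vitals=[(0, 140, 80)])).in_repository
        assert not flags_of(make_record(vitals=[(0, 139, 89)])).in_repository

    def test_anti_hyperglycemic_prescription(self):
        assert flags_of(make_record(meds=[(0, "Metformin 500 mg")])).in_repository
        assert not flags_of(make_record(meds=[(0, "lisinopril 10 mg")])).in_repository


class TestCkdRule:
    def test_egfr_pair_qualifies(self):
        f = flags_of(make_record(labs=[(0, "egfr", 55), (91, "egfr", 58)]))
        assert f.ckd and f.in_repository

    def test_single_low_egfr_is_repository_only(self):
        f = flags_of(make_record(labs=[(0, "egfr", 40)]))
        assert f.in_repository and not f.ckd and not f.in_registry

    def test_mixed_albuminuria_markers(self):
        rec = make_record(labs=[(0, "uacr", 35), (100, "upcr", 160)])
        assert flags_of(rec).ckd

    def test_same_marker_mode_rejects_mixed_pair(self):
        cfg = CriteriaConfig(albuminuria_mixed_markers=False)
        rec = make_record(labs=[(0, "uacr", 35), (100, "upcr", 160)])
        assert not flags_of(rec, cfg).ckd
        rec2 = make_record(labs=[(0, "uacr", 35), (100, "uacr", 40)])
        assert flags_of(rec2, cfg).ckd

    def test_dx_code_any_setting(self):
        for setting in ("inpatient", "outpatient"):
            assert flags_of(make_record(dx=[(0, "ICD-9", "585.3", setting)])).ckd

    def test_computed_egfr_feeds_rule(self, config):
        # adult creatinine high enough that CKD-EPI lands below 60 twice
        rec = make_record(
            birth="1940-01-01",
            labs=[(0, "serum_creatinine", 2.5), (120, "serum_creatinine", 2.4)],
        )
        assert flags_of(rec, config).ckd


class TestHtnRule:
    def test_pair_at_default_gap(self):
        f = flags_of(make_record(vitals=[(0, 142, 80), (14, 145, 78)]))
        assert f.htn

    def test_single_severe_reading_insufficient(self):
        f = flags_of(make_record(vitals=[(0, 180, 110)]))
        assert f.in_repository and not f.htn

    def test_dx_code_alone_qualifies(self):
        assert flags_of(make_record(dx=[(0, "ICD-10", "I10", "outpatient")])).htn

    def test_strict_gap_switch(self):
        cfg = CriteriaConfig(windows={"bp_gap_strict": True})
        rec14 = make_record(vitals=[(0, 142, 80), (14, 145, 78)])
        rec15 = make_record(vitals=[(0, 142, 80), (15, 145, 78)])
        assert not flags_of(rec14, cfg).htn
        assert flags_of(rec15, cfg).htn

    def test_diastolic_alone_can_qualify(self):
        f = flags_of(make_record(vitals=[(0, 120, 95), (30, 118, 92)]))
        assert f.htn


class TestDmRule:
    def test_single_hba1c(self):
        assert flags_of(make_record(labs=[(0, "hba1c", 6.5)])).dm

    def test_same_day_glucose_pair_fails_min_gap(self):
        rec = make_record(labs=[(0, "glucose_random", 210), (0, "glucose_random", 205)])
        f = flags_of(rec)
        assert f.in_repository and not f.dm

    def test_outpatient_codes_need_two_distinct_dates(self):
        one = make_record(dx=[(0, "ICD-10", "E11.9", "outpatient")])
        same_day = make_record(
            dx=[(0, "ICD-10", "E11.9", "outpatient"), (0, "ICD-10", "E11.65", "outpatient")]
        )
        two = make_record(
            dx=[(0, "ICD-10", "E11.9", "outpatient"), (30, "ICD-10", "E11.9", "outpatient")]
        )
        assert not flags_of(one).dm
        assert not flags_of(same_day).dm
        assert flags_of(two).dm

    def test_single_inpatient_code_suffices(self):
        assert flags_of(make_record(dx=[(0, "ICD-9", "250.00", "inpatient")])).dm

    def test_random_and_fasting_never_pool(self):
        rec = make_record(labs=[(0, "glucose_random", 210), (30, "glucose_fasting", 130)])
        assert not flags_of(rec).dm

    def test_fasting_pair_within_window(self):
        rec = make_record(labs=[(0, "glucose_fasting", 130), (30, "glucose_fasting", 127)])
        assert flags_of(rec).dm

    def test_medication_pathway(self):
        assert flags_of(make_record(meds=[(0, "insulin glargine 100 unit/mL")])).dm


class TestPrediabetesRule:
    def test_band_inclusive_both_ends(self):
        assert flags_of(make_record(labs=[(0, "hba1c", 5.7)])).prediabetes
        assert flags_of(make_record(labs=[(0, "hba1c", 6.4)])).prediabetes
        assert not flags_of(make_record(labs=[(0, "hba1c", 5.6)])).prediabetes
        assert not flags_of(make_record(labs=[(0, "hba1c", 6.5)])).prediabetes

    def test_fasting_pair_inside_window(self):
        rec = make_record(labs=[(0, "glucose_fasting", 110), (200, "glucose_fasting", 105)])
        assert flags_of(rec).prediabetes

    def test_pair_outside_two_year_cap(self):
        rec = make_record(labs=[(0, "glucose_fasting", 110), (731, "glucose_fasting", 105)])
        f = flags_of(rec)
        assert f.in_repository and not f.prediabetes

    def test_values_from_different_bands_never_combine(self):
        rec = make_record(labs=[(0, "glucose_random", 150), (30, "glucose_random", 210)])
        f = flags_of(rec)
        assert not f.prediabetes and not f.dm


class TestMedicationClassification:
    @pytest.mark.parametrize(
        "drug, expected",
        [
            ("metformin 500 mg", "metformin"),
            ("Metformin HCl ER", "metformin"),
            ("lisinopril", "acei"),
            ("ibuprofen", "nsaid"),
            ("omeprazole 20 mg", "ppi"),
            ("empagliflozin 10 mg", "sglt2_inhibitor"),
            ("mystery compound", "unclassified"),
        ],
    )
    def test_lexicon_lookup(self, drug, expected, config):
        order = MedicationOrder("P1", D0, drug)
        assert classify_medication(order, config.medication_lexicon) == expected


class TestEvidenceTrail:
    def test_qualifying_result_carries_witnesses(self, config):
        rec = make_record(labs=[(0, "egfr", 55), (91, "egfr", 58)])
        _, results, _ = phenotype_record(rec, config)
        ckd = next(r for r in results if r.condition == "ckd")
        assert ckd.pathway == "lab_pair_egfr"
        assert len(ckd.evidence) == 2 and all("egfr" in e for e in ckd.evidence)

    def test_registry_not_evaluated_for_non_repository_patient(self, config):
        rec = make_record(labs=[(0, "hba1c", 5.0)])
        _, results, _ = phenotype_record(rec, config)
        assert [r.condition for r in results] == ["repository"]
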