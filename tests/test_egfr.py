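"""Adult CKD-EPI / pediatric Schwartz estimation and age dispatch."""

import datetime

import pytest

from ckdcohort.config import CriteriaConfig, EgfrConfig
from ckdcohort.egfr import (
    DispatchError,
    EgfrInputError,
    age_in_years,
    compute_egfr_ckdepi,
    compute_egfr_schwartz,
    egfr_for_measurement,
    materialize_egfr,
)
from ckdcohort.model import Analyte, Sex

from conftest import D0, make_record


class TestCkdEpi:
    def test_female_at_knot(self):
        # at scr == kappa both ratio terms are 1: 141 * 0.993^50 * 1.018
        v = compute_egfr_ckdepi(0.7, 50, Sex.FEMALE)
        assert v == pytest.approx(141 * 0.993**50 * 1.018, rel=1e-12)
        assert v == pytest.approx(101.0, abs=0.1)

    def test_identity_case_every_factor_one(self):
        # male at the knot with zero age decay reduces to the scale constant
        params = EgfrConfig(pediatric_age_cutoff=0)
        assert compute_egfr_ckdepi(0.9, 0, Sex.MALE, params=params) == pytest.approx(141.0)

    def test_doubling_creatinine_decreases_egfr(self):
        for scr in (0.4, 0.7, 0.9, 1.5, 4.0):
            assert compute_egfr_ckdepi(2 * scr, 60, Sex.MALE) < compute_egfr_ckdepi(
                scr, 60, Sex.MALE
            )

    def test_race_coefficient_modes(self):
        base = compute_egfr_ckdepi(1.1, 55, Sex.MALE, black=True)  # default off
        on = compute_egfr_ckdepi(
            1.1, 55, Sex.MALE, black=True, params=EgfrConfig(race_coefficient_on=True)
        )
        assert on == pytest.approx(base * 1.159)

    def test_invalid_inputs(self):
        with pytest.raises(EgfrInputError):
            compute_egfr_ckdepi(0.0, 50, Sex.FEMALE)
        with pytest.raises(DispatchError):
            compute_egfr_ckdepi(1.0, 17, Sex.FEMALE)


class TestSchwartz:
    def test_direct_arithmetic(self):
        assert compute_egfr_schwartz(140, 0.5) == pytest.approx(0.413 * 140 / 0.5)
        assert compute_egfr_schwartz(140, 0.5) == pytest.approx(115.64)

    def test_k_cancels(self):
        assert compute_egfr_schwartz(100, 0.413) == pytest.approx(100.0)

    def test_limit_large_creatinine(self):
        assert compute_egfr_schwartz(140, 1e6) < 1e-3

    def test_invalid_inputs(self):
        with pytest.raises(EgfrInputError):
            compute_egfr_schwartz(0, 0.5)
        with pytest.raises(EgfrInputError):
            compute_egfr_schwartz(140, -1)


class TestDispatch:
    def test_age_convention_completed_years(self):
        b = datetime.date(2000, 5, 15)
        assert age_in_years(b, datetime.date(2018, 5, 14)) == 17
        assert age_in_years(b, datetime.date(2018, 5, 15)) == 18

    @pytest.mark.parametrize(
        "lab_day, pediatric",
        [(-1, True), (0, False)],  # day before vs day of the 18th birthday
    )
    def test_boundary_routes_to_exactly_one_equation(self, lab_day, pediatric, config):
        from ckdcohort.model import LabResult, VitalSign

        birthday18 = datetime.date(2010, 6, 1)
        lab_date = birthday18 + datetime.timedelta(days=lab_day)
        rec = make_record(birth="1992-06-01", sex=Sex.MALE)
        rec.labs = [LabResult("P1", lab_date, Analyte.SERUM_CREATININE, 1.2, "mg/dL")]
        rec.vitals = [
            VitalSign("P1", lab_date - datetime.timedelta(days=30), None, None, 170.0)
        ]
        out, msg = egfr_for_measurement(rec, rec.labs[0], config)
        assert msg is None
        if pediatric:
            assert out.value == pytest.approx(0.413 * 170.0 / 1.2)
        else:
            assert out.value == pytest.approx(compute_egfr_ckdepi(1.2, 18, Sex.MALE))

    def test_high_creatinine_adult_qualifies_downstream(self, config):
        v = compute_egfr_ckdepi(10.0, 60, Sex.MALE)
        assert v < 60

    def test_pediatric_without_height_is_logged_skip(self, config):
        rec = make_record(birth="2003-01-01", labs=[(0, "serum_creatinine", 1.0)])
        out, msg = egfr_for_measurement(rec, rec.labs[0], config)
        assert out is None and "no height" in msg

    def test_nearest_height_within_lookback(self, config):
        rec = make_record(
            birth="2003-01-01",
            labs=[(400, "serum_creatinine", 0.8)],
            vitals=[(20, None, None, 120.0), (390, None, None, 150.0)],
        )
        out, msg = egfr_for_measurement(rec, rec.labs[0], config)
        assert out.value == pytest.approx(0.413 * 150.0 / 0.8)


class TestMaterialize:
    def test_computed_wins_over_source_value_same_date(self, config):
        rec = make_record(
            birth="1950-01-01",
            labs=[(0, "serum_creatinine", 2.0), (0, "egfr", 90.0), (50, "egfr", 88.0)],
        )
        egfrs, logs = materialize_egfr(rec, config)
        assert len(egfrs) == 2
        computed = compute_egfr_ckdepi(2.0, 60, Sex.FEMALE)  # age 60 completed at D0
        assert egfrs[0].value == pytest.approx(computed)
        assert egfrs[1].value == 88.0  # source value kept on its own date
        assert any("discordant" in m for m in logs)

    def test_partition_every_creatinine_routes_once(self, config):
        rec = make_record(
            birth="2003-01-01",
            labs=[(0, "serum_creatinine", 1.0), (100, "serum_creatinine", 1.1)],
            vitals=[(95, None, None, 140.0)],
        )
        egfrs, logs = materialize_egfr(rec, config)
        assert len(egfrs) + len(logs) == 2
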