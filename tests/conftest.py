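import datetime

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from ckdcohort.config import CriteriaConfig
from ckdcohort.model import (
    Analyte,
    CodeSystem,
    DiagnosisEvent,
    LabResult,
    LongitudinalRecord,
    MedicationOrder,
    PatientDemographics,
    Setting,
    Sex,
    CANONICAL_UNITS,
)

#: anchor date for day-offset event specs in tests
D0 = datetime.date(2010, 1, 1)


def make_record(
    pid="P1",
    birth="1960-06-15",
    sex=Sex.FEMALE,
    race="unknown",
    zip_code=None,
    labs=(),
    vitals=(),
    dx=(),
    meds=(),
):
    """Compact record builder: events as day-offset tuples from D0.

    labs:   (day, analyte_name, value)
    vitals: (day, sbp, dbp) or (day, sbp, dbp, height_cm)
    dx:     (day, code_system, code, setting)
    meds:   (day, drug_name)
    """
    from ckdcohort.model import VitalSign

    rec = LongitudinalRecord(
        demographics=PatientDemographics(
            patient_id=pid,
            birth_date=datetime.date.fromisoformat(birth),
            sex=sex,
            race_ethnicity=race,
            zip_code=zip_code,
        )
    )
    for day, analyte, value in labs:
        a = Analyte(analyte)
        rec.labs.append(
            LabResult(pid, D0 + datetime.timedelta(days=day), a, float(value),
                      CANONICAL_UNITS[a])
        )
    for spec in vitals:
        day, sbp, dbp, *rest = spec
        rec.vitals.append(
            VitalSign(pid, D0 + datetime.timedelta(days=day), sbp, dbp,
                      rest[0] if rest else None)
        )
    for day, system, code, setting in dx:
        rec.diagnoses.append(
            DiagnosisEvent(pid, D0 + datetime.timedelta(days=day),
                           CodeSystem(system), code.replace(".", "").upper(),
                           Setting(setting))
        )
    for day, drug in meds:
        rec.medications.append(
            MedicationOrder(pid, D0 + datetime.timedelta(days=day), drug)
        )
    rec.sort_events()
    return rec


def flags_of(record, config=None):
    from ckdcohort.criteria import phenotype_record

    return phenotype_record(record, config or CriteriaConfig())[0]


@pytest.fixture(scope="session")
def config():
    return CriteriaConfig()
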