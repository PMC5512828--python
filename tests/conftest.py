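import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from penrisk.charts import RiskCategory, RiskChart, all_chart_keys, synthetic_chart, TC_BANDS
from penrisk.emr import Measurement, PatientRecord, Prescription, SmokingStatus

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

ENROL = dt.date(2015, 1, 15)


def make_patient(
    pid="P001",
    sex="female",
    age=55,
    enrol=ENROL,
    conditions=(),
    diabetes_type="none",
    smoking=SmokingStatus("never"),
    measurements=None,
    prescriptions=None,
    documented_scores=None,
    **kw,
):
    return PatientRecord(
        patient_id=pid,
        sex=sex,
        age=age,
        enrolment_date=enrol,
        conditions=frozenset(conditions),
        diabetes_type=diabetes_type,
        smoking=smoking,
        measurements=list(measurements or []),
        prescriptions=list(prescriptions or []),
        documented_scores=list(documented_scores or []),
        **kw,
    )


def sbp(day_offset, value, enrol=ENROL):
    return Measurement(enrol + dt.timedelta(days=day_offset), "sbp", value)


def tc(day_offset, value, enrol=ENROL):
    return Measurement(enrol + dt.timedelta(days=day_offset), "total_cholesterol", value)


def llt(day_offset, enrol=ENROL):
    return Prescription(enrol + dt.timedelta(days=day_offset), "lipid_lowering")


@pytest.fixture(scope="session")
def chart():
    """The packaged synthetic EMR-B-style chart."""
    return synthetic_chart()


@pytest.fixture(scope="session")
def constant_low_chart():
    """Degenerate chart: every cell is <10."""
    return RiskChart("constant", {k: RiskCategory.UNDER_10 for k in all_chart_keys()})


@pytest.fixture(scope="session")
def tc_rank_chart():
    """Test chart whose category equals the cholesterol band rank, so the
    calculated category is controlled directly through the TC value."""
    return RiskChart(
        "tc-rank",
        {k: RiskCategory(TC_BANDS.index(k[5])) for k in all_chart_keys()},
    )
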