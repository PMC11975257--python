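import datetime

import pytest

from cyclegate import (
    ANALYTES,
    AnalyteResult,
    CyclePlan,
    CycleRecord,
    EngineConfig,
    LabPanel,
    Questionnaire,
    SymptomReport,
    default_reference_ranges,
)

INFUSION = datetime.date(2020, 5, 15)
PATIENT = "PT000"


@pytest.fixture(scope="session")
def config() -> EngineConfig:
    return EngineConfig()


def make_questionnaire(grades, *, patient_id=PATIENT, completed_on=None, days_before=1):
    """Questionnaire from a {symptom: grade} dict, dated relative to INFUSION."""
    if completed_on is None:
        completed_on = INFUSION - datetime.timedelta(days=days_before)
    return Questionnaire(
        patient_id=patient_id,
        completed_on=completed_on,
        reports=tuple(SymptomReport(symptom=s, grade=g) for s, g in grades.items()),
    )


def make_panel(*, out_analyte=None, drop_analyte=None, patient_id=PATIENT, days_before=1):
    """Panel with midpoint values; one analyte optionally out of range or missing."""
    ranges = default_reference_ranges()
    results = []
    for analyte in ANALYTES:
        if analyte == drop_analyte:
            continue
        rng = ranges[analyte]
        if analyte == out_analyte:
            value = rng.low * 0.5 if rng.low is not None else rng.high * 1.5
        elif rng.low is not None and rng.high is not None:
            value = (rng.low + rng.high) / 2
        else:
            value = (rng.high or rng.low) / 2
        results.append(AnalyteResult(analyte=analyte, value=value))
    return LabPanel(
        patient_id=patient_id,
        sampled_on=INFUSION - datetime.timedelta(days=days_before),
        results=tuple(results),
    )


def make_record(questionnaire=None, panel=None, baseline=None, *, infusion=INFUSION):
    plan = CyclePlan(
        patient_id=PATIENT, cycle_number=1, planned_infusion_date=infusion
    )
    return CycleRecord(
        plan=plan, questionnaire=questionnaire, panel=panel, baseline=baseline
    )
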