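"""Synthetic cohorts for exercising the decision engine end to end.

Two generators live here:

* :func:`simulate_cohort` — a stochastic cohort with configurable
  questionnaire-completion probability, data-staleness probability,
  per-symptom CTCAE grade distributions, and lab out-of-range probability.
  Reproducible from its mandatory seed.

* :func:`build_reference_fixture` — a fully deterministic 43-patient,
  339-cycle cohort whose marginal counts match the reference usability
  cohort: 262 cycles with a fresh questionnaire, 221 with all symptoms at
  grade <= 1, 228 with labs in range, 843 completed questionnaires of which
  446 report fatigue and 429 report peripheral sensory neuropathy, and 137
  questionnaires carrying a grade 3-4 symptom record. Run through the
  engine it yields tier counts 145 / 83 / 111.

The joint structure of the fixture (which lab-failing cycles also have bad
questionnaires) is under-determined by the marginals alone; the canonical
assignment used here places every flagged-symptom questionnaire on a
lab-in-range cycle. Any assignment honouring the marginals produces the
same tier counts under the engine's precedence, which the test suite
asserts by rebuilding the fixture with a different stale/missing split.
"""

from __future__ import annotations

import datetime
from typing import Optional, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .engine import EngineConfig, decide
from .model import (
    ANALYTES,
    AnalyteRange,
    AnalyteResult,
    CohortLog,
    ConfigurationError,
    CyclePlan,
    CycleRecord,
    LabPanel,
    Questionnaire,
    SymptomReport,
)

GradeDistribution = tuple[float, float, float, float, float]

#: All probability mass on grade 0 — a symptom-free population.
MASS_ON_ZERO: GradeDistribution = (1.0, 0.0, 0.0, 0.0, 0.0)

#: A mild default grade mix: mostly absent, occasionally grade 1-2,
#: rarely severe — roughly the shape of chemotherapy side-effect reporting.
DEFAULT_GRADES: GradeDistribution = (0.55, 0.25, 0.15, 0.04, 0.01)


def _check_distribution(dist: tuple[float, ...]) -> None:
    if len(dist) != 5:
        raise ConfigurationError("grade distribution needs 5 probabilities (grades 0-4)")
    if any(p < 0 for p in dist):
        raise ConfigurationError("grade distribution has negative mass")
    if abs(sum(dist) - 1.0) > 1e-9:
        raise ConfigurationError("grade distribution must sum to 1")


class SimulationParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(ge=1)
    #: Fixed count, or an inclusive (low, high) range sampled per patient.
    cycles_per_patient: Union[int, tuple[int, int]] = 6
    p_questionnaire_completed: float = Field(default=1.0, ge=0.0, le=1.0)
    p_stale_given_completed: float = Field(default=0.0, ge=0.0, le=1.0)
    p_lab_out_of_range: float = Field(default=0.0, ge=0.0, le=1.0)
    default_grade_distribution: GradeDistribution = DEFAULT_GRADES
    grade_distributions: dict[str, GradeDistribution] = {}
    rng_seed: int

    @model_validator(mode="after")
    def _check(self) -> "SimulationParams":
        _check_distribution(self.default_grade_distribution)
        for dist in self.grade_distributions.values():
            _check_distribution(dist)
        if isinstance(self.cycles_per_patient, tuple):
            lo, hi = self.cycles_per_patient
            if not (1 <= lo <= hi):
                raise ConfigurationError("cycles_per_patient range must satisfy 1 <= low <= high")
        elif self.cycles_per_patient < 1:
            raise ConfigurationError("cycles_per_patient must be >= 1")
        return self


_STUDY_START = datetime.date(2020, 1, 6)
_CYCLE_INTERVAL_DAYS = 14


def _in_range_value(rng_def: AnalyteRange) -> float:
    if rng_def.low is not None and rng_def.high is not None:
        return (rng_def.low + rng_def.high) / 2.0
    if rng_def.high is not None:
        return rng_def.high / 2.0
    if rng_def.low is not None:
        return rng_def.low * 1.5
    return 1.0


def _out_of_range_value(rng_def: AnalyteRange) -> float:
    # prefer a low excursion (cytopenia-style) where a lower bound exists
    if rng_def.low is not None:
        return rng_def.low * 0.5
    if rng_def.high is not None:
        return rng_def.high * 1.5
    raise ConfigurationError("cannot place a value outside an unbounded range")


def _panel(
    patient_id: str,
    sampled_on: datetime.date,
    config: EngineConfig,
    out_analyte: Optional[str] = None,
) -> LabPanel:
    results = []
    for analyte in ANALYTES:
        rng_def = config.ranges[analyte]
        value = (
            _out_of_range_value(rng_def) if analyte == out_analyte else _in_range_value(rng_def)
        )
        results.append(AnalyteResult(analyte=analyte, value=value))
    return LabPanel(patient_id=patient_id, sampled_on=sampled_on, results=tuple(results))


def _zero_baseline(patient_id: str, on: datetime.date, config: EngineConfig) -> Questionnaire:
    reports = tuple(SymptomReport(symptom=s, grade=0) for s in config.catalog.symptoms)
    return Questionnaire(patient_id=patient_id, completed_on=on, reports=reports)


def simulate_cohort(
    params: SimulationParams, config: EngineConfig = EngineConfig()
) -> CohortLog:
    """Draw a synthetic cohort and run the engine over every cycle.

    Per cycle: a lab panel is sampled one day before the planned infusion,
    with probability ``p_lab_out_of_range`` one uniformly chosen analyte is
    placed outside its reference bound; with probability
    ``p_questionnaire_completed`` a questionnaire exists, whose per-symptom
    grades are drawn from the configured categorical distributions, and
    which with probability ``p_stale_given_completed`` is back-dated past
    the engine's freshness window. Baselines are symptom-free (all grade 0)
    pre-study questionnaires, one per patient. Identical seeds yield
    identical cohorts.
    """
    rng = np.random.default_rng(params.rng_seed)
    symbols = config.catalog.symptoms
    dists = {
        s: np.asarray(params.grade_distributions.get(s, params.default_grade_distribution))
        for s in symbols
    }

    records: list[CycleRecord] = []
    questionnaires: list[Questionnaire] = []
    for p in range(params.n_patients):
        patient_id = f"SIM{p:04d}"
        if isinstance(params.cycles_per_patient, tuple):
            lo, hi = params.cycles_per_patient
            n_cycles = int(rng.integers(lo, hi + 1))
        else:
            n_cycles = params.cycles_per_patient
        first_infusion = _STUDY_START + datetime.timedelta(days=int(p % 7))
        baseline = _zero_baseline(
            patient_id, first_infusion - datetime.timedelta(days=10), config
        )
        for c in range(n_cycles):
            infusion = first_infusion + datetime.timedelta(days=c * _CYCLE_INTERVAL_DAYS)
            plan = CyclePlan(
                patient_id=patient_id,
                cycle_number=c + 1,
                planned_infusion_date=infusion,
                regimen_label="oxaliplatin-doublet",
            )
            out_analyte = None
            if rng.random() < params.p_lab_out_of_range:
                out_analyte = ANALYTES[int(rng.integers(0, len(ANALYTES)))]
            panel = _panel(
                patient_id, infusion - datetime.timedelta(days=1), config, out_analyte
            )
            questionnaire = None
            if rng.random() < params.p_questionnaire_completed:
                stale = rng.random() < params.p_stale_given_completed
                completed_on = infusion - datetime.timedelta(
                    days=(config.max_age_days + 2) if stale else 1
                )
                reports = tuple(
                    SymptomReport(symptom=s, grade=int(rng.choice(5, p=dists[s])))
                    for s in symbols
                )
                questionnaire = Questionnaire(
                    patient_id=patient_id, completed_on=completed_on, reports=reports
                )
                questionnaires.append(questionnaire)
            records.append(
                CycleRecord(
                    plan=plan, questionnaire=questionnaire, panel=panel, baseline=baseline
                )
            )

    decisions = tuple(decide(r, config) for r in records)
    return CohortLog(
        records=tuple(records), decisions=decisions, questionnaires=tuple(questionnaires)
    )


# ---------------------------------------------------------------------------
# deterministic reference fixture
# ---------------------------------------------------------------------------

_N_PATIENTS = 43
_N_CYCLES = 339
_N_QUESTIONNAIRES = 843
_N_FATIGUE = 446
_N_NEUROPATHY = 429

# cycle categories: (lab status, questionnaire status)
_GO = "go"                    # labs in range, fresh questionnaire, all grades <= 1
_FLAG = "flag"                # labs in range, fresh questionnaire, nausea grade 2 above baseline
_STALE_IN = "stale_in"        # labs in range, questionnaire older than the freshness window
_MISSING_IN = "missing_in"    # labs in range, no questionnaire
_OK_OUT = "ok_out"            # one analyte out of range, fresh benign questionnaire
_STALE_OUT = "stale_out"      # one analyte out of range, stale questionnaire
_MISSING_OUT = "missing_out"  # one analyte out of range, no questionnaire

_FRESH = (_GO, _FLAG, _OK_OUT)
_STALE = (_STALE_IN, _STALE_OUT)
_LAB_OUT = (_OK_OUT, _STALE_OUT, _MISSING_OUT)

# symptoms eligible for the grade-3 embedding in interim questionnaires
_EMBED_SYMPTOMS = (
    "blood_in_urine", "dysuria", "eye_symptoms", "pain", "constipation",
    "cough", "decreased_appetite", "fever", "mouth_sores", "nausea",
    "rash_or_skin_changes", "shortness_of_breath", "vomiting",
)


def _fixture_categories(
    stale_in: int, missing_in: int, stale_out: int, missing_out: int
) -> list[str]:
    """The 339 per-cycle categories, deterministically interleaved."""
    if stale_in + missing_in != 42 or stale_out + missing_out != 35:
        raise ConfigurationError(
            "fixture splits must keep 42 non-fresh lab-in and 35 non-fresh lab-out cycles"
        )
    labels = (
        [_GO] * 145
        + [_FLAG] * 41
        + [_STALE_IN] * stale_in
        + [_MISSING_IN] * missing_in
        + [_OK_OUT] * 76
        + [_STALE_OUT] * stale_out
        + [_MISSING_OUT] * missing_out
    )
    order = np.random.default_rng(20200106).permutation(_N_CYCLES)
    return [labels[i] for i in order]


def _questionnaire_reports(i: int, extras: dict[str, int]) -> tuple[SymptomReport, ...]:
    """Reports for global questionnaire index ``i`` (0-based over all 843)."""
    grades: dict[str, int] = {}
    if i < _N_FATIGUE:
        grades["fatigue"] = 1
    if i >= _N_QUESTIONNAIRES - _N_NEUROPATHY:
        grades["peripheral_sensory_neuropathy"] = 1
    grades.update(extras)
    return tuple(SymptomReport(symptom=s, grade=g) for s, g in sorted(grades.items()))


def _build_fixture(
    config: EngineConfig,
    stale_in: int = 21,
    missing_in: int = 21,
    stale_out: int = 17,
    missing_out: int = 18,
) -> CohortLog:
    categories = _fixture_categories(stale_in, missing_in, stale_out, missing_out)
    n_completed_linked = 262 + stale_in + stale_out
    n_interim = _N_QUESTIONNAIRES - n_completed_linked

    # grade 3-4 embedding in interim questionnaires: 137 questionnaires, each
    # carrying exactly one grade 3-4 record; diarrhea in 5, neuropathy in 4,
    # the remaining 128 spread round-robin over the other symptoms
    interim_extras: dict[int, dict[str, int]] = {}
    for j in range(5):
        interim_extras[j] = {"diarrhea": 3}
    for k in range(128):
        interim_extras[5 + k] = {_EMBED_SYMPTOMS[k % len(_EMBED_SYMPTOMS)]: 3}
    # the four neuropathy grade-4 records upgrade questionnaires that already
    # report neuropathy (the tail of the global index range), so the
    # neuropathy-reporting total stays at 429
    for j in range(n_interim - 4, n_interim):
        interim_extras[j] = {"peripheral_sensory_neuropathy": 4}

    records: list[CycleRecord] = []
    questionnaires: list[Questionnaire] = []
    q_index = 0  # global questionnaire index, cycle-linked ones first

    def _next_questionnaire(
        patient_id: str, completed_on: datetime.date, extras: dict[str, int]
    ) -> Questionnaire:
        nonlocal q_index
        q = Questionnaire(
            patient_id=patient_id,
            completed_on=completed_on,
            reports=_questionnaire_reports(q_index, extras),
        )
        q_index += 1
        questionnaires.append(q)
        return q

    g = 0
    patient_ids = [f"PT{p:03d}" for p in range(_N_PATIENTS)]
    for p, patient_id in enumerate(patient_ids):
        n_cycles = 8 if p < _N_CYCLES - 7 * _N_PATIENTS else 7  # 38 patients x8, 5 x7
        first_infusion = _STUDY_START + datetime.timedelta(days=p)
        baseline = _zero_baseline(
            patient_id, first_infusion - datetime.timedelta(days=10), config
        )
        for c in range(n_cycles):
            infusion = first_infusion + datetime.timedelta(days=c * _CYCLE_INTERVAL_DAYS)
            category = categories[g]
            out_analyte = ANALYTES[g % len(ANALYTES)] if category in _LAB_OUT else None
            panel = _panel(
                patient_id, infusion - datetime.timedelta(days=1), config, out_analyte
            )
            questionnaire = None
            if category in _FRESH:
                extras = {"nausea": 2} if category == _FLAG else {}
                questionnaire = _next_questionnaire(
                    patient_id, infusion - datetime.timedelta(days=1), extras
                )
            elif category in _STALE:
                questionnaire = _next_questionnaire(
                    patient_id,
                    infusion - datetime.timedelta(days=config.max_age_days + 1),
                    {},
                )
            records.append(
                CycleRecord(
                    plan=CyclePlan(
                        patient_id=patient_id,
                        cycle_number=c + 1,
                        planned_infusion_date=infusion,
                        regimen_label="oxaliplatin-doublet",
                    ),
                    questionnaire=questionnaire,
                    panel=panel,
                    baseline=baseline,
                )
            )
            g += 1

    # interim questionnaires: completed between cycles, not attached to any
    # planned cycle; they carry the rest of the symptom-prevalence mass
    for j in range(n_interim):
        patient_id = patient_ids[j % _N_PATIENTS]
        completed_on = datetime.date(2020, 2, 3) + datetime.timedelta(days=(j // _N_PATIENTS) * 7)
        _next_questionnaire(patient_id, completed_on, interim_extras.get(j, {}))

    assert q_index == _N_QUESTIONNAIRES
    decisions = tuple(decide(r, config) for r in records)
    return CohortLog(
        records=tuple(records), decisions=decisions, questionnaires=tuple(questionnaires)
    )


def build_reference_fixture(config: EngineConfig = EngineConfig()) -> CohortLog:
    """The deterministic 339-cycle reference cohort (see module docstring)."""
    return _build_fixture(config)
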