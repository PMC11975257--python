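"""Domain types shared by every module.

The types here carry structure (fields, required-ness, JSON round-tripping);
clinical-domain invariants (CTCAE grade bounds, analyte membership,
duplicate detection, patient-id consistency) are checked by
:func:`validate_record`, which reports findings instead of raising so that
malformed input can be surfaced in bulk to the care team rather than
aborting on the first defect.
"""

from __future__ import annotations

import datetime
import math
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, model_validator

#: The seven blood analytes screened before each cycle: bone-marrow
#: function (red cells, white cells, platelets), liver function
#: (transaminases, bilirubin) and kidney function (creatinine).
ANALYTES: tuple[str, ...] = (
    "rbc",
    "wbc",
    "thrombocytes",
    "alt",
    "ast",
    "bilirubin",
    "creatinine",
)

#: Default symptom catalog: the core chemotherapy side-effect symptoms
#: assessed by the patient questionnaire, as lowercase slugs.
DEFAULT_SYMPTOMS: tuple[str, ...] = (
    "blood_in_urine",
    "dysuria",
    "eye_symptoms",
    "peripheral_sensory_neuropathy",
    "pain",
    "constipation",
    "cough",
    "decreased_appetite",
    "diarrhea",
    "fatigue",
    "fever",
    "mouth_sores",
    "nausea",
    "rash_or_skin_changes",
    "shortness_of_breath",
    "vomiting",
)

GRADE_MIN, GRADE_MAX = 0, 4

TIERS = (1, 2, 3)

# Rationale codes emitted by the decision engine.
LABS_OUT_OF_RANGE = "LABS_OUT_OF_RANGE"
LABS_MISSING = "LABS_MISSING"
LABS_STALE = "LABS_STALE"
EPRO_MISSING = "EPRO_MISSING"
EPRO_STALE = "EPRO_STALE"
SYMPTOM_GE2_ABOVE_BASELINE = "SYMPTOM_GE2_ABOVE_BASELINE"
ALL_CLEAR = "ALL_CLEAR"


class ConfigurationError(ValueError):
    """A declarative configuration document is malformed."""


class _Model(BaseModel):
    model_config = ConfigDict(frozen=True)


class SymptomCatalog(_Model):
    """Ordered, unique list of symptom identifiers the questionnaire asks about."""

    symptoms: tuple[str, ...] = DEFAULT_SYMPTOMS

    @model_validator(mode="after")
    def _check(self) -> "SymptomCatalog":
        if not self.symptoms:
            raise ConfigurationError("symptom catalog must not be empty")
        if len(set(self.symptoms)) != len(self.symptoms):
            raise ConfigurationError("symptom catalog contains duplicates")
        return self

    def __contains__(self, symptom: object) -> bool:
        return symptom in self.symptoms

    def index(self, symptom: str) -> int:
        return self.symptoms.index(symptom)


class SymptomReport(_Model):
    """One symptom graded on the NCI-CTCAE 0-4 severity scale."""

    symptom: str
    grade: int


class Questionnaire(_Model):
    """A completed patient symptom questionnaire (the ePRO record)."""

    patient_id: str
    completed_on: datetime.date
    reports: tuple[SymptomReport, ...]

    def grade_of(self, symptom: str) -> int:
        """Grade reported for ``symptom``; 0 when the symptom is absent."""
        for r in self.reports:
            if r.symptom == symptom:
                return r.grade
        return 0

    def reported_symptoms(self) -> tuple[str, ...]:
        return tuple(r.symptom for r in self.reports)


class AnalyteResult(_Model):
    analyte: str
    value: float


class LabPanel(_Model):
    """A timestamped peripheral-blood panel for one patient."""

    patient_id: str
    sampled_on: datetime.date
    results: tuple[AnalyteResult, ...]

    def value_of(self, analyte: str) -> Optional[float]:
        for r in self.results:
            if r.analyte == analyte:
                return r.value
        return None


class AnalyteRange(_Model):
    """Inclusive reference interval for one analyte; ``None`` = unbounded."""

    low: Optional[float] = None
    high: Optional[float] = None
    unit: str = ""


class ReferenceRangeSet(_Model):
    """Per-analyte reference intervals; must cover all seven analytes.

    Bounds are inclusive, following the convention for clinical reference
    intervals. A malformed interval (low > high) is rejected at
    construction because no decision may be computed against it.
    """

    ranges: dict[str, AnalyteRange]

    @model_validator(mode="after")
    def _check(self) -> "ReferenceRangeSet":
        missing = [a for a in ANALYTES if a not in self.ranges]
        if missing:
            raise ConfigurationError(f"reference ranges missing analytes: {missing}")
        unknown = [a for a in self.ranges if a not in ANALYTES]
        if unknown:
            raise ConfigurationError(f"reference ranges for unknown analytes: {unknown}")
        for name, rng in self.ranges.items():
            if rng.low is not None and rng.high is not None and rng.low > rng.high:
                raise ConfigurationError(f"range for {name}: low > high")
        return self

    def __getitem__(self, analyte: str) -> AnalyteRange:
        return self.ranges[analyte]


def default_reference_ranges() -> ReferenceRangeSet:
    """Illustrative adult reference intervals.

    These are textbook-style values shipped as a usable default; any real
    deployment must configure the institution's own prespecified bounds
    (typically derived from the summary of product characteristics of the
    regimen in use).
    """
    mk = lambda low, high, unit: AnalyteRange(low=low, high=high, unit=unit)
    return ReferenceRangeSet(
        ranges={
            "rbc": mk(3.5, 6.0, "10^12/L"),
            "wbc": mk(3.0, 11.0, "10^9/L"),
            "thrombocytes": mk(100.0, 450.0, "10^9/L"),
            "alt": mk(None, 50.0, "U/L"),
            "ast": mk(None, 45.0, "U/L"),
            "bilirubin": mk(None, 21.0, "umol/L"),
            "creatinine": mk(45.0, 100.0, "umol/L"),
        }
    )


class CyclePlan(_Model):
    """One planned chemotherapy administration."""

    patient_id: str
    cycle_number: int
    planned_infusion_date: datetime.date
    regimen_label: str = ""
    #: Cycle number of an earlier reservation this plan is merged into
    #: (e.g. an ambulatory-pump removal appointment); linked plans do not
    #: generate their own collection events.
    linked_to: Optional[int] = None


class CycleRecord(_Model):
    """The join the decision engine consumes: plan + latest data + baseline."""

    plan: CyclePlan
    questionnaire: Optional[Questionnaire] = None
    panel: Optional[LabPanel] = None
    baseline: Optional[Questionnaire] = None


class TierRecommendation(_Model):
    """Engine output: tier 1 (green/go), 2 (yellow/evaluate), 3 (red/postpone).

    An override never erases the engine's own tier and rationale — the
    original recommendation is the audit trail; :func:`~cyclegate.engine.effective_tier`
    resolves which tier governs downstream scheduling.
    """

    tier: int
    rationale: tuple[str, ...]
    flagged_symptoms: tuple[str, ...] = ()
    overridden_tier: Optional[int] = None
    override_note: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "TierRecommendation":
        if self.tier not in TIERS:
            raise ValueError(f"tier must be one of {TIERS}")
        if not self.rationale:
            raise ValueError("rationale must not be empty")
        if self.tier == 1 and tuple(self.rationale) != (ALL_CLEAR,):
            raise ValueError("tier 1 requires rationale == (ALL_CLEAR,)")
        if self.overridden_tier is not None and self.overridden_tier not in TIERS:
            raise ValueError(f"overridden_tier must be one of {TIERS}")
        return self


AlertTrigger = Literal["GRADE_GE3", "RISE_FROM_0"]


class AlertEvent(_Model):
    """An urgency alert to the study physician."""

    patient_id: str
    symptom: str
    grade: int
    trigger: AlertTrigger
    raised_on: datetime.date

    @model_validator(mode="after")
    def _check(self) -> "AlertEvent":
        if self.trigger == "GRADE_GE3" and self.grade < 3:
            raise ValueError("GRADE_GE3 alert requires grade >= 3")
        if self.trigger == "RISE_FROM_0" and self.grade < 2:
            raise ValueError("RISE_FROM_0 alert requires grade >= 2")
        return self


class CohortLog(_Model):
    """Cycle records with their decisions, plus every completed questionnaire.

    ``questionnaires`` carries all completed questionnaires in the cohort,
    including interim ones not attached to any planned cycle; it is the
    denominator for symptom-prevalence summaries.
    """

    records: tuple[CycleRecord, ...] = ()
    decisions: tuple[TierRecommendation, ...] = ()
    questionnaires: tuple[Questionnaire, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "CohortLog":
        if self.decisions and len(self.decisions) != len(self.records):
            raise ValueError("decisions must be empty or parallel to records")
        return self


class Finding(_Model):
    """One validation finding: the offending field and the violated rule."""

    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.field}: {self.rule}"


def _validate_questionnaire(
    q: Questionnaire, catalog: SymptomCatalog, prefix: str, out: list[Finding]
) -> None:
    if not q.reports:
        out.append(Finding(field=f"{prefix}.reports", rule="questionnaire has zero reports"))
    seen: set[str] = set()
    for i, r in enumerate(q.reports):
        loc = f"{prefix}.reports[{i}]"
        if r.symptom in seen:
            out.append(Finding(field=loc, rule=f"duplicate symptom {r.symptom!r}"))
        seen.add(r.symptom)
        if r.symptom not in catalog:
            out.append(Finding(field=loc, rule=f"symptom {r.symptom!r} not in catalog"))
        if not (GRADE_MIN <= r.grade <= GRADE_MAX):
            out.append(Finding(field=loc, rule=f"grade out of {GRADE_MIN}-{GRADE_MAX}"))


def validate_record(
    record: CycleRecord, catalog: SymptomCatalog, ranges: ReferenceRangeSet
) -> list[Finding]:
    """Check every domain invariant of ``record``; empty list means valid.

    Pure and total: never mutates its input and never raises on bad data —
    each problem becomes a :class:`Finding` naming the field and the rule.
    """
    out: list[Finding] = []
    if record.plan.cycle_number < 1:
        out.append(Finding(field="plan.cycle_number", rule="cycle_number must be >= 1"))
    for name, q in (("questionnaire", record.questionnaire), ("baseline", record.baseline)):
        if q is None:
            continue
        if q.patient_id != record.plan.patient_id:
            out.append(
                Finding(field=f"{name}.patient_id", rule="does not match plan.patient_id")
            )
        _validate_questionnaire(q, catalog, name, out)
    panel = record.panel
    if panel is not None:
        if panel.patient_id != record.plan.patient_id:
            out.append(Finding(field="panel.patient_id", rule="does not match plan.patient_id"))
        seen: set[str] = set()
        for i, r in enumerate(panel.results):
            loc = f"panel.results[{i}]"
            if r.analyte in seen:
                out.append(Finding(field=loc, rule=f"duplicate analyte {r.analyte!r}"))
            seen.add(r.analyte)
            if r.analyte not in ANALYTES:
                out.append(Finding(field=loc, rule=f"unknown analyte {r.analyte!r}"))
            if not math.isfinite(r.value) or r.value < 0:
                out.append(Finding(field=loc, rule="value must be finite and >= 0"))
    return out
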