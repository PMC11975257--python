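"""Questionnaire grading, baseline comparison, and urgency alerts.

Grades follow the NCI-CTCAE 0-4 severity scale. The mapping from raw
questionnaire answers to grades is configuration (a :class:`GradingRubric`),
not code: each deployment declares an ordered rule list per symptom and the
first matching rule wins. The default rubric is the identity on
already-graded integer input.

Two urgency rules fire alerts to the study physician:

* ``GRADE_GE3`` — any symptom currently at grade 3 or higher;
* ``RISE_FROM_0`` — a symptom that rose from grade 0 at the previous
  questionnaire to grade 2 now (grade >= 3 is already covered by the first
  rule, so no duplicate alert is emitted for the same symptom).
"""

from __future__ import annotations

import datetime
from typing import Literal, Mapping, Optional, Union

from pydantic import BaseModel, ConfigDict, model_validator

from .model import (
    GRADE_MAX,
    GRADE_MIN,
    AlertEvent,
    ConfigurationError,
    Questionnaire,
    SymptomCatalog,
    SymptomReport,
)

Answer = Union[str, int]


class GradingError(ValueError):
    """Raw answers could not be graded; names the offending symptom."""

    def __init__(self, symptom: str, message: str):
        self.symptom = symptom
        super().__init__(f"{symptom}: {message}")


class RubricRule(BaseModel):
    model_config = ConfigDict(frozen=True)

    answer: Answer
    grade: int

    @model_validator(mode="after")
    def _check(self) -> "RubricRule":
        if not (GRADE_MIN <= self.grade <= GRADE_MAX):
            raise ConfigurationError(f"rubric grade {self.grade} out of 0-4")
        return self


class GradingRubric(BaseModel):
    """Per-symptom ordered (answer -> grade) rules; first match wins.

    An empty ``rules`` mapping is the identity rubric: answers must already
    be integers 0-4 and are taken as the grade directly.
    """

    model_config = ConfigDict(frozen=True)

    rules: dict[str, tuple[RubricRule, ...]] = {}

    def grade(self, symptom: str, answer: Answer) -> int:
        symptom_rules = self.rules.get(symptom)
        if symptom_rules is None:
            # identity rubric for symptoms without declared rules
            if isinstance(answer, bool) or not isinstance(answer, int):
                raise GradingError(symptom, f"no rubric rules and answer {answer!r} is not a grade")
            if not (GRADE_MIN <= answer <= GRADE_MAX):
                raise GradingError(symptom, f"grade {answer} out of {GRADE_MIN}-{GRADE_MAX}")
            return answer
        for rule in symptom_rules:
            if rule.answer == answer:
                return rule.grade
        raise GradingError(symptom, f"answer {answer!r} matches no rubric rule")


IDENTITY_RUBRIC = GradingRubric()


def grade_questionnaire(
    raw_answers: Mapping[str, Answer],
    rubric: GradingRubric = IDENTITY_RUBRIC,
    *,
    patient_id: str,
    completed_on: datetime.date,
    catalog: Optional[SymptomCatalog] = None,
) -> Questionnaire:
    """Grade raw per-symptom answers into a :class:`Questionnaire`.

    Unanswered symptoms are simply absent from the result — absence is not
    grade 0, it is missing data. Unknown symptoms (when a catalog is given)
    or answers matching no rubric rule raise :class:`GradingError` naming
    the symptom.
    """
    reports = []
    for symptom, answer in raw_answers.items():
        if catalog is not None and symptom not in catalog:
            raise GradingError(symptom, "not in symptom catalog")
        reports.append(SymptomReport(symptom=symptom, grade=rubric.grade(symptom, answer)))
    return Questionnaire(
        patient_id=patient_id, completed_on=completed_on, reports=tuple(reports)
    )


def max_grade(q: Questionnaire) -> int:
    """Maximum CTCAE grade over all reports (0 when everything is grade 0)."""
    return max((r.grade for r in q.reports), default=0)


BaselineComparison = Literal["exceeds", "exempt_if_present"]


def flags_above_baseline(
    current: Questionnaire,
    baseline: Optional[Questionnaire],
    *,
    comparison: BaselineComparison = "exceeds",
) -> set[str]:
    """Symptoms at grade >= 2 now that are worse than at baseline.

    A symptom absent from the baseline (or a missing baseline altogether)
    counts as baseline grade 0. Under the default ``exceeds`` comparison a
    symptom flags when its current grade is >= 2 and strictly above its
    baseline grade, so a chronic baseline grade-2 symptom does not flag but
    its worsening to 3-4 does. ``exempt_if_present`` is the stricter
    exemption: any symptom already >= 2 at baseline never flags, however
    far it worsens.
    """
    flagged: set[str] = set()
    for r in current.reports:
        if r.grade < 2:
            continue
        base = baseline.grade_of(r.symptom) if baseline is not None else 0
        if comparison == "exempt_if_present" and base >= 2:
            continue
        if r.grade > base:
            flagged.add(r.symptom)
    return flagged


RiseRule = Literal["from_zero", "any_rise_ge2"]


def detect_alerts(
    current: Questionnaire,
    previous: Optional[Questionnaire] = None,
    *,
    catalog: SymptomCatalog = SymptomCatalog(),
    rise_rule: RiseRule = "from_zero",
) -> list[AlertEvent]:
    """Urgency alerts for one questionnaire, at most one per symptom.

    ``GRADE_GE3`` fires for every symptom currently at grade >= 3.
    ``RISE_FROM_0`` fires for a symptom at grade 2 whose previous grade was
    exactly 0 (``from_zero``, the default) or that rose by >= 2 grades
    (``any_rise_ge2``). Without a previous questionnaire no rise can be
    established, so only ``GRADE_GE3`` can fire. Alerts are ordered by
    catalog position; off-catalog symptoms follow in report order.
    """
    alerts: list[AlertEvent] = []
    order = {s: i for i, s in enumerate(catalog.symptoms)}
    reports = sorted(
        current.reports, key=lambda r: (order.get(r.symptom, len(order)), r.symptom)
    )
    for r in reports:
        if r.grade >= 3:
            alerts.append(
                AlertEvent(
                    patient_id=current.patient_id,
                    symptom=r.symptom,
                    grade=r.grade,
                    trigger="GRADE_GE3",
                    raised_on=current.completed_on,
                )
            )
        elif r.grade == 2 and previous is not None:
            prev = previous.grade_of(r.symptom)
            rose = prev == 0 if rise_rule == "from_zero" else r.grade - prev >= 2
            if rose:
                alerts.append(
                    AlertEvent(
                        patient_id=current.patient_id,
                        symptom=r.symptom,
                        grade=r.grade,
                        trigger="RISE_FROM_0",
                        raised_on=current.completed_on,
                    )
                )
    return alerts
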