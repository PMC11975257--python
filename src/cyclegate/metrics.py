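"""Performance and symptom-prevalence summaries over a cohort log.

Percentages are reported to one decimal place, rounded half away from zero
(so 262/339 prints as 77.3 and 83/339 as 24.5). The performance table
answers, per cycle: was a fresh questionnaire available, were all symptoms
at grade <= 1, were the labs in range, and which tier did the engine assign.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict

from .engine import EngineConfig
from .grading import max_grade
from .labs import IN_RANGE, evaluate_panel, is_fresh
from .model import CohortLog, Questionnaire, SymptomCatalog


def round_percent(count: int, denominator: int) -> float:
    """``100 * count / denominator`` rounded half-away-from-zero, one decimal."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    pct = Decimal(100 * count) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class PerformanceReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_cycles: int
    n_fresh_questionnaire: int
    pct_fresh_questionnaire: Optional[float]
    n_symptoms_acceptable: int
    pct_symptoms_acceptable: Optional[float]
    n_labs_acceptable: int
    pct_labs_acceptable: Optional[float]
    tier_counts: dict[int, int]
    tier_pcts: dict[int, Optional[float]]


class SymptomPrevalence(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_reporting: int          # questionnaires with the symptom at grade >= 1
    pct_reporting: float      # of all completed questionnaires
    n_grade34: int            # individual records at grade 3-4
    pct_grade34: Optional[float]  # of all grade 3-4 records


class PrevalenceReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_questionnaires: int
    n_grade34_records: int
    symptoms: dict[str, SymptomPrevalence]


def performance(log: CohortLog, config: EngineConfig = EngineConfig()) -> PerformanceReport:
    """Tier counts and data-availability metrics for a decided cohort.

    Freshness uses the same rule as the engine (questionnaire age relative
    to the planned infusion date, at most ``config.max_age_days`` days).
    An empty log yields zero counts with absent percentages.
    """
    n = len(log.records)
    fresh = 0
    acceptable = 0
    labs_ok = 0
    for record in log.records:
        q = record.questionnaire
        q_fresh = q is not None and is_fresh(
            q.completed_on, record.plan.planned_infusion_date, config.max_age_days
        )
        if q_fresh:
            fresh += 1
            if max_grade(q) <= 1:  # type: ignore[arg-type]
                acceptable += 1
        if record.panel is not None:
            if evaluate_panel(record.panel, config.ranges).overall == IN_RANGE:
                labs_ok += 1
    tier_counts = {t: 0 for t in (1, 2, 3)}
    for d in log.decisions:
        tier_counts[d.tier] += 1
    pct = (lambda c: round_percent(c, n)) if n else (lambda c: None)
    return PerformanceReport(
        n_cycles=n,
        n_fresh_questionnaire=fresh,
        pct_fresh_questionnaire=pct(fresh),
        n_symptoms_acceptable=acceptable,
        pct_symptoms_acceptable=pct(acceptable),
        n_labs_acceptable=labs_ok,
        pct_labs_acceptable=pct(labs_ok),
        tier_counts=tier_counts,
        tier_pcts={t: pct(c) for t, c in tier_counts.items()},
    )


def prevalence(
    questionnaires: Sequence[Questionnaire], catalog: SymptomCatalog = SymptomCatalog()
) -> PrevalenceReport:
    """Per-symptom reporting frequency and grade 3-4 burden.

    A questionnaire "reports" a symptom when its grade is >= 1 (grade 0
    entries denote the symptom's absence). The reporting denominator is the
    number of completed questionnaires; the grade 3-4 denominator is the
    total number of grade 3-4 symptom records. Ordering of the input is
    irrelevant.
    """
    n_q = len(questionnaires)
    reporting = {s: 0 for s in catalog.symptoms}
    grade34 = {s: 0 for s in catalog.symptoms}
    for q in questionnaires:
        for r in q.reports:
            if r.symptom not in reporting:
                continue
            if r.grade >= 1:
                reporting[r.symptom] += 1
            if r.grade >= 3:
                grade34[r.symptom] += 1
    total34 = sum(grade34.values())
    symptoms = {}
    if n_q:
        for s in catalog.symptoms:
            symptoms[s] = SymptomPrevalence(
                n_reporting=reporting[s],
                pct_reporting=round_percent(reporting[s], n_q),
                n_grade34=grade34[s],
                pct_grade34=round_percent(grade34[s], total34) if total34 else None,
            )
    return PrevalenceReport(
        n_questionnaires=n_q, n_grade34_records=total34, symptoms=symptoms
    )
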