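"""The 3-tier recommendation engine for one planned chemotherapy cycle.

Tier semantics: 1 = green/"go" (the nurse places the planned order),
2 = yellow/"evaluate" (a human reviews before prescribing),
3 = red/"postpone" (labs out of the preset range; the cycle is delayed).

Rule precedence (first match sets the tier):

1. lab panel present, fresh, and out of range          -> tier 3
2. lab panel absent, stale, or incomplete              -> tier 2
3. questionnaire absent or stale                       -> tier 2
4. any symptom at grade >= 2 above its baseline grade  -> tier 2
5. otherwise                                           -> tier 1

Out-of-range labs dominate missing data: an unfit blood count postpones the
cycle no matter what the questionnaire says. Missing or stale data of either
kind can only ever demand human evaluation (tier 2), never an automatic
postponement. The rationale lists every code that held at the winning tier,
so a cycle with both stale labs and a missing questionnaire reports both.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

from .grading import BaselineComparison, flags_above_baseline
from .labs import INCOMPLETE, OUT_OF_RANGE, evaluate_panel, is_fresh
from .model import (
    ALL_CLEAR,
    EPRO_MISSING,
    EPRO_STALE,
    LABS_MISSING,
    LABS_OUT_OF_RANGE,
    LABS_STALE,
    SYMPTOM_GE2_ABOVE_BASELINE,
    TIERS,
    CycleRecord,
    Finding,
    ReferenceRangeSet,
    SymptomCatalog,
    TierRecommendation,
    default_reference_ranges,
    validate_record,
)


class InvalidRecordError(ValueError):
    """The cycle record violates domain invariants; findings attached."""

    def __init__(self, findings: list[Finding]):
        self.findings = findings
        super().__init__("; ".join(str(f) for f in findings))


class EngineConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    #: Maximum whole-day age of questionnaire and lab data relative to the
    #: planned infusion date; older data cannot support an automated decision.
    max_age_days: int = Field(default=3, ge=0)
    ranges: ReferenceRangeSet = Field(default_factory=default_reference_ranges)
    catalog: SymptomCatalog = Field(default_factory=SymptomCatalog)
    #: Where the baseline questionnaire comes from when a record carries
    #: none: the patient's first questionnaire on record, or only an
    #: explicitly supplied one.
    baseline_policy: Literal["first_questionnaire", "explicit"] = "first_questionnaire"
    #: How a symptom's baseline grade exempts it from flagging; see
    #: :func:`cyclegate.grading.flags_above_baseline`.
    baseline_comparison: BaselineComparison = "exceeds"


def decide(record: CycleRecord, config: EngineConfig = EngineConfig()) -> TierRecommendation:
    """Compute the tier recommendation for one cycle record.

    Pure and deterministic: reads nothing but ``record`` and ``config``.
    Raises :class:`InvalidRecordError` when the record violates domain
    invariants.
    """
    findings = validate_record(record, config.catalog, config.ranges)
    if findings:
        raise InvalidRecordError(findings)

    reference = record.plan.planned_infusion_date
    panel = record.panel
    panel_fresh = panel is not None and is_fresh(
        panel.sampled_on, reference, config.max_age_days
    )
    evaluation = evaluate_panel(panel, config.ranges)

    if panel_fresh and evaluation.overall == OUT_OF_RANGE:
        return TierRecommendation(tier=3, rationale=(LABS_OUT_OF_RANGE,))

    codes: list[str] = []
    flagged: tuple[str, ...] = ()
    if panel is None:
        codes.append(LABS_MISSING)
    elif not panel_fresh:
        codes.append(LABS_STALE)
    elif evaluation.overall == INCOMPLETE:
        codes.append(LABS_MISSING)

    q = record.questionnaire
    if q is None:
        codes.append(EPRO_MISSING)
    elif not is_fresh(q.completed_on, reference, config.max_age_days):
        codes.append(EPRO_STALE)
    else:
        flags = flags_above_baseline(
            q, record.baseline, comparison=config.baseline_comparison
        )
        if flags:
            codes.append(SYMPTOM_GE2_ABOVE_BASELINE)
            flagged = tuple(sorted(flags, key=lambda s: (
                config.catalog.index(s) if s in config.catalog else len(config.catalog.symptoms)
            )))

    if codes:
        return TierRecommendation(tier=2, rationale=tuple(codes), flagged_symptoms=flagged)
    return TierRecommendation(tier=1, rationale=(ALL_CLEAR,))


def apply_override(rec: TierRecommendation, new_tier: int, note: str) -> TierRecommendation:
    """Record a care-team override, preserving the engine's recommendation.

    The original tier and rationale remain untouched as the audit trail;
    only ``overridden_tier``/``override_note`` are set on the returned copy.
    Overrides must be attributable, so an empty note is rejected.
    """
    if new_tier not in TIERS:
        raise ValueError(f"override tier must be one of {TIERS}")
    if not note or not note.strip():
        raise ValueError("override note must be non-empty")
    return rec.model_copy(update={"overridden_tier": new_tier, "override_note": note})


def effective_tier(rec: TierRecommendation) -> int:
    """The tier that governs downstream scheduling: the override if present."""
    return rec.overridden_tier if rec.overridden_tier is not None else rec.tier


def attach_baselines(
    records: list[CycleRecord], config: EngineConfig = EngineConfig()
) -> list[CycleRecord]:
    """Fill missing baselines from each patient's earliest questionnaire.

    Under the ``first_questionnaire`` policy, a record without an explicit
    baseline receives the chronologically first questionnaire seen for that
    patient anywhere in ``records``. Under ``explicit`` the records are
    returned unchanged.
    """
    if config.baseline_policy == "explicit":
        return list(records)
    first: dict[str, object] = {}
    for r in records:
        for q in (r.baseline, r.questionnaire):
            if q is None:
                continue
            cur = first.get(q.patient_id)
            if cur is None or q.completed_on < cur.completed_on:  # type: ignore[union-attr]
                first[q.patient_id] = q
    out = []
    for r in records:
        if r.baseline is None and r.plan.patient_id in first:
            out.append(r.model_copy(update={"baseline": first[r.plan.patient_id]}))
        else:
            out.append(r)
    return out
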