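"""The 3-tier decision engine: truth table, precedence, overrides, purity."""

import itertools

import pytest

from cyclegate import (
    InvalidRecordError,
    TierRecommendation,
    apply_override,
    decide,
    effective_tier,
)

from conftest import make_panel, make_questionnaire, make_record

# --- the five lab states and five ePRO states of the exhaustive oracle ----

LAB_STATES = {
    "in_range": lambda: make_panel(),
    "out_of_range": lambda: make_panel(out_analyte="wbc"),
    "incomplete": lambda: make_panel(drop_analyte="bilirubin"),
    "absent": lambda: None,
    # a stale panel is dated outside the freshness window; it is also out of
    # range here to confirm staleness is checked before the range rule
    "stale": lambda: make_panel(out_analyte="wbc", days_before=5),
}

BASELINE = {"peripheral_sensory_neuropathy": 2}

EPRO_STATES = {
    "fresh_all_le1": lambda: make_questionnaire({"fatigue": 1, "nausea": 0}),
    "fresh_flagged": lambda: make_questionnaire({"nausea": 2}),
    "fresh_at_baseline": lambda: make_questionnaire(
        {"peripheral_sensory_neuropathy": 2, "fatigue": 1}
    ),
    "absent": lambda: None,
    "stale": lambda: make_questionnaire({"fatigue": 0}, days_before=5),
}

# hand-derived truth table: out-of-range fresh labs always postpone (tier 3);
# any missing/stale input demands evaluation (tier 2); a fresh benign
# questionnaire with fresh in-range labs is a go (tier 1), including when a
# grade-2 symptom is merely at its baseline level
def _expected_tier(lab: str, epro: str) -> int:
    if lab == "out_of_range":
        return 3
    if lab in ("incomplete", "absent", "stale"):
        return 2
    if epro in ("fresh_all_le1", "fresh_at_baseline"):
        return 1
    return 2


@pytest.mark.parametrize("lab", list(LAB_STATES))
@pytest.mark.parametrize("epro", list(EPRO_STATES))
def test_truth_table_over_all_lab_and_epro_states(lab, epro, config):
    record = make_record(
        questionnaire=EPRO_STATES[epro](),
        panel=LAB_STATES[lab](),
        baseline=make_questionnaire(BASELINE, days_before=60),
    )
    rec = decide(record, config)
    assert rec.tier == _expected_tier(lab, epro), (lab, epro, rec.rationale)


def test_rationale_codes_name_every_contributing_cause(config):
    baseline = make_questionnaire(BASELINE, days_before=60)
    rec = decide(
        make_record(
            questionnaire=EPRO_STATES["fresh_all_le1"](),
            panel=make_panel(),
            baseline=baseline,
        ),
        config,
    )
    assert rec.rationale == ("ALL_CLEAR",)
    rec = decide(
        make_record(questionnaire=None, panel=make_panel(days_before=5), baseline=baseline),
        config,
    )
    assert set(rec.rationale) == {"LABS_STALE", "EPRO_MISSING"}
    rec = decide(
        make_record(
            questionnaire=EPRO_STATES["fresh_flagged"](),
            panel=make_panel(),
            baseline=baseline,
        ),
        config,
    )
    assert rec.rationale == ("SYMPTOM_GE2_ABOVE_BASELINE",)
    assert rec.flagged_symptoms == ("nausea",)
    rec = decide(
        make_record(questionnaire=None, panel=make_panel(out_analyte="rbc")), config
    )
    assert rec.tier == 3
    assert rec.rationale == ("LABS_OUT_OF_RANGE",)


def test_stale_questionnaire_with_good_labs_needs_evaluation(config):
    record = make_record(
        questionnaire=make_questionnaire({"fatigue": 0}, days_before=4),
        panel=make_panel(),
    )
    rec = decide(record, config)
    assert rec.tier == 2
    assert rec.rationale == ("EPRO_STALE",)


def test_out_of_range_labs_dominate_missing_questionnaire(config):
    """Tier 3 fires iff the panel is present, fresh, and out of range."""
    for epro_state, builder in EPRO_STATES.items():
        record = make_record(questionnaire=builder(), panel=make_panel(out_analyte="alt"))
        assert decide(record, config).tier == 3, epro_state


def test_monotonicity_in_symptom_grade(config):
    """With fresh in-range labs, raising a symptom grade never lowers the tier."""
    previous_tier = 0
    for grade in range(5):
        record = make_record(
            questionnaire=make_questionnaire({"vomiting": grade}),
            panel=make_panel(),
        )
        tier = decide(record, config).tier
        assert tier >= previous_tier
        previous_tier = tier


def test_decide_is_pure_and_repeatable(config):
    record = make_record(
        questionnaire=EPRO_STATES["fresh_flagged"](), panel=make_panel()
    )
    before = record.model_dump()
    first = decide(record, config)
    assert decide(record, config) == first
    assert record.model_dump() == before


def test_invalid_record_rejected_with_findings(config):
    record = make_record(questionnaire=make_questionnaire({"nausea": 7}))
    with pytest.raises(InvalidRecordError) as exc:
        decide(record, config)
    assert exc.value.findings


class TestOverride:
    def test_override_preserves_engine_recommendation(self):
        rec = TierRecommendation(tier=2, rationale=("EPRO_MISSING",))
        overridden = apply_override(rec, 1, "physician reviewed by phone")
        assert overridden.tier == 2
        assert overridden.rationale == ("EPRO_MISSING",)
        assert overridden.overridden_tier == 1
        assert effective_tier(overridden) == 1
        assert effective_tier(rec) == 2  # original untouched

    def test_same_tier_override_is_recorded_noop(self):
        rec = TierRecommendation(tier=3, rationale=("LABS_OUT_OF_RANGE",))
        overridden = apply_override(rec, 3, "confirmed with hematology")
        assert overridden.overridden_tier == 3
        assert effective_tier(overridden) == 3

    @pytest.mark.parametrize("note", ["", "   "])
    def test_unattributable_override_rejected(self, note):
        rec = TierRecommendation(tier=2, rationale=("LABS_MISSING",))
        with pytest.raises(ValueError):
            apply_override(rec, 1, note)

    def test_override_tier_must_be_valid(self):
        rec = TierRecommendation(tier=1, rationale=("ALL_CLEAR",))
        with pytest.raises(ValueError):
            apply_override(rec, 4, "note")
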