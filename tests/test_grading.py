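"""Symptom grading, baseline comparison, and the urgency-alert rules."""

import datetime
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclegate import (
    GradingError,
    GradingRubric,
    RubricRule,
    SymptomCatalog,
    detect_alerts,
    flags_above_baseline,
    grade_questionnaire,
    max_grade,
)

from conftest import make_questionnaire

DATE = datetime.date(2020, 5, 14)


class TestGradeQuestionnaire:
    def test_identity_rubric_passes_grades_through(self):
        q = grade_questionnaire(
            {"diarrhea": 3}, patient_id="P1", completed_on=DATE
        )
        assert q.reports[0].symptom == "diarrhea"
        assert q.reports[0].grade == 3

    def test_answer_mapping_rubric_all_none_answers_grade_zero(self):
        rubric = GradingRubric(
            rules={
                s: (RubricRule(answer="none", grade=0),)
                for s in SymptomCatalog().symptoms
            }
        )
        answers = {s: "none" for s in SymptomCatalog().symptoms}
        q = grade_questionnaire(answers, rubric, patient_id="P1", completed_on=DATE)
        assert {r.grade for r in q.reports} == {0}
        assert len(q.reports) == 16

    def test_first_matching_rule_wins(self):
        rubric = GradingRubric(
            rules={
                "fatigue": (
                    RubricRule(answer="a", grade=1),
                    RubricRule(answer="b", grade=2),
                    RubricRule(answer="b", grade=4),  # shadowed by the first b-rule
                )
            }
        )
        q = grade_questionnaire({"fatigue": "b"}, rubric, patient_id="P1", completed_on=DATE)
        assert q.reports[0].grade == 2

    def test_unanswered_symptoms_are_absent_not_zero(self):
        q = grade_questionnaire({"pain": 2}, patient_id="P1", completed_on=DATE)
        assert q.reported_symptoms() == ("pain",)
        assert q.grade_of("nausea") == 0  # absent reads as 0 downstream

    @pytest.mark.parametrize(
        "answers, rubric",
        [
            ({"not_a_symptom": 1}, None),
            ({"fatigue": "weird"}, GradingRubric(rules={"fatigue": (RubricRule(answer="a", grade=1),)})),
            ({"fatigue": 7}, None),
        ],
        ids=["unknown-symptom", "unmatched-answer", "out-of-scale"],
    )
    def test_rejections_name_the_symptom(self, answers, rubric):
        with pytest.raises(GradingError) as exc:
            grade_questionnaire(
                answers,
                rubric or GradingRubric(),
                patient_id="P1",
                completed_on=DATE,
                catalog=SymptomCatalog(),
            )
        assert exc.value.symptom in str(exc.value)


@pytest.mark.parametrize(
    "grades, expected",
    [({"pain": 0, "nausea": 0}, 0), ({"pain": 1, "nausea": 1, "cough": 2}, 2), ({"pain": 4, "nausea": 1}, 4)],
)
def test_max_grade(grades, expected):
    assert max_grade(make_questionnaire(grades)) == expected


class TestFlagsAboveBaseline:
    def test_symptom_already_at_baseline_does_not_flag(self):
        current = make_questionnaire({"peripheral_sensory_neuropathy": 2})
        baseline = make_questionnaire({"peripheral_sensory_neuropathy": 2})
        assert flags_above_baseline(current, baseline) == set()

    def test_absent_baseline_defaults_to_grade_zero(self):
        current = make_questionnaire({"peripheral_sensory_neuropathy": 2})
        assert flags_above_baseline(current, None) == {"peripheral_sensory_neuropathy"}

    def test_brute_force_over_all_grade_pairs(self):
        """Oracle: flag iff current >= 2 and current > baseline."""
        for cur, base in itertools.product(range(5), repeat=2):
            current = make_questionnaire({"nausea": cur})
            baseline = make_questionnaire({"nausea": base})
            expected = {"nausea"} if cur >= 2 and cur > base else set()
            assert flags_above_baseline(current, baseline) == expected, (cur, base)

    def test_mixed_questionnaire_only_flags_qualifying_symptom(self):
        current = make_questionnaire({"pain": 1, "nausea": 3})
        baseline = make_questionnaire({"nausea": 2})
        assert flags_above_baseline(current, baseline) == {"nausea"}

    def test_exempt_if_present_mode_never_flags_baseline_ge2_symptoms(self):
        current = make_questionnaire({"nausea": 4})
        baseline = make_questionnaire({"nausea": 2})
        assert flags_above_baseline(current, baseline) == {"nausea"}
        assert (
            flags_above_baseline(current, baseline, comparison="exempt_if_present")
            == set()
        )

    @settings(max_examples=60, deadline=None)
    @given(
        st.dictionaries(
            st.sampled_from(SymptomCatalog().symptoms),
            st.integers(0, 4),
            min_size=1,
            max_size=5,
        )
    )
    def test_questionnaire_compared_to_itself_never_flags(self, grades):
        q = make_questionnaire(grades)
        assert flags_above_baseline(q, q) == set()


def _expected_alerts(prev, cur):
    """Hand-written truth table: GRADE_GE3 at cur >= 3; RISE_FROM_0 at prev == 0 and cur == 2."""
    if cur >= 3:
        return ["GRADE_GE3"]
    if cur == 2 and prev == 0:
        return ["RISE_FROM_0"]
    return []


class TestDetectAlerts:
    def test_grade_three_symptom_alerts(self):
        alerts = detect_alerts(make_questionnaire({"diarrhea": 3}))
        assert [(a.trigger, a.symptom) for a in alerts] == [("GRADE_GE3", "diarrhea")]

    def test_rise_from_zero_to_two_alerts(self):
        alerts = detect_alerts(
            make_questionnaire({"fatigue": 2}),
            make_questionnaire({"fatigue": 0}, days_before=8),
        )
        assert [(a.trigger, a.symptom) for a in alerts] == [("RISE_FROM_0", "fatigue")]

    def test_exhaustive_truth_table_over_grade_pairs(self):
        """All 25 (previous, current) pairs match the two stated rules."""
        for prev, cur in itertools.product(range(5), repeat=2):
            alerts = detect_alerts(
                make_questionnaire({"nausea": cur}),
                make_questionnaire({"nausea": prev}, days_before=8),
            )
            assert [a.trigger for a in alerts] == _expected_alerts(prev, cur), (prev, cur)

    def test_no_previous_questionnaire_only_severe_grades_alert(self):
        for cur in range(5):
            alerts = detect_alerts(make_questionnaire({"vomiting": cur}), None)
            expected = ["GRADE_GE3"] if cur >= 3 else []
            assert [a.trigger for a in alerts] == expected

    def test_at_most_one_alert_per_symptom_and_catalog_order(self):
        current = make_questionnaire({"vomiting": 4, "diarrhea": 3, "fatigue": 2})
        previous = make_questionnaire(
            {"vomiting": 0, "diarrhea": 0, "fatigue": 0}, days_before=8
        )
        alerts = detect_alerts(current, previous)
        assert [a.symptom for a in alerts] == ["diarrhea", "fatigue", "vomiting"]
        assert len({a.symptom for a in alerts}) == len(alerts)

    @settings(max_examples=60, deadline=None)
    @given(prev=st.integers(0, 4), cur=st.integers(0, 3))
    def test_alert_presence_monotone_in_current_grade(self, prev, cur):
        """Raising the current grade never removes an alert."""
        previous = make_questionnaire({"pain": prev}, days_before=8)
        low = detect_alerts(make_questionnaire({"pain": cur}), previous)
        high = detect_alerts(make_questionnaire({"pain": cur + 1}), previous)
        assert len(low) <= len(high)
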