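"""Cycle-event state machine: data collection timing and postponement.

Each planned cycle generates two collection events ahead of the infusion —
the symptom questionnaire is sent ``questionnaire_lead_days`` before and the
blood draw is booked ``lab_lead_days`` before — so that both inputs are
fresh when the decision is made. After a decision:

* tier 1 — the plan stands; a go-notification (treatment timetable) is sent;
* tier 2 — nothing is automated: a nurse or physician evaluates and acts;
* tier 3 — the cycle is postponed by ``postpone_delay_days``, the patient is
  notified of the new date, and collection events are re-programmed against
  the new infusion date.

Near-adjacent reservations for the same patient (e.g. an ambulatory-pump
removal appointment booked alongside the infusion itself) are chain-merged
so that only the earliest reservation in a cluster drives questionnaire and
lab collection.
"""

from __future__ import annotations

import datetime
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field

from .model import CyclePlan, TierRecommendation
from .engine import effective_tier

EventKind = Literal["SEND_QUESTIONNAIRE", "COLLECT_LABS", "NOTIFY_GO", "NOTIFY_POSTPONED"]


class ScheduledEvent(BaseModel):
    model_config = ConfigDict(frozen=True)

    kind: EventKind
    due_on: datetime.date
    patient_id: str
    cycle_number: int


class SchedulingConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    questionnaire_lead_days: int = Field(default=3, ge=0)
    lab_lead_days: int = Field(default=1, ge=0)
    # a postponement must move the infusion to a strictly later date
    postpone_delay_days: int = Field(default=7, ge=1)
    reservation_merge_window_days: int = Field(default=3, ge=0)


def schedule_cycle(plan: CyclePlan, cfg: SchedulingConfig = SchedulingConfig()) -> list[ScheduledEvent]:
    """Collection events for one planned cycle (deterministic date arithmetic)."""
    d = plan.planned_infusion_date
    return [
        ScheduledEvent(
            kind="SEND_QUESTIONNAIRE",
            due_on=d - datetime.timedelta(days=cfg.questionnaire_lead_days),
            patient_id=plan.patient_id,
            cycle_number=plan.cycle_number,
        ),
        ScheduledEvent(
            kind="COLLECT_LABS",
            due_on=d - datetime.timedelta(days=cfg.lab_lead_days),
            patient_id=plan.patient_id,
            cycle_number=plan.cycle_number,
        ),
    ]


def on_decision(
    plan: CyclePlan,
    rec: TierRecommendation,
    cfg: SchedulingConfig = SchedulingConfig(),
) -> tuple[CyclePlan, list[ScheduledEvent]]:
    """Advance the state machine after a decision.

    Returns the (possibly re-dated) plan and the events to emit. A tier-3
    decision always yields a strictly later infusion date and a full fresh
    collection schedule for it; tier 2 emits nothing because the follow-up
    is a human workflow, not an automated one.
    """
    tier = effective_tier(rec)
    if tier == 1:
        event = ScheduledEvent(
            kind="NOTIFY_GO",
            due_on=plan.planned_infusion_date,
            patient_id=plan.patient_id,
            cycle_number=plan.cycle_number,
        )
        return plan, [event]
    if tier == 2:
        return plan, []
    new_date = plan.planned_infusion_date + datetime.timedelta(days=cfg.postpone_delay_days)
    new_plan = plan.model_copy(update={"planned_infusion_date": new_date})
    events = [
        ScheduledEvent(
            kind="NOTIFY_POSTPONED",
            due_on=new_date,
            patient_id=plan.patient_id,
            cycle_number=plan.cycle_number,
        )
    ]
    events.extend(schedule_cycle(new_plan, cfg))
    return new_plan, events


def merge_reservations(
    plans: list[CyclePlan], cfg: SchedulingConfig = SchedulingConfig()
) -> list[CyclePlan]:
    """Chain-merge near-adjacent reservations of one patient.

    ``plans`` must belong to a single patient and be sorted by date.
    Reservations whose dates fall within ``reservation_merge_window_days``
    of the previous reservation in the cluster are linked to the cluster's
    earliest plan (``linked_to``) and generate no collection events of
    their own. Idempotent: already-linked plans stay linked to the same
    primary.
    """
    out: list[CyclePlan] = []
    primary: CyclePlan | None = None
    prev_date: datetime.date | None = None
    for plan in plans:
        if (
            primary is not None
            and prev_date is not None
            and (plan.planned_infusion_date - prev_date).days <= cfg.reservation_merge_window_days
        ):
            out.append(plan.model_copy(update={"linked_to": primary.cycle_number}))
        else:
            primary = plan.model_copy(update={"linked_to": None}) if plan.linked_to is not None else plan
            out.append(primary)
        prev_date = plan.planned_infusion_date
    return out


def schedule_plans(
    plans: list[CyclePlan], cfg: SchedulingConfig = SchedulingConfig()
) -> list[ScheduledEvent]:
    """Collection events for a patient's merged reservation list."""
    events: list[ScheduledEvent] = []
    for plan in merge_reservations(plans, cfg):
        if plan.linked_to is None:
            events.extend(schedule_cycle(plan, cfg))
    return events
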