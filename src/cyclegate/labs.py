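"""Laboratory-panel evaluation against configured reference ranges.

Each of the seven analytes is compared inclusively to its [low, high]
interval; the panel's overall status is

* ``IN_RANGE``   — all seven analytes present and inside their bounds,
* ``OUT_OF_RANGE`` — at least one analyte below low or above high,
* ``INCOMPLETE`` — no out-of-range analyte but at least one missing.

``INCOMPLETE`` is deliberately distinct from ``OUT_OF_RANGE``: a missing
value is missing data (routed to manual evaluation), not evidence that the
patient is unfit for the next cycle.
"""

from __future__ import annotations

import datetime
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict

from .model import ANALYTES, AnalyteRange, LabPanel, ReferenceRangeSet

AnalyteStatus = Literal["in_range", "below_low", "above_high", "missing"]
OverallStatus = Literal["IN_RANGE", "OUT_OF_RANGE", "INCOMPLETE"]

IN_RANGE: OverallStatus = "IN_RANGE"
OUT_OF_RANGE: OverallStatus = "OUT_OF_RANGE"
INCOMPLETE: OverallStatus = "INCOMPLETE"


class PanelEvaluation(BaseModel):
    model_config = ConfigDict(frozen=True)

    statuses: dict[str, AnalyteStatus]
    overall: OverallStatus


def _status(value: Optional[float], rng: AnalyteRange) -> AnalyteStatus:
    if value is None:
        return "missing"
    if rng.low is not None and value < rng.low:
        return "below_low"
    if rng.high is not None and value > rng.high:
        return "above_high"
    return "in_range"


def evaluate_panel(panel: Optional[LabPanel], ranges: ReferenceRangeSet) -> PanelEvaluation:
    """Evaluate ``panel`` (or its absence) against ``ranges``.

    Comparison is inclusive at both bounds: a value exactly equal to low or
    high is in range. An absent panel evaluates to all-missing, overall
    ``INCOMPLETE``. Deterministic and pure.
    """
    statuses: dict[str, AnalyteStatus] = {}
    for analyte in ANALYTES:
        value = panel.value_of(analyte) if panel is not None else None
        statuses[analyte] = _status(value, ranges[analyte])
    if any(s in ("below_low", "above_high") for s in statuses.values()):
        overall: OverallStatus = OUT_OF_RANGE
    elif any(s == "missing" for s in statuses.values()):
        overall = INCOMPLETE
    else:
        overall = IN_RANGE
    return PanelEvaluation(statuses=statuses, overall=overall)


def is_fresh(
    observed_on: datetime.date, reference_date: datetime.date, max_age_days: int
) -> bool:
    """True iff the observation is 0..max_age_days whole days old.

    Age is ``reference_date - observed_on`` in calendar days. Future-dated
    observations (negative age) are never fresh: a prescribing decision must
    rest on data collected before the planned infusion.
    """
    if max_age_days < 0:
        raise ValueError("max_age_days must be >= 0")
    age = (reference_date - observed_on).days
    return 0 <= age <= max_age_days
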