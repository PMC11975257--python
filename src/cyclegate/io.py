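"""File readers/writers and the bundled application configuration.

JSON is the canonical on-disk format (cohort records are nested); CSV is
supported for lab panels, which arrive naturally as flat analyte rows.
Configuration is one YAML/JSON document validated into :class:`AppConfig`;
defaults applied for omitted fields are logged so an audit can reconstruct
the exact configuration a decision ran under.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .engine import EngineConfig
from .grading import GradingRubric
from .model import CohortLog, ConfigurationError, CycleRecord, LabPanel
from .scheduling import SchedulingConfig

logger = logging.getLogger("cyclegate")

PathLike = Union[str, Path]


class AppConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    engine: EngineConfig = Field(default_factory=EngineConfig)
    scheduling: SchedulingConfig = Field(default_factory=SchedulingConfig)
    rubric: GradingRubric = Field(default_factory=GradingRubric)


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        key = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{key}: {err['msg']}")
    return "; ".join(parts)


def load_config(path: PathLike) -> AppConfig:
    """Load and validate a YAML/JSON configuration document.

    Raises :class:`~cyclegate.model.ConfigurationError` naming every
    offending key on schema violations. Omitted optional sections fall back
    to package defaults, and each applied default is logged.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config document must be a mapping")
    for section in ("engine", "scheduling", "rubric"):
        if section not in data:
            logger.info("config %s: section %r omitted, defaults applied", path, section)
    try:
        return AppConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigurationError(f"{path}: {_format_validation_error(exc)}") from exc


def save_config(config: AppConfig, path: PathLike) -> None:
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


class CohortReadError(ValueError):
    """A cohort file contains malformed records; names the record index."""


def write_cohort(log: CohortLog, path: PathLike) -> None:
    """Write a cohort log as JSON with stable field ordering (diffable)."""
    Path(path).write_text(json.dumps(log.model_dump(mode="json"), indent=2) + "\n")


def read_cohort(path: PathLike) -> CohortLog:
    """Read a cohort log back; lossless inverse of :func:`write_cohort`.

    An empty file or empty document is an empty log. Malformed records are
    reported with their index and the violated rule.
    """
    text = Path(path).read_text().strip()
    if not text:
        return CohortLog()
    data = json.loads(text)
    # validate record-by-record so errors carry the record index
    for i, raw in enumerate(data.get("records", [])):
        try:
            CycleRecord.model_validate(raw)
        except ValidationError as exc:
            raise CohortReadError(
                f"record {i}: {_format_validation_error(exc)}"
            ) from exc
    try:
        return CohortLog.model_validate(data)
    except ValidationError as exc:
        raise CohortReadError(_format_validation_error(exc)) from exc


PANEL_CSV_COLUMNS = ("patient_id", "sampled_on", "analyte", "value")


def read_panels_csv(path: PathLike) -> list[LabPanel]:
    """Read lab panels from flat CSV rows (patient_id, sampled_on, analyte, value).

    Rows sharing a (patient_id, sampled_on) pair form one panel; panels are
    returned sorted by patient then date.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in PANEL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CohortReadError(f"panel CSV missing columns: {missing}")
    panels = []
    for (patient_id, sampled_on), group in df.groupby(
        ["patient_id", "sampled_on"], sort=True
    ):
        panels.append(
            LabPanel.model_validate(
                {
                    "patient_id": patient_id,
                    "sampled_on": sampled_on,
                    "results": [
                        {"analyte": row.analyte, "value": float(row.value)}
                        for row in group.itertuples()
                    ],
                }
            )
        )
    return panels


def write_panels_csv(panels: list[LabPanel], path: PathLike) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "sampled_on": p.sampled_on.isoformat(),
            "analyte": r.analyte,
            "value": r.value,
        }
        for p in panels
        for r in p.results
    ]
    pd.DataFrame(rows, columns=list(PANEL_CSV_COLUMNS)).to_csv(path, index=False)
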