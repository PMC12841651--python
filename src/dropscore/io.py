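"""Cohort CSV and config/report JSON input-output.

Cohort dialect: UTF-8, comma-separated, header row, empty cell = missing,
flags coded 0/1. Mandatory columns are the profile fields listed in
``REQUIRED_COLUMNS``; unknown columns pass through untouched. Reports are
serialized as JSON with stable key order and full float precision so a
write-read round trip is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .config import ScoreConfig, default_score_config, validate_cohort_ranges
from .exceptions import ValidationError
from .outcomes import OutcomeModelParams, default_outcome_params
from .simulate import SimulatorConfig

REQUIRED_COLUMNS = (
    "eye_id",
    "age",
    "diagnosis",
    "diabetes",
    "hypertension",
    "glaucoma",
    "ice_iris",
    "lens_status",
    "vascularization_grade",
    "donor_ecd",
    "donor_age",
    "scroll_grade",
    "storage_days",
    "surgeon_cases",
    "unfolding_min",
    "tamponade",
    "triple_dmek",
    "epi_debridement",
    "annual_volume",
)

_NUMERIC_COLUMNS = (
    "age",
    "diabetes",
    "hypertension",
    "glaucoma",
    "ice_iris",
    "vascularization_grade",
    "donor_ecd",
    "donor_age",
    "storage_days",
    "surgeon_cases",
    "unfolding_min",
    "triple_dmek",
    "epi_debridement",
    "annual_volume",
)


class RunConfig(BaseModel):
    """Top-level JSON configuration: score, outcome and simulator blocks."""

    model_config = ConfigDict(extra="forbid")

    version: str = "1.0"
    seed: int = 42
    score: ScoreConfig = Field(default_factory=default_score_config)
    outcomes: OutcomeModelParams = Field(default_factory=default_outcome_params)
    simulator: SimulatorConfig = Field(default_factory=SimulatorConfig)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def default_run_config() -> RunConfig:
    return RunConfig()


def read_config(path: Union[str, Path]) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        return RunConfig(**json.load(fh))


def write_config(config: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(config.model_dump(mode="json"), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    """Read a cohort CSV, validate the dialect and type the columns."""
    df = pd.read_csv(path, dtype={"eye_id": str}, keep_default_na=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort file lacks mandatory column(s): {missing}")
    for col in _NUMERIC_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()].tolist()
            lines = [i + 2 for i in bad[:5]]  # +2: header + 1-based
            raise ValidationError(
                f"unparseable value(s) in column {col!r} near line(s) {lines}"
            ) from exc
    for col in ("diagnosis", "lens_status", "scroll_grade", "tamponade"):
        df[col] = df[col].astype("object").where(df[col].notna(), other=np.nan)
    validate_cohort_ranges(df)
    return df


def write_cohort(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="index"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_report(report: dict, path: Union[str, Path]) -> None:
    """Serialize a report deterministically (sorted keys, full precision)."""
    Path(path).write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_report(path: Union[str, Path]) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


class RunLog(BaseModel):
    """Stage-by-stage log of one pipeline run (emitted to stderr)."""

    model_config = ConfigDict(extra="forbid")

    seed: int
    config_hash: str
    stages: list[dict] = Field(default_factory=list)
    warnings: list[str] = Field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, "time": time.time(), **info})

    def to_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)
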