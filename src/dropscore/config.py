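"""Configuration schema for the composite risk score.

The composite score is a weighted sum of four domain subscores — Patient
Risk Profile (PRP), Donor Tissue Quality (DTQ), Surgical Complexity Index
(SCI) and Center Performance Factor (CPF) — each mapped to a 0-100 scale by
an additive point table over the domain's risk factors. The point tables
ship as a versioned, fully overridable default configuration: every point
value is inspectable and can be replaced via a JSON config document.

Schema rules enforced here:

* domain weights are fractions in [0, 1] that sum to 1 (tolerance 1e-9);
* every factor level has a defined point contribution, points are
  non-negative (adding a risk factor can never lower a subscore);
* the zero-risk profile maps to 0 and the worst-level profile to exactly
  100 after normalization by the per-domain maximum;
* unknown keys anywhere in the document are rejected.
"""

from __future__ import annotations

import hashlib
import json
import math
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .exceptions import ConfigurationError, ValidationError

CONFIG_VERSION = "1.0"

#: Risk-category labels in ascending order of risk.
CATEGORIES = ("Low", "Moderate", "High", "VeryHigh")

#: Half-open category boundaries on the continuous 0-100 score:
#: [0, 26) Low, [26, 51) Moderate, [51, 76) High, [76, 100] VeryHigh.
DEFAULT_THRESHOLDS = (26.0, 51.0, 76.0)


class DomainWeights(BaseModel):
    """Weights (alpha, beta, gamma, delta) of the four domain subscores."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    alpha: float = 0.40  # patient
    beta: float = 0.25   # donor
    gamma: float = 0.20  # surgical
    delta: float = 0.15  # center

    @model_validator(mode="after")
    def _check(self) -> "DomainWeights":
        vals = (self.alpha, self.beta, self.gamma, self.delta)
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise ValueError("each weight must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {sum(vals)!r})")
        return self

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.delta])


class FlagFactor(BaseModel):
    """Binary risk factor: contributes ``points`` when present, else 0."""

    model_config = ConfigDict(extra="forbid")
    kind: Literal["flag"] = "flag"
    points: float = Field(ge=0)

    @property
    def max_points(self) -> float:
        return self.points


class EnumFactor(BaseModel):
    """Categorical factor: each level maps to a point contribution."""

    model_config = ConfigDict(extra="forbid")
    kind: Literal["enum"] = "enum"
    levels: dict[str, float]

    @field_validator("levels")
    @classmethod
    def _nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        if not v:
            raise ValueError("enum factor needs at least one level")
        if any(p < 0 for p in v.values()):
            raise ValueError("point contributions must be non-negative")
        return v

    @property
    def max_points(self) -> float:
        return max(self.levels.values())


class BandedFactor(BaseModel):
    """Continuous factor binned into bands.

    ``edges`` are ascending cut points; a value v falls in band i where
    ``edges[i-1] <= v < edges[i]`` (band 0 is v < edges[0], the last band is
    v >= edges[-1]), and contributes ``points[i]``.
    """

    model_config = ConfigDict(extra="forbid")
    kind: Literal["bands"] = "bands"
    edges: list[float]
    points: list[float]

    @model_validator(mode="after")
    def _check(self) -> "BandedFactor":
        if len(self.points) != len(self.edges) + 1:
            raise ValueError("need len(edges) + 1 point values")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly ascending")
        if any(p < 0 for p in self.points):
            raise ValueError("point contributions must be non-negative")
        return self

    @property
    def max_points(self) -> float:
        return max(self.points)


FactorSpec = Union[FlagFactor, EnumFactor, BandedFactor]


class DomainPointTable(BaseModel):
    """Additive point table for one domain: factor name -> factor spec."""

    model_config = ConfigDict(extra="forbid")
    factors: dict[str, FactorSpec]

    @field_validator("factors")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("point table must define at least one factor")
        return v

    @property
    def max_raw(self) -> float:
        total = sum(f.max_points for f in self.factors.values())
        if total <= 0:
            raise ConfigurationError("domain point table has zero total range")
        return total


class ScoreConfig(BaseModel):
    """Full scoring configuration: weights, point tables, thresholds."""

    model_config = ConfigDict(extra="forbid")

    version: str = CONFIG_VERSION
    weights: DomainWeights = Field(default_factory=DomainWeights)
    category_thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    point_tables: dict[str, DomainPointTable]

    @model_validator(mode="after")
    def _check(self) -> "ScoreConfig":
        missing = {"patient", "donor", "surgical", "center"} - set(self.point_tables)
        if missing:
            raise ValueError(f"point_tables missing domains: {sorted(missing)}")
        t = self.category_thresholds
        if not (0 < t[0] < t[1] < t[2] < 100):
            raise ValueError("category thresholds must be ascending within (0, 100)")
        return self

    def config_hash(self) -> str:
        """Stable sha256 of the canonical JSON serialization."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Default point tables
# ---------------------------------------------------------------------------
# Each domain's maxima sum to 100, so raw points are already on the 0-100
# scale; the normalization divides by the maximum anyway so overrides need
# not preserve this property. Values are anchored to the ordering of the
# published univariate odds ratios (diabetes strongest, then hypertension,
# then PBK-vs-FECD diagnosis) and chosen so that a clinical-style case mix
# (about half PBK, typical comorbidity rates, experienced surgeons) lands
# near a mean PRP in the high 30s and a mean composite near 39.

DEFAULT_POINT_TABLES: dict[str, dict] = {
    "patient": {
        "factors": {
            "diabetes": {"kind": "flag", "points": 20},
            "hypertension": {"kind": "flag", "points": 16},
            "diagnosis": {"kind": "enum", "levels": {"FECD": 0, "PBK": 14}},
            "glaucoma": {"kind": "flag", "points": 10},
            "ice_iris": {"kind": "flag", "points": 10},
            "lens_status": {
                "kind": "enum",
                "levels": {"phakic": 0, "pseudophakic": 4, "aphakic": 8},
            },
            "age": {"kind": "bands", "edges": [50, 65, 75], "points": [0, 4, 8, 12]},
            "vascularization_grade": {
                "kind": "enum",
                "levels": {"0": 0, "1": 2.5, "2": 5, "3": 7.5, "4": 10},
            },
        }
    },
    "donor": {
        "factors": {
            "donor_ecd": {
                "kind": "bands",
                "edges": [2300, 2400, 2600, 2800],
                "points": [40, 30, 20, 10, 0],
            },
            "donor_age": {"kind": "bands", "edges": [55, 65, 75], "points": [0, 8, 15, 20]},
            "scroll_grade": {
                "kind": "enum",
                "levels": {"I": 0, "II": 7, "III": 14, "IV": 20},
            },
            "storage_days": {"kind": "bands", "edges": [7, 10], "points": [0, 10, 20]},
        }
    },
    "surgical": {
        "factors": {
            "surgeon_cases": {
                "kind": "bands",
                "edges": [25, 50, 100, 200],
                "points": [30, 22, 15, 8, 0],
            },
            "unfolding_min": {
                "kind": "bands",
                "edges": [5, 10, 15, 20],
                "points": [0, 8, 15, 22, 30],
            },
            "tamponade": {"kind": "enum", "levels": {"air": 0, "SF6": 10}},
            "triple_dmek": {"kind": "flag", "points": 15},
            "epi_debridement": {"kind": "flag", "points": 15},
        }
    },
    "center": {
        "factors": {
            "annual_volume": {
                "kind": "bands",
                "edges": [10, 25, 50, 100],
                "points": [100, 75, 50, 25, 0],
            },
        }
    },
}


def default_score_config() -> ScoreConfig:
    """The shipped v1.0 scoring configuration."""
    return ScoreConfig(point_tables=DEFAULT_POINT_TABLES)


# ---------------------------------------------------------------------------
# Point-table evaluation (vectorized over cohort columns)
# ---------------------------------------------------------------------------

def _flag_points(spec: FlagFactor, values: pd.Series) -> np.ndarray:
    v = pd.to_numeric(values, errors="coerce")
    pts = np.where(v.to_numpy(dtype=float) > 0, spec.points, 0.0)
    return np.where(v.isna().to_numpy(), spec.max_points / 2.0, pts)


def _enum_points(spec: EnumFactor, values: pd.Series, factor: str) -> np.ndarray:
    s = values.astype("object")
    missing = s.isna() | (s == "")
    key = s.astype(str).str.strip()
    # integer-coded ordinal levels may arrive as floats ("2.0")
    key = key.str.replace(r"\.0$", "", regex=True)
    mapped = key.map(spec.levels)
    unknown = mapped.isna() & ~missing
    if unknown.any():
        bad = sorted(set(key[unknown]))
        raise ConfigurationError(
            f"unknown level(s) {bad} for factor {factor!r}; "
            f"configured levels: {sorted(spec.levels)}"
        )
    out = mapped.to_numpy(dtype=float)
    out[missing.to_numpy()] = spec.max_points / 2.0
    return out


def _band_points(spec: BandedFactor, values: pd.Series) -> np.ndarray:
    v = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
    idx = np.searchsorted(np.asarray(spec.edges), v, side="right")
    pts = np.asarray(spec.points)[np.clip(idx, 0, len(spec.points) - 1)]
    return np.where(np.isnan(v), spec.max_points / 2.0, pts)


def factor_points(spec: FactorSpec, values: pd.Series, factor: str) -> np.ndarray:
    """Point contribution per row; missing values contribute mid-range points."""
    if isinstance(spec, FlagFactor):
        return _flag_points(spec, values)
    if isinstance(spec, EnumFactor):
        return _enum_points(spec, values, factor)
    return _band_points(spec, values)


def score_domain(df: pd.DataFrame, table: DomainPointTable) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate one domain's subscore for every cohort row.

    Returns ``(scores, defaulted)`` where ``scores`` is the 0-100 subscore
    (raw points normalized by the domain maximum) and ``defaulted`` flags
    rows on which *every* factor of the domain was missing, i.e. the row
    received the documented mid-range default of exactly 50.0.
    """
    n = len(df)
    raw = np.zeros(n)
    all_missing = np.ones(n, dtype=bool)
    for name, spec in table.factors.items():
        col = df[name] if name in df.columns else pd.Series([math.nan] * n, index=df.index)
        missing = pd.isna(col) | (col.astype("object") == "")
        all_missing &= missing.to_numpy()
        raw += factor_points(spec, col, name)
    scores = raw / table.max_raw * 100.0
    # guard against float drift at the ceiling
    scores = np.clip(scores, 0.0, 100.0)
    return scores, all_missing


def validate_cohort_ranges(df: pd.DataFrame) -> None:
    """Reject physically impossible values before scoring."""
    checks = {
        "age": lambda v: v > 0,
        "donor_ecd": lambda v: v > 0,
        "donor_age": lambda v: v > 0,
        "storage_days": lambda v: v >= 0,
        "surgeon_cases": lambda v: v >= 0,
        "unfolding_min": lambda v: v >= 0,
        "annual_volume": lambda v: v >= 0,
    }
    for col, ok in checks.items():
        if col not in df.columns:
            continue
        v = pd.to_numeric(df[col], errors="coerce")
        bad = v.notna() & ~ok(v)
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise ValidationError(f"column {col!r} has out-of-range values at rows {rows}")
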