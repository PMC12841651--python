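"""Composite risk score: subscores, weighted composite, categories.

The composite score of one eye is

    score = alpha * PRP + beta * DTQ + gamma * SCI + delta * CPF

with weights (0.40, 0.25, 0.20, 0.15) by default and each subscore on a
0-100 scale from an additive point table (see :mod:`dropscore.config`).
Eyes are stratified into four categories on half-open intervals
[0, 26) Low, [26, 51) Moderate, [51, 76) High, [76, 100] VeryHigh.

`DropScorer` is the estimator-style entry point: a stateless transformer
that appends ``prp, dtq, sci, cpf, drop_score, risk_category`` columns to a
cohort DataFrame. The module-level functions are thin wrappers over the
same code path for single profiles.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import (
    CATEGORIES,
    DEFAULT_THRESHOLDS,
    DomainPointTable,
    DomainWeights,
    ScoreConfig,
    default_score_config,
    score_domain,
    validate_cohort_ranges,
)
from .exceptions import ValidationError
from .profiles import (
    CenterProfile,
    DonorProfile,
    DropResult,
    PatientProfile,
    RiskProfileBundle,
    SubscoreSet,
    SurgicalProfile,
)

SUBSCORE_COLUMNS = ("prp", "dtq", "sci", "cpf")
SCORE_COLUMNS = SUBSCORE_COLUMNS + ("drop_score", "risk_category")

_DOMAIN_OF_SUBSCORE = {"prp": "patient", "dtq": "donor", "sci": "surgical", "cpf": "center"}


def _coerce_weights(weights: Union[DomainWeights, Mapping, Sequence, None]) -> DomainWeights:
    if weights is None:
        return DomainWeights()
    if isinstance(weights, DomainWeights):
        return weights
    if isinstance(weights, Mapping):
        return DomainWeights(**weights)
    a, b, g, d = weights
    return DomainWeights(alpha=a, beta=b, gamma=g, delta=d)


def classify_risk(
    composite: Union[float, np.ndarray, pd.Series],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> Union[str, np.ndarray]:
    """Map composite score(s) to risk categories.

    Boundaries are half-open: a score exactly at a threshold belongs to the
    higher category (26.0 -> Moderate, 51.0 -> High, 76.0 -> VeryHigh).
    """
    arr = np.asarray(composite, dtype=float)
    if np.any(np.isnan(arr)) or np.any(arr < 0) or np.any(arr > 100):
        raise ValidationError("composite score must lie in [0, 100]")
    idx = np.searchsorted(np.asarray(thresholds, dtype=float), arr, side="right")
    cats = np.asarray(CATEGORIES, dtype=object)[idx]
    if np.ndim(composite) == 0:
        return str(np.asarray(cats).item()) if np.ndim(cats) == 0 else str(cats)
    return cats


def compute_composite(
    subscores: Union[SubscoreSet, Sequence[float]],
    weights: Union[DomainWeights, Mapping, Sequence, None] = None,
) -> float:
    """Weighted composite of the four subscores (Low->VeryHigh risk scale)."""
    w = _coerce_weights(weights)
    s = subscores.as_tuple() if isinstance(subscores, SubscoreSet) else tuple(subscores)
    if any(not (0 <= v <= 100) for v in s):
        raise ValidationError("subscores must lie in [0, 100]")
    return float(np.dot(w.as_array(), np.asarray(s, dtype=float)))


class DropScorer(BaseEstimator, TransformerMixin):
    """Transformer computing subscores, composite score and risk category.

    Parameters
    ----------
    config : ScoreConfig, dict or None
        Scoring configuration (weights, point tables, category thresholds).
        ``None`` uses the shipped v1.0 defaults.

    The transformer is stateless: :meth:`fit` only validates the
    configuration and records the input columns. :meth:`transform` returns
    a copy of the cohort with ``prp, dtq, sci, cpf, drop_score,
    risk_category`` appended.

    Attributes
    ----------
    config_ : ScoreConfig
        The validated configuration in use.
    defaulted_counts_ : dict
        After ``transform``: number of rows per domain that were scored at
        the mid-range default because every factor was missing.
    """

    def __init__(self, config: Union[ScoreConfig, dict, None] = None):
        self.config = config

    def _resolved(self) -> ScoreConfig:
        if self.config is None:
            return default_score_config()
        if isinstance(self.config, ScoreConfig):
            return self.config
        return ScoreConfig(**self.config)

    def fit(self, X: pd.DataFrame, y=None) -> "DropScorer":
        self.config_ = self._resolved()
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "config_"):
            self.fit(X)
        cfg = self.config_
        validate_cohort_ranges(X)
        out = X.copy()
        defaulted: dict[str, int] = {}
        subs = {}
        for sub, domain in _DOMAIN_OF_SUBSCORE.items():
            scores, miss = score_domain(X, cfg.point_tables[domain])
            subs[sub] = scores
            defaulted[domain] = int(miss.sum())
        w = cfg.weights.as_array()
        composite = (
            w[0] * subs["prp"] + w[1] * subs["dtq"] + w[2] * subs["sci"] + w[3] * subs["cpf"]
        )
        for sub in SUBSCORE_COLUMNS:
            out[sub] = subs[sub]
        out["drop_score"] = composite
        out["risk_category"] = classify_risk(composite, cfg.category_thresholds)
        self.defaulted_counts_ = defaulted
        return out

    def score_bundle(self, bundle: RiskProfileBundle) -> DropResult:
        """Score a single typed profile bundle."""
        row = self.transform(bundle.to_frame()).iloc[0]
        return DropResult(
            subscores=SubscoreSet(
                prp=row["prp"], dtq=row["dtq"], sci=row["sci"], cpf=row["cpf"]
            ),
            composite=float(row["drop_score"]),
            category=row["risk_category"],
        )


def _single_domain_score(
    profile_row: dict, domain: str, table: Optional[DomainPointTable]
) -> float:
    cfg = default_score_config()
    tab = table if table is not None else cfg.point_tables[domain]
    df = pd.DataFrame([profile_row])
    validate_cohort_ranges(df)
    scores, _ = score_domain(df, tab)
    return float(scores[0])


def compute_prp(profile: PatientProfile, table: Optional[DomainPointTable] = None) -> float:
    """Patient Risk Profile subscore (0-100)."""
    return _single_domain_score(profile.to_row(), "patient", table)


def compute_dtq(profile: DonorProfile, table: Optional[DomainPointTable] = None) -> float:
    """Donor Tissue Quality subscore (0-100); fully missing donor -> 50.0."""
    return _single_domain_score(profile.to_row(), "donor", table)


def compute_sci(profile: SurgicalProfile, table: Optional[DomainPointTable] = None) -> float:
    """Surgical Complexity Index subscore (0-100)."""
    return _single_domain_score(profile.to_row(), "surgical", table)


def compute_cpf(profile: CenterProfile, table: Optional[DomainPointTable] = None) -> float:
    """Center Performance Factor subscore (0-100); missing volume -> 50.0."""
    return _single_domain_score(profile.to_row(), "center", table)


# ---------------------------------------------------------------------------
# Weight sensitivity analysis
# ---------------------------------------------------------------------------

def table_scenarios() -> dict[str, DomainWeights]:
    """The three standard weighting scenarios for the sensitivity analysis.

    ``prp_dominant`` fixes alpha at 0.60 and splits the remaining 0.40
    across the other domains proportionally to their baseline weights
    (0.25 : 0.20 : 0.15).
    """
    rest = np.array([0.25, 0.20, 0.15])
    rest = 0.40 * rest / rest.sum()
    return {
        "original": DomainWeights(),
        "equal": DomainWeights(alpha=0.25, beta=0.25, gamma=0.25, delta=0.25),
        "prp_dominant": DomainWeights(
            alpha=0.60, beta=float(rest[0]), gamma=float(rest[1]), delta=float(rest[2])
        ),
    }


def weight_sensitivity(
    cohort: pd.DataFrame,
    scenarios: Optional[Mapping[str, Union[DomainWeights, Mapping, Sequence]]] = None,
    baseline: Union[DomainWeights, Mapping, Sequence, None] = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Recompute the composite under alternative weights and summarize.

    Parameters
    ----------
    cohort : DataFrame with ``prp, dtq, sci, cpf`` columns.
    scenarios : mapping name -> weights; defaults to :func:`table_scenarios`.
    baseline : weights against which category changes are counted
        (default: the original published weights).

    Returns
    -------
    DataFrame indexed by scenario with columns ``mean, sd, pct_high_or_above,
    pct_changed_category``.
    """
    if len(cohort) == 0:
        raise ValidationError("weight sensitivity needs a non-empty cohort")
    missing = [c for c in SUBSCORE_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort lacks subscore columns: {missing}")
    scen = dict(scenarios) if scenarios is not None else table_scenarios()
    base_w = _coerce_weights(baseline)
    S = cohort[list(SUBSCORE_COLUMNS)].to_numpy(dtype=float)
    base_cat = classify_risk(S @ base_w.as_array(), thresholds)

    rows = []
    for name, w in scen.items():
        wv = _coerce_weights(w)
        comp = S @ wv.as_array()
        cat = classify_risk(comp, thresholds)
        high_up = np.isin(cat, ("High", "VeryHigh"))
        rows.append(
            {
                "scenario": name,
                "mean": float(np.mean(comp)),
                "sd": float(np.std(comp, ddof=1)) if len(comp) > 1 else 0.0,
                "pct_high_or_above": float(100.0 * np.mean(high_up)),
                "pct_changed_category": float(100.0 * np.mean(cat != base_cat)),
            }
        )
    return pd.DataFrame(rows).set_index("scenario")
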