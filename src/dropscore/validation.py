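"""Model-validation statistics.

Discrimination (DeLong AUC with asymptotic CI), calibration
(Hosmer-Lemeshow, calibration slope, calibration-in-the-large),
decision-curve analysis, 2x2 Fisher/odds-ratio tables, logistic fitting
with likelihood-ratio comparison, Brier score, events-per-variable and
Pearson correlation — the evaluation battery for composite-risk-score
validation on clinical or simulated cohorts.

Conventions worth noting:

* AUC ties count 1/2 (the Mann-Whitney definition underlying DeLong);
  the default CI is a Wald interval on the AUC scale truncated to [0, 1]
  (a logit-scale interval is available via ``ci_scale="logit"``).
* Odds-ratio confidence intervals use the Woolf logit method with a
  Haldane-Anscombe 0.5 correction when any cell is zero (flagged in the
  result); the two-sided Fisher p sums hypergeometric outcomes no more
  probable than the observed table.
* Hosmer-Lemeshow groups are quantiles of predicted probability
  (default 10); degrees of freedom are ``groups - 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    DiscriminationUndefinedError,
    SeparationError,
    ValidationError,
)


def _check_pred_set(probs: np.ndarray, y: np.ndarray, open_unit: bool = False) -> None:
    if len(probs) != len(y):
        raise ValidationError("predictions and outcomes must be paired")
    if len(y) < 2:
        raise ValidationError("need at least two observations")
    if not np.all(np.isin(y, (0, 1))):
        raise ValidationError("outcomes must be coded 0/1")
    if open_unit and (np.any(probs <= 0) or np.any(probs >= 1)):
        raise ValidationError("predicted probabilities must lie strictly in (0, 1)")


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    n_events: int
    n_nonevents: int


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_auc(
    scores: Sequence[float],
    outcomes: Sequence[int],
    alpha: float = 0.05,
    ci_scale: str = "auc",
) -> AucResult:
    """Mann-Whitney AUC with a DeLong-variance confidence interval.

    ``scores`` may be any risk marker (not necessarily probabilities);
    higher scores are assumed to indicate events.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    _check_pred_set(x, y)
    pos, neg = x[y == 1], x[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise DiscriminationUndefinedError(
            "discrimination undefined: need at least one event and one non-event"
        )
    all_r = _midranks(np.concatenate([pos, neg]))
    pos_r, neg_r = _midranks(pos), _midranks(neg)
    # structural components (Sun & Xu midrank formulation)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    auc = float(np.mean(v10))
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    zq = stats.norm.ppf(1 - alpha / 2)
    if ci_scale == "logit" and 0 < auc < 1 and se > 0:
        lg = np.log(auc / (1 - auc))
        se_lg = se / (auc * (1 - auc))
        lo, hi = 1 / (1 + np.exp(-(lg - zq * se_lg))), 1 / (1 + np.exp(-(lg + zq * se_lg)))
    else:
        lo, hi = auc - zq * se, auc + zq * se
    return AucResult(
        auc=auc,
        ci_low=float(max(0.0, lo)),
        ci_high=float(min(1.0, hi)),
        se=se,
        n_events=m,
        n_nonevents=n,
    )


def brier_score(probs: Sequence[float], outcomes: Sequence[int]) -> float:
    """Mean squared error of probabilistic predictions."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    _check_pred_set(p, y)
    return float(np.mean((p - y) ** 2))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationReport:
    hl_chi2: float
    hl_df: int
    hl_p: float
    groups: pd.DataFrame  # per-group n, observed, expected, mean_pred
    slope: Optional[float] = None
    intercept_in_the_large: Optional[float] = None


def hosmer_lemeshow(
    probs: Sequence[float], outcomes: Sequence[int], groups: int = 10
) -> CalibrationReport:
    """Hosmer-Lemeshow goodness-of-fit over predicted-probability quantiles.

    ``chi2 = sum (O_g - E_g)^2 / (E_g (1 - E_g / n_g))``; df = groups - 2.
    Ties at quantile edges can merge groups; the statistic then uses the
    actual number of groups formed.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    _check_pred_set(p, y)
    if groups < 3:
        raise ValidationError("need at least 3 groups")
    if len(y) < groups:
        raise ValidationError("need at least as many observations as groups")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, groups + 1)))
    bins = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    tab = []
    for g in np.unique(bins):
        sel = bins == g
        ng = int(sel.sum())
        obs = float(y[sel].sum())
        exp = float(p[sel].sum())
        tab.append({"group": int(g), "n": ng, "observed": obs, "expected": exp,
                    "mean_pred": float(p[sel].mean())})
    gdf = pd.DataFrame(tab)
    denom = gdf["expected"] * (1 - gdf["expected"] / gdf["n"])
    valid = denom > 0
    chi2 = float(((gdf["observed"] - gdf["expected"]) ** 2 / denom)[valid].sum())
    df = int(len(gdf) - 2)
    if df < 1:
        raise ValidationError("too few distinct probability groups for the HL test")
    pval = float(stats.chi2.sf(chi2, df))
    return CalibrationReport(hl_chi2=chi2, hl_df=df, hl_p=pval, groups=gdf)


def calibration_line(
    probs: Sequence[float], outcomes: Sequence[int]
) -> tuple[float, float]:
    """Calibration slope and calibration-in-the-large.

    Slope: coefficient of ``logit(p)`` in a refit logistic model of the
    outcome. Calibration-in-the-large: intercept of a logistic model with
    ``logit(p)`` as a fixed offset (slope pinned at 1); negative values
    mean the predictions are systematically too high.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    _check_pred_set(p, y, open_unit=True)
    if y.sum() in (0, len(y)):
        raise ValidationError("degenerate outcomes: calibration line undefined")
    lp = np.log(p / (1 - p))
    X = sm.add_constant(lp)
    slope = float(sm.GLM(y, X, family=sm.families.Binomial()).fit().params[1])
    citl_fit = sm.GLM(
        y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=lp
    ).fit()
    return slope, float(citl_fit.params[0])


# ---------------------------------------------------------------------------
# Decision-curve analysis
# ---------------------------------------------------------------------------

def treat_all_net_benefit(prevalence: float, threshold: float) -> float:
    """Net benefit of treating everyone at a given threshold probability."""
    if not 0 <= prevalence <= 1:
        raise ValidationError("prevalence must lie in [0, 1]")
    if not 0 <= threshold < 1:
        raise ValidationError("threshold must lie in [0, 1)")
    return prevalence - (1 - prevalence) * threshold / (1 - threshold)


def decision_curve(
    probs: Sequence[float],
    outcomes: Sequence[int],
    thresholds: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Net benefit of the model vs. treat-all / treat-none across thresholds.

    Model net benefit at threshold t classifies positive when the predicted
    probability is >= t: ``TP/n - FP/n * t / (1 - t)``. Treat-none is
    identically zero.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    _check_pred_set(p, y)
    t = np.arange(0.0, 0.60, 0.01) if thresholds is None else np.asarray(thresholds, float)
    if np.any(t < 0) or np.any(t >= 1):
        raise ValidationError("thresholds must lie in [0, 1)")
    n = len(y)
    prev = y.mean()
    rows = []
    for th in t:
        positive = p >= th
        tp = float(np.sum(positive & (y == 1)))
        fp = float(np.sum(positive & (y == 0)))
        w = th / (1 - th)
        rows.append(
            {
                "threshold": float(th),
                "net_benefit_model": tp / n - fp / n * w,
                "net_benefit_treat_all": prev - (1 - prev) * w,
                "net_benefit_treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 2x2 tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FisherOrResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    continuity_corrected: bool


def fisher_or(
    a: int, b: int, c: int, d: int, alpha: float = 0.05
) -> FisherOrResult:
    """Odds ratio, Woolf CI and two-sided Fisher exact p for a 2x2 table.

    Cells: a = exposed events, b = exposed non-events, c = unexposed
    events, d = unexposed non-events. A 0.5 continuity correction is
    applied to OR and CI (not the exact p) when any cell is zero.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0) or np.any(cells != np.round(cells)):
        raise ValidationError("cell counts must be non-negative integers")
    if cells.sum() < 1:
        raise ValidationError("empty table")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValidationError("empty margin: odds ratio undefined")
    corrected = bool(np.any(cells == 0))
    aa, bb, cc, dd = cells + (0.5 if corrected else 0.0)
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    zq = stats.norm.ppf(1 - alpha / 2)
    _, pval = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return FisherOrResult(
        odds_ratio=float(or_),
        ci_low=float(np.exp(np.log(or_) - zq * se)),
        ci_high=float(np.exp(np.log(or_) + zq * se)),
        p_value=float(pval),
        continuity_corrected=corrected,
    )


# ---------------------------------------------------------------------------
# Logistic fitting and model comparison
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    llf: float
    aic: float
    n: int
    converged: bool
    model: object = field(repr=False, default=None)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xd = sm.add_constant(X, has_constant="add")
        lp = Xd.to_numpy(dtype=float) @ self.params.reindex(Xd.columns).to_numpy()
        return 1.0 / (1.0 + np.exp(-lp))


def fit_logistic(
    design: Union[pd.DataFrame, np.ndarray],
    outcomes: Sequence[int],
    add_intercept: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic regression (IRLS via statsmodels GLM).

    Raises :class:`SeparationError` when the likelihood degenerates
    (perfect separation: diverging coefficients / vanishing residual
    deviance).
    """
    X = pd.DataFrame(design).copy()
    y = np.asarray(outcomes, dtype=int)
    if len(X) != len(y):
        raise ValidationError("design and outcomes must be paired")
    if len(X) <= X.shape[1] + int(add_intercept):
        raise ValidationError("need more observations than coefficients")
    if not np.all(np.isin(y, (0, 1))):
        raise ValidationError("outcomes must be coded 0/1")
    if y.sum() in (0, len(y)):
        raise ValidationError("single-class outcome: logistic fit undefined")
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200, tol=1e-10)
    except Exception as exc:  # statsmodels raises PerfectSeparationError
        if "erfect" in type(exc).__name__ or "separat" in str(exc).lower():
            raise SeparationError(str(exc)) from exc
        raise
    params = pd.Series(res.params, index=X.columns)
    if np.any(np.abs(params.to_numpy()) > 30):
        raise SeparationError(
            "diverging coefficients suggest (quasi-)perfect separation"
        )
    ci = pd.DataFrame(
        np.asarray(res.conf_int()), index=X.columns, columns=["low", "high"]
    )
    return LogisticFit(
        params=params,
        bse=pd.Series(res.bse, index=X.columns),
        conf_int=ci,
        llf=float(res.llf),
        aic=float(2 * len(params) - 2 * res.llf),
        n=len(y),
        converged=bool(res.converged),
        model=res,
    )


def likelihood_ratio_test(
    logl_full: float, logl_reduced: float, df: int
) -> tuple[float, float]:
    """LR statistic ``2 (logL_full - logL_reduced)`` and its chi-square p."""
    if df < 1:
        raise ValidationError("df must be at least 1")
    lr = 2.0 * (logl_full - logl_reduced)
    if lr < -1e-8:
        raise ValidationError(
            "full model has lower likelihood than reduced: models are not nested"
        )
    lr = max(lr, 0.0)
    return float(lr), float(stats.chi2.sf(lr, df))


def events_per_variable(events: int, predictors: int) -> float:
    """Overfitting diagnostic: outcome events per fitted predictor."""
    if predictors < 1:
        raise ValidationError("need at least one predictor")
    if events < 0:
        raise ValidationError("event count cannot be negative")
    return events / predictors


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation and two-sided p (t distribution, n-2 df)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya) or len(xa) < 3:
        raise ValidationError("need paired samples of length >= 3")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValidationError("zero variance: correlation undefined")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Risk-stratified outcome tables
# ---------------------------------------------------------------------------

def stratified_outcome_table(
    cohort: pd.DataFrame,
    binary_outcomes: Sequence[str] = (),
    continuous_outcomes: Sequence[str] = (),
    category_col: str = "risk_category",
) -> dict[str, pd.DataFrame]:
    """Per-category outcome summary with between-category tests.

    For every outcome: per-category n, event counts / rates (binary) or
    mean +/- SD (continuous), the pooled value across categories, and a
    between-category p-value comparing the lowest vs. highest occupied
    category (Fisher exact for binary, Welch t for continuous). Empty
    categories are omitted.
    """
    from .config import CATEGORIES

    if category_col not in cohort.columns:
        raise ValidationError(f"cohort has no {category_col!r} column")
    present = [c for c in CATEGORIES if (cohort[category_col] == c).any()]
    if not present:
        raise ValidationError("no occupied risk categories")
    groups = {c: cohort[cohort[category_col] == c] for c in present}
    lo_g, hi_g = groups[present[0]], groups[present[-1]]

    out: dict[str, pd.DataFrame] = {}
    rows = []
    for col in binary_outcomes:
        row = {"outcome": col}
        events_total = 0
        n_total = 0
        for c in present:
            v = groups[c][col].dropna().astype(int)
            row[f"{c}_n"] = len(v)
            row[f"{c}_events"] = int(v.sum())
            row[f"{c}_rate_pct"] = 100.0 * v.mean() if len(v) else np.nan
            events_total += int(v.sum())
            n_total += len(v)
        row["pooled_rate_pct"] = 100.0 * events_total / n_total if n_total else np.nan
        if len(present) >= 2:
            a = int(hi_g[col].dropna().astype(int).sum())
            b = int(hi_g[col].dropna().count()) - a
            c2 = int(lo_g[col].dropna().astype(int).sum())
            d = int(lo_g[col].dropna().count()) - c2
            _, p = stats.fisher_exact([[a, b], [c2, d]])
            row["p_value"] = float(p)
        else:
            row["p_value"] = np.nan
        rows.append(row)
    if rows:
        out["binary"] = pd.DataFrame(rows).set_index("outcome")

    rows = []
    for col in continuous_outcomes:
        row = {"outcome": col}
        pooled = cohort[col].dropna()
        for c in present:
            v = groups[c][col].dropna()
            row[f"{c}_mean"] = float(v.mean()) if len(v) else np.nan
            row[f"{c}_sd"] = float(v.std(ddof=1)) if len(v) > 1 else np.nan
        row["pooled_mean"] = float(pooled.mean()) if len(pooled) else np.nan
        row["pooled_sd"] = float(pooled.std(ddof=1)) if len(pooled) > 1 else np.nan
        if len(present) >= 2 and len(lo_g[col].dropna()) > 1 and len(hi_g[col].dropna()) > 1:
            _, p = stats.ttest_ind(
                hi_g[col].dropna(), lo_g[col].dropna(), equal_var=False
            )
            row["p_value"] = float(p)
        else:
            row["p_value"] = np.nan
        rows.append(row)
    if rows:
        out["continuous"] = pd.DataFrame(rows).set_index("outcome")
    return out


def stepwise_backward(
    design: pd.DataFrame,
    outcomes: Sequence[int],
    entry_p: float = 0.10,
    removal_p: float = 0.15,
) -> LogisticFit:
    """Backward stepwise logistic selection (optional utility).

    Starts from the covariates whose univariate Wald p is below
    ``entry_p`` and iteratively drops the covariate with the largest
    multivariate p while it exceeds ``removal_p``. Stepwise selection is
    known to produce optimistic, sample-dependent models; it is provided
    for reproducing legacy analyses, not recommended for new ones.
    """
    X = pd.DataFrame(design).copy()
    y = np.asarray(outcomes, dtype=int)
    keep = []
    for col in X.columns:
        fit = fit_logistic(X[[col]], y)
        wald_p = 2 * stats.norm.sf(abs(fit.params[col] / fit.bse[col]))
        if wald_p < entry_p:
            keep.append(col)
    if not keep:
        return fit_logistic(pd.DataFrame(index=X.index), y, add_intercept=True)
    while len(keep) > 1:
        fit = fit_logistic(X[keep], y)
        z = (fit.params[keep] / fit.bse[keep]).abs()
        pvals = 2 * stats.norm.sf(z)
        worst = int(np.argmax(pvals))
        if pvals[worst] > removal_p:
            keep.pop(worst)
        else:
            break
    return fit_logistic(X[keep], y)


# ---------------------------------------------------------------------------
# One-call validation report
# ---------------------------------------------------------------------------

def validation_report(
    probs: Sequence[float],
    outcomes: Sequence[int],
    hl_groups: int = 10,
    dca_thresholds: Optional[Sequence[float]] = None,
) -> dict:
    """AUC, calibration, Brier and decision-curve bundle as plain dicts."""
    auc = delong_auc(probs, outcomes)
    hl = hosmer_lemeshow(probs, outcomes, groups=hl_groups)
    try:
        slope, citl = calibration_line(probs, outcomes)
    except ValidationError:
        slope, citl = None, None
    dca = decision_curve(probs, outcomes, dca_thresholds)
    return {
        "n": int(len(np.asarray(outcomes))),
        "prevalence": float(np.mean(np.asarray(outcomes, dtype=float))),
        "auc": {
            "estimate": auc.auc,
            "ci_low": auc.ci_low,
            "ci_high": auc.ci_high,
            "se": auc.se,
        },
        "calibration": {
            "hl_chi2": hl.hl_chi2,
            "hl_df": hl.hl_df,
            "hl_p": hl.hl_p,
            "slope": slope,
            "intercept_in_the_large": citl,
        },
        "brier": brier_score(probs, outcomes),
        "decision_curve": dca.to_dict(orient="list"),
    }
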