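"""Seeded synthetic DMEK cohort generation.

The generator emulates a multicenter-style validation cohort: per-eye risk
profiles over the four scoring domains, composite scores covering all four
risk categories, and outcomes drawn from the package's own outcome models
plus noise.

Structure
---------
* **Profiles** are drawn through a copula-style latent layer: one
  standardized latent variable per risk factor, built as
  ``Z_i = l_i * G + sqrt(1 - l_i^2) * e_i`` from a common "case-severity"
  factor G (per-factor loadings, configurable) and Gaussian residuals
  with optional explicit pairwise correlations. G is a standardized
  log-normal (right-skewed, ``severity_skew`` = log-scale sigma; 0 gives
  a Gaussian factor), which reproduces the right tail of a heterogeneous
  multicenter case mix — a minority of eyes accumulate many risk factors
  at once. Each latent is mapped to its marginal by quantile transform
  (flag and ordinal thresholds are exact quantiles of the latent mixture,
  computed by Gauss-Hermite quadrature), oriented so that a *higher*
  latent value always means *higher* risk (e.g. high latent -> low donor
  ECD). The common factor produces the moderate positive correlations
  between domain subscores and widens the composite-score distribution
  relative to a single homogeneous center.
* **Outcomes**: binary complications are Bernoulli draws from the logistic
  model probabilities; graft failure comes from exponentially distributed
  failure times under the proportional-hazards model; 12-month BCVA adds
  Gaussian noise (default SD 0.15 logMAR) to the linear prediction; 12-month
  ECD multiplies the exponential-decay prediction by mean-one log-normal
  noise so densities stay positive.

Determinism: a single integer seed drives one `numpy` SeedSequence;
per-stage child streams are spawned deterministically, so identical
(config, seed) reproduce the cohort bit-for-bit.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from .config import ScoreConfig, default_score_config
from .exceptions import ConfigurationError, ValidationError
from .outcomes import (
    OutcomeModelParams,
    default_outcome_params,
    effective_lambda,
    predict_bcva,
    predict_complication,
    predict_ecd,
)
from .profiles import (
    CenterProfile,
    DonorProfile,
    PatientProfile,
    RiskProfileBundle,
    SurgicalProfile,
)
from .scoring import DropScorer

OUTCOME_COLUMNS = (
    "graft_failure_1y",
    "graft_failure_3y",
    "rebubbling",
    "rejection",
    "bcva_12m",
    "ecl_12m_pct",
)

#: Latent factor order used by the copula (fixed; documented for overrides).
FACTOR_ORDER = (
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
    "bcva_pre",
)


class ContinuousMarginal(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dist: str = "normal"  # "normal" or "lognormal"
    mean: float
    sd: float = Field(ge=0)
    lo: float = -np.inf
    hi: float = np.inf


class SimulatorConfig(BaseModel):
    """Distributions, associations and noise levels of the generator.

    Defaults reflect a clinical-style case mix (about half PBK, typical
    systemic-comorbidity rates, mostly experienced surgeons) widened across
    centers and donors so the composite score covers all four categories.
    """

    model_config = ConfigDict(extra="forbid")

    n: int = Field(default=500, ge=1)
    seed: int = 42

    # flag / enum marginals (proportions)
    p_pbk: float = Field(default=0.50, ge=0, le=1)
    p_diabetes: float = Field(default=0.35, ge=0, le=1)
    p_hypertension: float = Field(default=0.50, ge=0, le=1)
    p_glaucoma: float = Field(default=0.20, ge=0, le=1)
    p_ice_iris: float = Field(default=0.08, ge=0, le=1)
    p_pseudophakic_fecd: float = Field(default=0.40, ge=0, le=1)
    p_aphakic_fecd: float = Field(default=0.02, ge=0, le=1)
    p_vascularization: tuple[float, ...] = (0.40, 0.25, 0.17, 0.12, 0.06)
    p_scroll: tuple[float, ...] = (0.22, 0.33, 0.27, 0.18)  # grades I-IV
    p_sf6: float = Field(default=0.30, ge=0, le=1)
    p_triple: float = Field(default=0.25, ge=0, le=1)
    p_epi_debridement: float = Field(default=0.30, ge=0, le=1)

    # continuous marginals
    age: ContinuousMarginal = ContinuousMarginal(mean=70, sd=12, lo=35, hi=95)
    donor_ecd: ContinuousMarginal = ContinuousMarginal(mean=2580, sd=300, lo=2300, hi=3200)
    donor_age: ContinuousMarginal = ContinuousMarginal(mean=62, sd=14, lo=30, hi=85)
    storage_days: ContinuousMarginal = ContinuousMarginal(mean=8, sd=3.5, lo=1, hi=14)
    surgeon_cases: ContinuousMarginal = ContinuousMarginal(
        dist="lognormal", mean=4.6, sd=1.1, lo=5, hi=1000
    )
    unfolding_min: ContinuousMarginal = ContinuousMarginal(
        dist="lognormal", mean=2.25, sd=0.75, lo=2, hi=45
    )
    annual_volume: ContinuousMarginal = ContinuousMarginal(
        dist="lognormal", mean=3.3, sd=1.1, lo=5, hi=300
    )
    bcva_pre: ContinuousMarginal = ContinuousMarginal(mean=1.2, sd=0.4, lo=0.3, hi=2.5)

    # association structure: common case-severity factor loadings per factor
    common_factor_loadings: dict[str, float] = Field(
        default_factory=lambda: {
            "age": 0.50,
            "diagnosis": 0.68,
            "diabetes": 0.62,
            "hypertension": 0.62,
            "glaucoma": 0.62,
            "ice_iris": 0.50,
            "lens_status": 0.68,
            "vascularization_grade": 0.62,
            "donor_ecd": 0.44,
            "donor_age": 0.44,
            "scroll_grade": 0.44,
            "storage_days": 0.38,
            "surgeon_cases": 0.56,
            "unfolding_min": 0.68,
            "tamponade": 0.38,
            "triple_dmek": 0.0,
            "epi_debridement": 0.50,
            "annual_volume": 0.56,
            "bcva_pre": 0.68,
        }
    )
    #: log-scale sigma of the standardized log-normal severity factor;
    #: 0 gives a symmetric Gaussian factor
    severity_skew: float = Field(default=0.5, ge=0)
    # optional explicit latent correlations overriding the one-factor value
    pairwise_correlations: list[tuple[str, str, float]] = Field(default_factory=list)

    # outcome noise
    bcva_noise_sd: float = Field(default=0.15, ge=0)  # logMAR, additive Gaussian
    ecd_lognormal_sigma: float = Field(default=0.12, ge=0)  # multiplicative

    # event link strengths: score slopes of the generating models; None
    # keeps the outcome-model defaults. 0.0 yields a no-signal null.
    link_strength_scale: float = Field(default=1.0, ge=0)


def _residual_correlation(config: SimulatorConfig, load: np.ndarray) -> np.ndarray:
    """Residual correlation among the e_i implied by pairwise overrides."""
    k = len(FACTOR_ORDER)
    R = np.eye(k)
    idx = {f: i for i, f in enumerate(FACTOR_ORDER)}
    s = np.sqrt(1.0 - load**2)
    for f1, f2, r in config.pairwise_correlations:
        if f1 not in idx or f2 not in idx:
            raise ConfigurationError(f"unknown factor in pairwise correlation: {(f1, f2)}")
        if not -1 < r < 1:
            raise ConfigurationError("pairwise correlations must lie in (-1, 1)")
        i, j = idx[f1], idx[f2]
        re = (r - load[i] * load[j]) / (s[i] * s[j])
        if not -1 < re < 1:
            raise ConfigurationError(
                f"pairwise correlation {r} for {(f1, f2)} is incompatible with the "
                "common-factor loadings"
            )
        R[i, j] = R[j, i] = re
    # eigenvalue clipping keeps user-overridden matrices positive definite
    w, v = np.linalg.eigh(R)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        R = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(80)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2 * np.pi)


def _severity_factor(x_norm: np.ndarray, sigma: float) -> np.ndarray:
    """Standardized (mean 0, var 1) log-normal transform of standard normals."""
    if sigma == 0:
        return x_norm
    m1 = np.exp(sigma**2 / 2.0)
    sv = np.sqrt((np.exp(sigma**2) - 1.0) * np.exp(sigma**2))
    return (np.exp(sigma * x_norm) - m1) / sv


def _latent_cdf(t: float, loading: float, sigma: float) -> float:
    """CDF of Z = loading * G + sqrt(1-loading^2) * e at t (G-H quadrature)."""
    s = np.sqrt(1.0 - loading**2)
    if s < 1e-12:
        g = _severity_factor(_GH_NODES, sigma)
        return float(np.sum(_GH_WEIGHTS * (loading * g <= t)))
    g = _severity_factor(_GH_NODES, sigma)
    return float(np.sum(_GH_WEIGHTS * stats.norm.cdf((t - loading * g) / s)))


def _latent_quantile(p: float, loading: float, sigma: float) -> float:
    """Exact p-quantile of the latent mixture, so thresholds hit configured
    prevalences even with a skewed severity factor."""
    from scipy.optimize import brentq

    if sigma == 0 or loading == 0:
        return float(stats.norm.ppf(p))
    lo, hi = -15.0, 15.0
    while _latent_cdf(hi, loading, sigma) < p:
        hi *= 2
    while _latent_cdf(lo, loading, sigma) > p:
        lo *= 2
    return float(brentq(lambda t: _latent_cdf(t, loading, sigma) - p, lo, hi, xtol=1e-10))


def _continuous(z: np.ndarray, m: ContinuousMarginal, risk_increases: bool) -> np.ndarray:
    """Map standardized latents to a continuous marginal; higher z = higher risk."""
    zz = z if risk_increases else -z
    if m.dist == "normal":
        x = m.mean + m.sd * zz
    elif m.dist == "lognormal":
        x = np.exp(m.mean + m.sd * zz)
    else:
        raise ConfigurationError(f"unknown marginal distribution {m.dist!r}")
    return np.clip(x, m.lo, m.hi)


def _flag(z: np.ndarray, p: float, loading: float, sigma: float) -> np.ndarray:
    """Bernoulli(p): true on the upper-p tail of the latent distribution."""
    if p <= 0:
        return np.zeros(len(z), dtype=int)
    if p >= 1:
        return np.ones(len(z), dtype=int)
    return (z > _latent_quantile(1 - p, loading, sigma)).astype(int)


def _ordinal(
    z: np.ndarray, probs: Sequence[float], loading: float, sigma: float
) -> np.ndarray:
    """Ordered categorical via latent thresholds; higher z = higher level."""
    p = np.asarray(probs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6 or np.any(p < 0):
        raise ConfigurationError("ordinal probabilities must be non-negative and sum to 1")
    cum = np.clip(np.cumsum(p)[:-1], 1e-12, 1 - 1e-12)
    cuts = np.array([_latent_quantile(q, loading, sigma) for q in cum])
    return np.searchsorted(cuts, z, side="right")


class CohortSimulator:
    """Generate seeded synthetic cohorts and simulate their outcomes.

    Parameters
    ----------
    config : SimulatorConfig, dict or None
        Generator distributions and associations (``None``: defaults).
    params : OutcomeModelParams, dict or None
        Outcome models used both for the deterministic predictions and as
        the generating process of the simulated outcomes.
    score_config : ScoreConfig or None
        Scoring configuration used to compute subscores and categories.
    """

    def __init__(
        self,
        config: Union[SimulatorConfig, dict, None] = None,
        params: Union[OutcomeModelParams, dict, None] = None,
        score_config: Optional[ScoreConfig] = None,
    ):
        if isinstance(config, dict):
            config = SimulatorConfig(**config)
        self.config = config or SimulatorConfig()
        if isinstance(params, dict):
            params = OutcomeModelParams(**params)
        self.params = params or default_outcome_params()
        self.score_config = score_config or default_score_config()

    # -- profiles ----------------------------------------------------------

    def generate_profiles(
        self, n: Optional[int] = None, seed: Optional[int] = None
    ) -> pd.DataFrame:
        """Draw ``n`` risk profiles as a cohort DataFrame (dialect columns)."""
        cfg = self.config
        n = cfg.n if n is None else n
        if n < 1:
            raise ValidationError("cohort size must be at least 1")
        seed = cfg.seed if seed is None else seed
        ss = np.random.SeedSequence(seed)
        rng = np.random.default_rng(ss.spawn(2)[0])

        load = np.array(
            [cfg.common_factor_loadings.get(f, 0.0) for f in FACTOR_ORDER]
        )
        if np.any(np.abs(load) >= 1):
            raise ConfigurationError("common factor loadings must lie in (-1, 1)")
        sig = cfg.severity_skew
        G = _severity_factor(rng.standard_normal(n), sig)
        Re = _residual_correlation(cfg, load)
        L = np.linalg.cholesky(Re)
        E = rng.standard_normal((n, len(FACTOR_ORDER))) @ L.T
        Z = G[:, None] * load + E * np.sqrt(1.0 - load**2)
        z = {f: Z[:, i] for i, f in enumerate(FACTOR_ORDER)}
        ld = {f: float(load[i]) for i, f in enumerate(FACTOR_ORDER)}

        def flag(name: str, p: float) -> np.ndarray:
            return _flag(z[name], p, ld[name], sig)

        def ordinal(name: str, probs) -> np.ndarray:
            return _ordinal(z[name], probs, ld[name], sig)

        pbk = flag("diagnosis", cfg.p_pbk)
        diagnosis = np.where(pbk == 1, "PBK", "FECD")

        # lens status: PBK is pseudophakic by definition; FECD eyes split
        # phakic / pseudophakic / aphakic on the lens latent
        zl, llens = z["lens_status"], ld["lens_status"]
        q_aph = _latent_quantile(1 - cfg.p_aphakic_fecd, llens, sig) \
            if cfg.p_aphakic_fecd > 0 else np.inf
        q_pse = _latent_quantile(
            max(1e-12, 1 - cfg.p_aphakic_fecd - cfg.p_pseudophakic_fecd), llens, sig
        )
        lens = np.where(
            pbk == 1,
            "pseudophakic",
            np.where(zl > q_aph, "aphakic",
                     np.where(zl > q_pse, "pseudophakic", "phakic")),
        )

        df = pd.DataFrame(
            {
                "eye_id": [f"syn-{i:05d}" for i in range(n)],
                "age": np.round(_continuous(z["age"], cfg.age, True), 1),
                "diagnosis": diagnosis,
                "diabetes": flag("diabetes", cfg.p_diabetes),
                "hypertension": flag("hypertension", cfg.p_hypertension),
                "glaucoma": flag("glaucoma", cfg.p_glaucoma),
                "ice_iris": flag("ice_iris", cfg.p_ice_iris),
                "lens_status": lens,
                "vascularization_grade": ordinal(
                    "vascularization_grade", cfg.p_vascularization
                ),
                "donor_ecd": np.round(_continuous(z["donor_ecd"], cfg.donor_ecd, False)),
                "donor_age": np.round(_continuous(z["donor_age"], cfg.donor_age, True)),
                "scroll_grade": np.array(["I", "II", "III", "IV"], dtype=object)[
                    ordinal("scroll_grade", cfg.p_scroll)
                ],
                "storage_days": np.round(
                    _continuous(z["storage_days"], cfg.storage_days, True), 1
                ),
                "surgeon_cases": np.round(
                    _continuous(z["surgeon_cases"], cfg.surgeon_cases, False)
                ),
                "unfolding_min": np.round(
                    _continuous(z["unfolding_min"], cfg.unfolding_min, True), 1
                ),
                "tamponade": np.where(flag("tamponade", cfg.p_sf6) == 1, "SF6", "air"),
                "triple_dmek": flag("triple_dmek", cfg.p_triple),
                "epi_debridement": flag("epi_debridement", cfg.p_epi_debridement),
                "annual_volume": np.round(
                    _continuous(z["annual_volume"], cfg.annual_volume, False)
                ),
                "bcva_pre": np.round(_continuous(z["bcva_pre"], cfg.bcva_pre, True), 2),
            }
        )
        return df

    def generate_bundles(
        self, n: Optional[int] = None, seed: Optional[int] = None
    ) -> list[RiskProfileBundle]:
        """Typed view of :meth:`generate_profiles`."""
        df = self.generate_profiles(n=n, seed=seed)
        bundles = []
        for _, r in df.iterrows():
            bundles.append(
                RiskProfileBundle(
                    eye_id=r["eye_id"],
                    patient=PatientProfile(
                        age=r["age"],
                        diagnosis=r["diagnosis"],
                        diabetes=bool(r["diabetes"]),
                        hypertension=bool(r["hypertension"]),
                        glaucoma=bool(r["glaucoma"]),
                        ice_or_iris_abnormality=bool(r["ice_iris"]),
                        lens_status=r["lens_status"],
                        vascularization_grade=int(r["vascularization_grade"]),
                    ),
                    donor=DonorProfile(
                        donor_ecd=r["donor_ecd"],
                        donor_age=r["donor_age"],
                        scroll_grade=r["scroll_grade"],
                        storage_time=r["storage_days"],
                    ),
                    surgical=SurgicalProfile(
                        surgeon_experience_cases=r["surgeon_cases"],
                        unfolding_time=r["unfolding_min"],
                        tamponade=r["tamponade"],
                        triple_dmek=bool(r["triple_dmek"]),
                        epithelial_debridement=bool(r["epi_debridement"]),
                    ),
                    center=CenterProfile(annual_dmek_volume=r["annual_volume"]),
                )
            )
        return bundles

    # -- outcomes ----------------------------------------------------------

    def simulate_outcomes(
        self, scored: pd.DataFrame, seed: Optional[int] = None
    ) -> pd.DataFrame:
        """Draw outcomes for a scored cohort under the outcome models.

        Requires ``drop_score`` (and ``diagnosis``) columns; appends the
        ``OUTCOME_COLUMNS``. The generating process is exactly the
        package's prediction equations plus the configured noise.
        """
        if "drop_score" not in scored.columns:
            raise ValidationError("cohort has no 'drop_score' column; score it first")
        cfg, p = self.config, self.params
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
        n = len(scored)
        score = scored["drop_score"].to_numpy(dtype=float)
        diag = scored["diagnosis"].astype(str).to_numpy()
        pbk = (diag == "PBK").astype(float)

        scale = cfg.link_strength_scale

        # graft failure: exponential failure times under the hazard model
        sp = p.survival
        lp = scale * sp.coefficients.get("drop_score", 0.0) * (score - sp.score_center)
        rate = sp.baseline_hazard * np.exp(lp)
        t_fail = rng.exponential(1.0, size=n) / rate
        out = scored.copy()
        out["graft_failure_1y"] = (t_fail <= 12.0).astype(int)
        out["graft_failure_3y"] = (t_fail <= 36.0).astype(int)

        # binary complications from the logistic probabilities
        for name, coef in p.complications.items():
            scaled = coef.model_copy(
                update={
                    "coefficients": {k: scale * v for k, v in coef.coefficients.items()},
                    "intercept": coef.intercept
                    + (1 - scale)
                    * coef.coefficients.get("drop_score", 0.0)
                    * np.mean(score),
                }
            )
            prob = predict_complication(score, {"pbk": pbk}, scaled)
            out[name] = (rng.uniform(size=n) < prob).astype(int)

        # continuous outcomes: model prediction + noise
        bcva_pre = (
            pd.to_numeric(scored["bcva_pre"], errors="coerce").fillna(1.2).to_numpy()
            if "bcva_pre" in scored.columns
            else np.full(n, 1.2)
        )
        bcva_det = predict_bcva(score, bcva_pre, {"pbk": pbk}, p)
        out["bcva_12m"] = np.round(
            np.maximum(bcva_det + rng.normal(0.0, cfg.bcva_noise_sd, size=n), 0.0), 3
        )

        ecd0 = (
            pd.to_numeric(scored["donor_ecd"], errors="coerce")
            .fillna(p.ecd.default_ecd0)
            .to_numpy()
            if "donor_ecd" in scored.columns
            else np.full(n, p.ecd.default_ecd0)
        )
        lam = effective_lambda(score, diag, p)
        sig = cfg.ecd_lognormal_sigma
        noise = np.exp(rng.normal(0.0, sig, size=n) - sig**2 / 2.0)  # mean-one
        ecd12 = predict_ecd(ecd0, lam, 12.0) * noise
        out["ecl_12m_pct"] = np.round((ecd0 - ecd12) / ecd0 * 100.0, 2)
        return out

    # -- one-call pipeline -------------------------------------------------

    def sample(self, n: Optional[int] = None, seed: Optional[int] = None) -> pd.DataFrame:
        """Profiles -> scores -> simulated outcomes, in one deterministic call."""
        profiles = self.generate_profiles(n=n, seed=seed)
        scored = DropScorer(self.score_config).fit(profiles).transform(profiles)
        return self.simulate_outcomes(scored, seed=seed)


def simulate_cohort(
    n: int = 500,
    seed: int = 42,
    config: Union[SimulatorConfig, dict, None] = None,
    params: Union[OutcomeModelParams, dict, None] = None,
) -> pd.DataFrame:
    """Convenience wrapper: default simulator, one seeded cohort."""
    return CohortSimulator(config=config, params=params).sample(n=n, seed=seed)


# ---------------------------------------------------------------------------
# Benchmark summary tables
# ---------------------------------------------------------------------------

def benchmark_tables(simulated: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summaries of a simulated cohort keyed like the validation report.

    Returns ``score_summary`` (distribution of the composite),
    ``category_shares`` (risk-category counts and percentages),
    ``outcomes_by_category`` (outcome x category table) and
    ``aggregate_outcomes`` (cohort-level rates and means).
    """
    from .config import CATEGORIES  # local to avoid cycle noise

    if "drop_score" not in simulated.columns:
        raise ValidationError("cohort has no 'drop_score' column")
    s = simulated["drop_score"]
    score_summary = pd.DataFrame(
        {
            "value": [s.mean(), s.std(ddof=1) if len(s) > 1 else 0.0, s.min(),
                      s.median(), s.max()],
        },
        index=["mean", "sd", "min", "median", "max"],
    )

    cat = pd.Categorical(simulated["risk_category"], categories=list(CATEGORIES))
    counts = pd.Series(cat).value_counts().reindex(CATEGORIES).fillna(0).astype(int)
    category_shares = pd.DataFrame(
        {"n": counts, "pct": 100.0 * counts / len(simulated)}
    )

    present = [c for c in OUTCOME_COLUMNS if c in simulated.columns]
    grouped = simulated.assign(risk_category=cat).groupby("risk_category", observed=True)
    rows = {}
    for col in present:
        if col in ("bcva_12m", "ecl_12m_pct"):
            rows[col] = grouped[col].mean()
        else:
            rows[col] = 100.0 * grouped[col].mean()  # percent
    outcomes_by_category = pd.DataFrame(rows).T
    outcomes_by_category = outcomes_by_category.reindex(
        columns=[c for c in CATEGORIES if c in outcomes_by_category.columns]
    )

    agg = {}
    for col in present:
        if col in ("bcva_12m", "ecl_12m_pct"):
            agg[col + "_mean"] = float(simulated[col].mean())
        else:
            agg[col + "_rate_pct"] = float(100.0 * simulated[col].mean())
    aggregate_outcomes = pd.DataFrame({"value": pd.Series(agg)})

    return {
        "score_summary": score_summary,
        "category_shares": category_shares,
        "outcomes_by_category": outcomes_by_category,
        "aggregate_outcomes": aggregate_outcomes,
    }
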