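"""Synthetic observational data with confounded treatment, two-part
zero-inflated count outcomes and known heterogeneous treatment effects.

The generator emulates the structure of a household-survey evaluation of
subsidised health insurance: mixed demographic / socioeconomic / geographic /
healthcare-access covariates, a binary insurance indicator whose propensity
depends on those covariates (bounded away from 0 and 1), and utilisation
counts produced by a hurdle process — a Bernoulli "participation" gate
(any care use) followed by a zero-truncated count "consumption" intensity
among users. Treatment may shift both components, and the per-row potential
outcome contrasts are returned analytically as ground truth so that every
downstream estimator can be checked against the truth.

Random-number discipline: one master seed fans out into independent named
streams (covariates / treatment / participation / consumption / weights), and
outcome noise is drawn as uniforms that do not depend on the treatment arm,
so regenerating with a flipped treatment vector changes outcomes only through
the effect terms (counterfactual coherence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from ._utils import derive_rng, weighted_mean
from .data import BINARY, CONTINUOUS, ColumnMeta, ObservationTable

logger = logging.getLogger(__name__)

__all__ = [
    "LinearEffect",
    "TwoPartTargetEffect",
    "CovariateConfig",
    "ScenarioConfig",
    "GroundTruth",
    "ztp_mean",
    "ztp_mean_inverse",
    "generate_covariates",
    "simulate_treatment",
    "simulate_outcome",
    "generate_dataset",
    "paper_like_scenario",
    "heterogeneous_scenario",
    "homogeneous_scenario",
    "null_scenario",
]


# ----------------------------------------------------------------------
# effect / coefficient specifications
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class LinearEffect:
    """Linear predictor ``intercept + sum_j coef_j * (x_j - center_j)``.

    Used for the propensity (log-odds scale), the baseline participation
    (log-odds) and consumption (log-mean) models, and for effect terms added
    to those linear predictors under treatment.
    """

    intercept: float = 0.0
    coefs: dict[str, float] = field(default_factory=dict)
    centers: dict[str, float] = field(default_factory=dict)

    def value(self, covariates: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(covariates), float(self.intercept))
        for name, c in self.coefs.items():
            if name not in covariates.columns:
                raise ValueError(f"effect references unknown covariate {name!r}")
            lp += c * (covariates[name].to_numpy(dtype=float) - self.centers.get(name, 0.0))
        return lp


@dataclass(frozen=True)
class TwoPartTargetEffect:
    """Consumption effect calibrated so the *two-part* treatment effect equals
    a prescribed linear function of the covariates exactly.

    With no participation effect, the two-part contrast is
    ``tau(x) = m1(x) * (m2_1(x) - m2_0(x))``.  Given a target ``g(x)`` this
    solves, row by row, for the treated zero-truncated mean
    ``m2_1 = m2_0 + g(x) / m1(x)`` so that ``tau(x) = g(x)`` holds exactly.
    Requires ``g(x) > 0`` on the support (the treated truncated mean must stay
    above the untreated one).
    """

    target: LinearEffect

    def value(self, covariates: pd.DataFrame) -> np.ndarray:
        return self.target.value(covariates)


# ----------------------------------------------------------------------
# covariate blocks
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateConfig:
    """Block structure of the covariate matrix.

    Defaults emulate a national household survey: age and per-capita monthly
    expenditure (in 100k-currency units) as continuous blocks, an urban
    indicator, socioeconomic binaries at survey-like rates, a 7-category
    region one-hot block, and healthcare-access indicators correlated with
    urbanicity and region.
    """

    age_mean: float = 30.0
    age_sd: float = 20.0
    age_range: tuple[float, float] = (0.0, 99.0)
    expenditure_meanlog: float = 1.80
    expenditure_sdlog: float = 0.70
    expenditure_cap: float = 60.0  # top-coding, as household surveys apply
    urban_rate: float = 0.47
    binary_rates: dict[str, float] = field(default_factory=lambda: {
        "male": 0.50,
        "edu_compulsory": 0.58,
        "literate": 0.82,
        "employed": 0.42,
        "married": 0.45,
        "internet": 0.24,
        "own_home": 0.84,
        "savings": 0.45,
        "food_insecure": 0.26,
        "car": 0.09,
    })
    region_probs: dict[str, float] = field(default_factory=lambda: {
        "sumatera": 0.22, "jakarta": 0.03, "java": 0.51, "bali_nt": 0.06,
        "kalimantan": 0.07, "sulawesi": 0.08, "maluku_papua": 0.03,
    })
    # access indicators: P(easy access) = logistic(base + b_urban*urban + b_jakarta*jakarta)
    access_spec: dict[str, tuple[float, float, float]] = field(default_factory=lambda: {
        "access_primary": (1.2, 0.6, 1.0),
        "access_secondary": (0.9, 0.8, 1.2),
        "access_community": (2.2, 0.4, 0.8),
        "access_maternal": (1.5, 0.5, 0.8),
    })

    def validate(self) -> None:
        for name, r in {**self.binary_rates, "urban": self.urban_rate}.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate for {name!r} outside [0,1]")
        probs = np.array(list(self.region_probs.values()))
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("region probabilities must be non-negative and sum to 1")
        if self.age_sd <= 0 or self.expenditure_sdlog <= 0:
            raise ValueError("scale parameters must be positive")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full data-generating scenario: covariates, treatment assignment and
    two-part outcome process with treatment-effect terms."""

    n: int
    seed: int
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    propensity: LinearEffect = field(default_factory=LinearEffect)
    participation: LinearEffect = field(default_factory=LinearEffect)
    participation_effect: LinearEffect = field(default_factory=LinearEffect)
    consumption: LinearEffect = field(default_factory=LinearEffect)
    consumption_effect: LinearEffect | TwoPartTargetEffect = field(default_factory=LinearEffect)
    consumption_family: str = "ztpoisson"  # or "ztnb"
    nb_dispersion: float = 2.0  # theta for the negative-binomial option
    weight_spec: tuple = ("constant",)
    log_mean_bound: float = 8.0  # clip on log consumption means
    outcome_name: str = "visits"

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.consumption_family not in {"ztpoisson", "ztnb"}:
            raise ValueError(f"unknown consumption family {self.consumption_family!r}")
        self.covariates.validate()


@dataclass
class GroundTruth:
    """Analytic per-row potential-outcome quantities of a generated dataset."""

    e_true: np.ndarray
    m1_true: np.ndarray  # (n, 2): participation probability under d=0,1
    m2_true: np.ndarray  # (n, 2): truncated-count mean under d=0,1
    tau1_true: np.ndarray  # participation contrast
    tau2_true: np.ndarray  # consumption contrast (always-user scale)
    tau_true: np.ndarray  # two-part contrast m1(1)m2(1) - m1(0)m2(0)
    ate_true: dict[str, float] = field(default_factory=dict)


# ----------------------------------------------------------------------
# zero-truncated count moments
# ----------------------------------------------------------------------

def ztp_mean(lam) -> np.ndarray:
    """Mean of the zero-truncated Poisson: lambda / (1 - exp(-lambda))."""
    lam = np.asarray(lam, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = lam / -np.expm1(-lam)
    return np.where(lam <= 0, 1.0, m)  # limit as lambda -> 0+ is 1


def ztp_mean_inverse(mu) -> np.ndarray:
    """Solve ztp_mean(lambda) = mu for lambda (mu > 1), by Newton iteration.

    The truncated mean is strictly increasing in lambda with derivative in
    (0, 1]; starting from lambda = mu the iteration converges monotonically.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 1.0):
        raise ValueError("zero-truncated Poisson mean must exceed 1")
    lam = np.maximum(mu - 1.0, 1e-8)
    for _ in range(60):
        em = -np.expm1(-lam)  # 1 - exp(-lam)
        f = lam / em - mu
        # d/dlam [lam / (1 - e^-lam)]
        df = (em - lam * np.exp(-lam)) / em**2
        step = f / np.maximum(df, 1e-12)
        lam = np.maximum(lam - step, 1e-10)
        if np.max(np.abs(f)) < 1e-12:
            break
    return lam


def _ztnb_p0(mu, theta):
    return (theta / (theta + mu)) ** theta


def ztnb_mean(mu, theta) -> np.ndarray:
    """Mean of the zero-truncated negative binomial with NB mean mu, size theta."""
    mu = np.asarray(mu, dtype=float)
    return mu / (1.0 - _ztnb_p0(mu, theta))


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------

def generate_covariates(config: ScenarioConfig) -> tuple[pd.DataFrame, list[ColumnMeta]]:
    """Draw the covariate matrix; deterministic given the scenario seed."""
    config.validate()
    cc = config.covariates
    n = config.n
    rng = derive_rng(config.seed, "covariates")

    cols: dict[str, np.ndarray] = {}
    meta: list[ColumnMeta] = []

    age = np.clip(rng.normal(cc.age_mean, cc.age_sd, n), *cc.age_range)
    cols["age"] = age
    meta.append(ColumnMeta("age", CONTINUOUS))

    cols["expenditure"] = np.minimum(
        rng.lognormal(cc.expenditure_meanlog, cc.expenditure_sdlog, n),
        cc.expenditure_cap)
    meta.append(ColumnMeta("expenditure", CONTINUOUS))

    urban = (rng.random(n) < cc.urban_rate).astype(float)
    cols["urban"] = urban
    meta.append(ColumnMeta("urban", BINARY))

    for name, rate in cc.binary_rates.items():
        cols[name] = (rng.random(n) < rate).astype(float)
        meta.append(ColumnMeta(name, BINARY))

    region_names = list(cc.region_probs)
    probs = np.array([cc.region_probs[r] for r in region_names])
    draws = rng.choice(len(region_names), size=n, p=probs)
    for j, r in enumerate(region_names):
        col = f"region_{r}"
        cols[col] = (draws == j).astype(float)
        meta.append(ColumnMeta(col, "onehot-group:region"))

    jakarta = cols.get("region_jakarta", np.zeros(n))
    for name, (base, b_urban, b_jak) in cc.access_spec.items():
        p = expit(base + b_urban * urban + b_jak * jakarta)
        cols[name] = (rng.random(n) < p).astype(float)
        meta.append(ColumnMeta(name, BINARY))

    return pd.DataFrame(cols), meta


def simulate_treatment(covariates: pd.DataFrame, propensity: LinearEffect,
                       seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli treatment with logistic propensity on the covariates."""
    e_true = expit(propensity.value(covariates))
    rng = derive_rng(seed, "treatment")
    d = (rng.random(len(covariates)) < e_true).astype(np.int8)
    return d, e_true


def _consumption_log_means(config: ScenarioConfig, covariates: pd.DataFrame,
                           m1_by_arm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log consumption means (lam or NB mu) for d=0 and d=1."""
    bound = config.log_mean_bound
    lp0 = config.consumption.value(covariates)
    if np.any(np.abs(lp0) > bound):
        logger.warning("clipping %d baseline log-mean values at ±%g",
                       int(np.sum(np.abs(lp0) > bound)), bound)
        lp0 = np.clip(lp0, -bound, bound)

    eff = config.consumption_effect
    if isinstance(eff, TwoPartTargetEffect):
        if config.consumption_family != "ztpoisson":
            raise ValueError("target-calibrated consumption effect requires ztpoisson")
        g = eff.value(covariates)
        if np.any(g <= 0):
            raise ValueError("two-part target effect must be positive on the support")
        m1_0 = m1_by_arm[:, 0]
        mu1 = ztp_mean(np.exp(lp0)) + g / np.maximum(m1_0, 1e-8)
        lp1 = np.log(ztp_mean_inverse(mu1))
    else:
        lp1 = lp0 + eff.value(covariates)
    if np.any(np.abs(lp1) > bound):
        logger.warning("clipping %d treated log-mean values at ±%g",
                       int(np.sum(np.abs(lp1) > bound)), bound)
        lp1 = np.clip(lp1, -bound, bound)
    return lp0, lp1


def _truncated_mean(config: ScenarioConfig, log_mean: np.ndarray) -> np.ndarray:
    mu = np.exp(log_mean)
    if config.consumption_family == "ztpoisson":
        return ztp_mean(mu)
    return ztnb_mean(mu, config.nb_dispersion)


def _sample_truncated(config: ScenarioConfig, log_mean: np.ndarray,
                      u: np.ndarray) -> np.ndarray:
    """Inverse-CDF sample of the zero-truncated count given uniforms u."""
    mu = np.exp(log_mean)
    if config.consumption_family == "ztpoisson":
        p0 = np.exp(-mu)
        c = stats.poisson.ppf(p0 + u * (1.0 - p0), mu)
    else:
        theta = config.nb_dispersion
        p0 = _ztnb_p0(mu, theta)
        pnb = theta / (theta + mu)
        c = stats.nbinom.ppf(p0 + u * (1.0 - p0), theta, pnb)
    return np.maximum(c, 1.0)


def simulate_outcome(config: ScenarioConfig, covariates: pd.DataFrame,
                     d: np.ndarray, e_true: np.ndarray,
                     weights: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, GroundTruth]:
    """Draw the hurdle outcome and fill the analytic ground truth.

    Participation is Bernoulli with logit ``beta'x + d * tau1-predictor``;
    given participation, consumption is a zero-truncated count with log mean
    ``gamma'x + d * effect`` (or the target-calibrated treated mean).  The
    uniforms driving both stages are arm-independent.
    """
    n = len(covariates)
    d = np.asarray(d)

    lp_part = config.participation.value(covariates)
    eff_part = config.participation_effect.value(covariates)
    m1 = np.column_stack([expit(lp_part), expit(lp_part + eff_part)])

    lp0, lp1 = _consumption_log_means(config, covariates, m1)
    m2 = np.column_stack([_truncated_mean(config, lp0), _truncated_mean(config, lp1)])

    u_part = derive_rng(config.seed, "participation").random(n)
    u_cons = derive_rng(config.seed, "consumption").random(n)

    p_own = np.where(d == 1, m1[:, 1], m1[:, 0])
    z = (u_part < p_own).astype(np.int64)
    log_mean_own = np.where(d == 1, lp1, lp0)
    c = _sample_truncated(config, log_mean_own, u_cons)
    y = (z * c).astype(np.int64)

    tau1 = m1[:, 1] - m1[:, 0]
    tau2 = m2[:, 1] - m2[:, 0]
    tau = m1[:, 1] * m2[:, 1] - m1[:, 0] * m2[:, 0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    gt = GroundTruth(
        e_true=np.asarray(e_true, dtype=float),
        m1_true=m1, m2_true=m2,
        tau1_true=tau1, tau2_true=tau2, tau_true=tau,
        ate_true={
            "two_part": weighted_mean(tau, w),
            "participation": weighted_mean(tau1, w),
            "consumption": weighted_mean(tau2, w),
        },
    )
    return y, gt


def _draw_weights(config: ScenarioConfig) -> np.ndarray:
    spec = config.weight_spec
    n = config.n
    if spec[0] == "constant":
        return np.ones(n)
    rng = derive_rng(config.seed, "weights")
    if spec[0] == "integer_uniform":
        lo, hi = int(spec[1]), int(spec[2])
        return rng.integers(lo, hi + 1, n).astype(float)
    if spec[0] == "uniform":
        lo, hi = float(spec[1]), float(spec[2])
        return rng.uniform(lo, hi, n)
    raise ValueError(f"unknown weight spec {spec!r}")


def generate_dataset(config: ScenarioConfig) -> tuple[ObservationTable, GroundTruth]:
    """Generate a full dataset: covariates, treatment, outcome, weights.

    Asserts empirical overlap: all true propensities strictly inside
    (0.01, 0.99).
    """
    cov, meta = generate_covariates(config)
    d, e_true = simulate_treatment(cov, config.propensity, config.seed)
    if e_true.min() <= 0.01 or e_true.max() >= 0.99:
        raise ValueError(
            f"scenario violates overlap: propensity range "
            f"[{e_true.min():.4f}, {e_true.max():.4f}] not within (0.01, 0.99)")
    weights = _draw_weights(config)
    y, gt = simulate_outcome(config, cov, d, e_true, weights)
    table = ObservationTable(cov, d, {config.outcome_name: y}, weights, meta)
    return table, gt


# ----------------------------------------------------------------------
# shipped scenarios
# ----------------------------------------------------------------------

def _base_propensity() -> LinearEffect:
    return LinearEffect(
        intercept=-0.10,
        coefs={
            "age": 0.012, "expenditure": -0.02, "literate": 0.35,
            "edu_compulsory": 0.25, "urban": -0.10, "access_primary": -0.20,
            "region_jakarta": 0.70, "region_sulawesi": 0.40, "region_java": -0.30,
        },
        centers={"age": 30.0, "expenditure": 8.0},
    )


def _base_participation() -> LinearEffect:
    return LinearEffect(
        intercept=-1.30,
        coefs={"age": 0.008, "expenditure": 0.02, "access_primary": 0.30, "urban": 0.10},
        centers={"age": 30.0, "expenditure": 8.0},
    )


def _base_consumption() -> LinearEffect:
    return LinearEffect(
        intercept=0.70,
        coefs={"age": 0.005, "expenditure": 0.01, "access_secondary": 0.15},
        centers={"age": 30.0, "expenditure": 8.0},
    )


def paper_like_scenario(n: int = 20_000, seed: int = 7, **overrides) -> ScenarioConfig:
    """Default survey-like scenario: confounded treatment, ~70-80% zeros,
    positive two-part ATE with a participation effect much smaller than the
    consumption effect."""
    cfg = ScenarioConfig(
        n=n, seed=seed,
        propensity=_base_propensity(),
        participation=_base_participation(),
        participation_effect=LinearEffect(intercept=0.15),
        consumption=_base_consumption(),
        consumption_effect=LinearEffect(intercept=0.35),
    )
    return replace(cfg, **overrides) if overrides else cfg


def heterogeneous_scenario(n: int = 20_000, seed: int = 7, **overrides) -> ScenarioConfig:
    """Effect heterogeneity driven by supply-side access (urban location, the
    classic urban/rural facility-availability divide) and age.

    The two-part treatment effect is exactly
    ``tau(x) = 0.5 + 1.0 * urban + 0.015 * (age - 30)``
    (participation effect zero; consumption effect target-calibrated), so the
    best linear projection of the true effect on (urban, age) has
    coefficients exactly (1.0, 0.015) with intercept 0.5.
    """
    target = LinearEffect(intercept=0.5,
                          coefs={"urban": 1.0, "age": 0.015},
                          centers={"age": 30.0})
    cfg = ScenarioConfig(
        n=n, seed=seed,
        propensity=_base_propensity(),
        participation=_base_participation(),
        participation_effect=LinearEffect(),
        consumption=_base_consumption(),
        consumption_effect=TwoPartTargetEffect(target),
    )
    return replace(cfg, **overrides) if overrides else cfg


def homogeneous_scenario(n: int = 20_000, seed: int = 7, effect: float = 0.5,
                         **overrides) -> ScenarioConfig:
    """Constant two-part effect tau(x) = effect exactly, for GATE calibration."""
    cfg = ScenarioConfig(
        n=n, seed=seed,
        propensity=_base_propensity(),
        participation=_base_participation(),
        participation_effect=LinearEffect(),
        consumption=_base_consumption(),
        consumption_effect=TwoPartTargetEffect(LinearEffect(intercept=effect)),
    )
    return replace(cfg, **overrides) if overrides else cfg


def null_scenario(n: int = 20_000, seed: int = 7, **overrides) -> ScenarioConfig:
    """No treatment effect anywhere (confounding retained)."""
    cfg = ScenarioConfig(
        n=n, seed=seed,
        propensity=_base_propensity(),
        participation=_base_participation(),
        participation_effect=LinearEffect(),
        consumption=_base_consumption(),
        consumption_effect=LinearEffect(),
    )
    return replace(cfg, **overrides) if overrides else cfg


SCENARIOS = {
    "paper_like": paper_like_scenario,
    "heterogeneous": heterogeneous_scenario,
    "homogeneous": homogeneous_scenario,
    "null": null_scenario,
}
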