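"""Doubly robust scores, AIPTW average treatment effects, and IPTW balance
diagnostics.

The per-observation doubly robust (AIPTW) score is

    Gamma_i = tau_hat(X_i) + (D_i - e_i) / (e_i (1 - e_i))
              * ( Y_i - m_i - (D_i - e_i) * tau_hat(X_i) ),

whose weighted mean estimates the ATE and is consistent if either the
propensity e or the outcome model (m, tau_hat) is correct.  Standard errors
use the weighted influence-function form with the Kish effective sample size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import kish_neff, weighted_mean, weighted_sd, weighted_var
from .data import ObservationTable

logger = logging.getLogger(__name__)

__all__ = [
    "AteEstimate",
    "dr_score",
    "aiptw_ate",
    "iptw_weights",
    "smd",
    "balance_table",
    "overlap_report",
    "clip_propensity",
]

PROPENSITY_CLIP = 0.01
Z95 = 1.959963984540054  # two-sided 95% normal quantile


def clip_propensity(e_hat, eps: float = PROPENSITY_CLIP) -> np.ndarray:
    e = np.asarray(e_hat, float)
    n_clip = int(np.sum((e < eps) | (e > 1 - eps)))
    if n_clip:
        logger.warning("clipping %d propensity scores to [%g, %g]", n_clip, eps, 1 - eps)
    return np.clip(e, eps, 1 - eps)


def dr_score(tau_hat, e_hat, m_hat, d, y, clip: float = PROPENSITY_CLIP) -> np.ndarray:
    """Per-observation AIPTW doubly robust scores Gamma_i."""
    tau = np.asarray(tau_hat, float)
    e = clip_propensity(e_hat, clip)
    m = np.asarray(m_hat, float)
    d = np.asarray(d, float)
    y = np.asarray(y, float)
    resid = y - m - (d - e) * tau
    return tau + (d - e) / (e * (1.0 - e)) * resid


@dataclass(frozen=True)
class AteEstimate:
    estimate: float
    se: float
    ci95: tuple[float, float]
    n_effective: float
    model_tag: str = ""

    def covers(self, value: float) -> bool:
        return self.ci95[0] <= value <= self.ci95[1]


def aiptw_ate(gamma, weights=None, model_tag: str = "") -> AteEstimate:
    """Weighted mean of the DR scores with influence-function SE
    (weighted SD over the Kish effective sample size)."""
    gamma = np.asarray(gamma, float)
    if gamma.size == 0:
        raise ValueError("empty score vector")
    w = np.ones(len(gamma)) if weights is None else np.asarray(weights, float)
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    est = weighted_mean(gamma, w)
    neff = kish_neff(w)
    se = weighted_sd(gamma, w) / np.sqrt(neff)
    return AteEstimate(est, se, (est - Z95 * se, est + Z95 * se), neff, model_tag)


def iptw_weights(d, e_hat, estimand: str = "ATE", survey_weights=None,
                 clip: float = PROPENSITY_CLIP) -> np.ndarray:
    """Inverse-probability-of-treatment weights times survey weights.

    ATE: 1/e for treated, 1/(1-e) for controls.  ATT: 1 for treated,
    e/(1-e) for controls.
    """
    d = np.asarray(d, float)
    e = clip_propensity(e_hat, clip)
    if estimand == "ATE":
        ipw = np.where(d == 1, 1.0 / e, 1.0 / (1.0 - e))
    elif estimand == "ATT":
        ipw = np.where(d == 1, 1.0, e / (1.0 - e))
    else:
        raise ValueError(f"unknown estimand {estimand!r}")
    if survey_weights is not None:
        ipw = ipw * np.asarray(survey_weights, float)
    return ipw


def smd(x, group, weights=None) -> float:
    """Standardised mean difference (group 1 minus group 0) with the pooled-SD
    denominator sqrt((s1^2 + s0^2) / 2); weighted means and variances."""
    x = np.asarray(x, float)
    g = np.asarray(group)
    w = np.ones(len(x)) if weights is None else np.asarray(weights, float)
    m1, m0 = (g == 1), (g == 0)
    if not m1.any() or not m0.any():
        raise ValueError("both groups must be non-empty")
    mu1, mu0 = weighted_mean(x[m1], w[m1]), weighted_mean(x[m0], w[m0])
    v1, v0 = weighted_var(x[m1], w[m1]), weighted_var(x[m0], w[m0])
    pooled = (v1 + v0) / 2.0
    if pooled <= 0:
        return 0.0 if np.isclose(mu1, mu0) else np.inf
    return float((mu1 - mu0) / np.sqrt(pooled))


def balance_table(table: ObservationTable, e_hat=None,
                  threshold: float = 0.1) -> pd.DataFrame:
    """Per-covariate means/SDs by arm, raw SMD and (when propensities are
    given) IPTW-weighted SMD, flagged at |SMD| >= threshold."""
    d = table.treatment
    w = table.weights
    rows = []
    ipw = iptw_weights(d, e_hat, "ATE", w) if e_hat is not None else None
    for name in table.covariate_names:
        x = table.covariates[name].to_numpy()
        m1, m0 = (d == 1), (d == 0)
        raw = smd(x, d, w)
        rec = {
            "covariate": name,
            "mean_control": weighted_mean(x[m0], w[m0]),
            "sd_control": weighted_sd(x[m0], w[m0]),
            "mean_treated": weighted_mean(x[m1], w[m1]),
            "sd_treated": weighted_sd(x[m1], w[m1]),
            "smd_raw": raw,
            "flag_raw": abs(raw) >= threshold,
        }
        if ipw is not None:
            wsmd = smd(x, d, ipw)
            rec["smd_iptw"] = wsmd
            rec["flag_iptw"] = abs(wsmd) >= threshold
        rows.append(rec)
    return pd.DataFrame(rows)


def overlap_report(e_hat, d, bins: int = 25,
                   clip: float = PROPENSITY_CLIP) -> dict:
    """Per-arm propensity histogram coordinates plus clipping counts."""
    e = np.asarray(e_hat, float)
    d = np.asarray(d)
    edges = np.linspace(0.0, 1.0, bins + 1)
    hist1, _ = np.histogram(e[d == 1], bins=edges)
    hist0, _ = np.histogram(e[d == 0], bins=edges)
    return {
        "bin_edges": edges,
        "treated_counts": hist1,
        "control_counts": hist0,
        "min": float(e.min()),
        "max": float(e.max()),
        "n_clipped": int(np.sum((e < clip) | (e > 1 - clip))),
    }
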