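"""Heterogeneity summaries built on the cross-fitted DR-score panel.

All summaries consume per-observation doubly robust scores Gamma_i (so group
means remain unbiased ATE estimates under confounding) together with the
out-of-sample CATE predictions tau_hat(X_i) used only for ranking/grouping:

* sorted GATEs: ATEs within weighted quintiles of tau_hat;
* pairwise quintile contrasts Qk - Q1 with Romano-Wolf stepdown adjustment
  from a studentised pairs bootstrap within quintiles;
* classification analysis: quintile covariate profiles, normalised distances
  from overall means, and data-driven modifier discovery by Q1-vs-Q5 SMD;
* subgroup GATEs over dichotomised modifiers;
* best linear projection (BLP): weighted OLS of Gamma on chosen regressors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._utils import kish_neff, weighted_mean, weighted_quantile, weighted_sd
from .data import BINARY, ObservationTable
from .effects import Z95, smd

logger = logging.getLogger(__name__)

__all__ = [
    "QuintileAssignment",
    "BlpResult",
    "ClassificationResult",
    "assign_quintiles",
    "sorted_gates",
    "quintile_difference_tests",
    "classification_analysis",
    "subgroup_gates",
    "blp",
]


@dataclass(frozen=True)
class QuintileAssignment:
    labels: np.ndarray  # 1..n_groups per row
    cutpoints: np.ndarray
    n_groups: int = 5

    def rows(self, q: int) -> np.ndarray:
        return np.flatnonzero(self.labels == q)


def assign_quintiles(tau_hat, weights=None, n_groups: int = 5) -> QuintileAssignment:
    """Weighted quantile groups of tau_hat (Q1 lowest .. Q5 highest).

    Rows are ranked by tau_hat with stable original-order tie-breaking, then
    cut at equal shares of total weight (each row placed by the midpoint of
    its weight interval), so group shares are as equal as the tie mass and
    weight discreteness allow, invariant to rescaling the weights.
    """
    tau = np.asarray(tau_hat, float)
    if not np.all(np.isfinite(tau)):
        raise ValueError("tau_hat must be finite")
    w = np.ones(len(tau)) if weights is None else np.asarray(weights, float)
    if tau.min() == tau.max():
        logger.warning("all CATE predictions identical; assigning every row to Q1")
        return QuintileAssignment(np.ones(len(tau), np.int64), np.array([]), n_groups)
    order = np.argsort(tau, kind="stable")
    cw = np.cumsum(w[order])
    mid = (cw - w[order] / 2.0) / w.sum()
    lab_sorted = np.minimum((mid * n_groups).astype(np.int64), n_groups - 1) + 1
    labels = np.empty(len(tau), np.int64)
    labels[order] = lab_sorted
    cut = weighted_quantile(tau, w, np.arange(1, n_groups) / n_groups)
    return QuintileAssignment(labels, cut, n_groups)


def _group_gate(gamma, w) -> dict:
    est = weighted_mean(gamma, w)
    neff = kish_neff(w)
    se = weighted_sd(gamma, w) / np.sqrt(neff)
    return {"estimate": est, "se": se, "lo": est - Z95 * se, "hi": est + Z95 * se,
            "n_effective": neff}


def sorted_gates(gamma, assignment: QuintileAssignment, weights=None) -> pd.DataFrame:
    """Per-quintile weighted mean of the DR scores with influence-function SE."""
    gamma = np.asarray(gamma, float)
    w = np.ones(len(gamma)) if weights is None else np.asarray(weights, float)
    rows = []
    for q in range(1, assignment.n_groups + 1):
        idx = assignment.rows(q)
        if len(idx) == 0:
            raise ValueError(f"quintile Q{q} is empty")
        rows.append({"group": f"Q{q}", **_group_gate(gamma[idx], w[idx])})
    return pd.DataFrame(rows)


def quintile_difference_tests(gamma, assignment: QuintileAssignment, weights=None,
                              n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Contrasts Qk - Q1 with Romano-Wolf stepdown adjusted p-values.

    Studentised statistics; the null distribution comes from a pairs
    bootstrap resampling rows with replacement *within* quintiles and
    re-centring at the observed contrasts.  Both unadjusted and adjusted
    p-values are bootstrap-based, so adjusted >= unadjusted holds by
    construction and the single-contrast case reduces to the unadjusted test.
    """
    if n_boot < 200:
        raise ValueError("need at least 200 bootstrap replicates")
    gamma = np.asarray(gamma, float)
    w = np.ones(len(gamma)) if weights is None else np.asarray(weights, float)
    rng = np.random.default_rng(seed)
    groups = list(range(1, assignment.n_groups + 1))

    obs_mean, obs_se2 = {}, {}
    boot_mean, boot_se2 = {}, {}
    for q in groups:
        idx = assignment.rows(q)
        g, wq = gamma[idx], w[idx]
        stat = _group_gate(g, wq)
        obs_mean[q], obs_se2[q] = stat["estimate"], stat["se"] ** 2
        take = rng.integers(0, len(idx), size=(n_boot, len(idx)))
        wB, gB = wq[take], g[take]
        swB = wB.sum(1)
        mB = (wB * gB).sum(1) / swB
        varB = (wB * (gB - mB[:, None]) ** 2).sum(1) / np.maximum(swB - 1.0, 1e-12)
        neffB = swB**2 / (wB**2).sum(1)
        boot_mean[q], boot_se2[q] = mB, varB / neffB

    contrasts = [q for q in groups if q != 1]
    est = np.array([obs_mean[q] - obs_mean[1] for q in contrasts])
    se = np.sqrt([obs_se2[q] + obs_se2[1] for q in contrasts])
    t_obs = est / se
    t_boot = np.column_stack([
        (boot_mean[q] - boot_mean[1] - (obs_mean[q] - obs_mean[1]))
        / np.sqrt(boot_se2[q] + boot_se2[1])
        for q in contrasts])  # (n_boot, n_contrasts), centred & studentised

    abs_t = np.abs(t_obs)
    p_unadj = (np.abs(t_boot) >= abs_t).mean(axis=0)
    # stepdown: most significant first; compare against max over the
    # not-yet-rejected set; enforce monotonicity down the ordering
    order = np.argsort(-abs_t, kind="stable")
    p_adj = np.empty(len(contrasts))
    running_max = 0.0
    for step, h in enumerate(order):
        remaining = order[step:]
        max_boot = np.abs(t_boot[:, remaining]).max(axis=1)
        p = float((max_boot >= abs_t[h]).mean())
        running_max = max(running_max, p)
        p_adj[h] = running_max
    p_normal = 2.0 * sps.norm.sf(abs_t)
    return pd.DataFrame({
        "contrast": [f"Q{q}-Q1" for q in contrasts],
        "estimate": est, "se": se, "t": t_obs,
        "p_unadjusted": p_unadj, "p_adjusted": p_adj,
        "p_normal": p_normal,
    })


@dataclass
class ClassificationResult:
    table: pd.DataFrame  # covariate x quintile: mean, se, distance
    ranking: pd.DataFrame  # covariate, smd_q1_q5, rank (excluded covariates noted)
    top_modifiers: list[str]


def classification_analysis(table: ObservationTable, assignment: QuintileAssignment,
                            top_k: int = 20, top_modifiers: int = 5,
                            ) -> ClassificationResult:
    """Quintile covariate profiles and data-driven effect-modifier discovery.

    For every covariate and quintile: weighted mean, SE, and the normalised
    distance |quintile mean - overall mean| / overall SD.  Covariates are
    ranked by |SMD(Q1 vs Q5)|; the top_k are retained for plotting and the
    top_modifiers names returned as data-driven effect modifiers.
    Zero-variance covariates are excluded from the ranking.
    """
    w = table.weights
    labels = assignment.labels
    recs, rank_rows = [], []
    for name in table.covariate_names:
        x = table.covariates[name].to_numpy()
        mu_all = weighted_mean(x, w)
        sd_all = weighted_sd(x, w)
        for q in range(1, assignment.n_groups + 1):
            idx = assignment.rows(q)
            mu_q = weighted_mean(x[idx], w[idx])
            se_q = weighted_sd(x[idx], w[idx]) / np.sqrt(kish_neff(w[idx]))
            dist = abs(mu_q - mu_all) / sd_all if sd_all > 0 else 0.0
            recs.append({"covariate": name, "group": f"Q{q}", "mean": mu_q,
                         "se": se_q, "distance": dist})
        if sd_all <= 0:
            rank_rows.append({"covariate": name, "smd_q1_q5": np.nan,
                              "excluded": True})
            continue
        sel = (labels == 1) | (labels == assignment.n_groups)
        grp = (labels[sel] == assignment.n_groups).astype(int)
        val = smd(x[sel], grp, w[sel])
        rank_rows.append({"covariate": name, "smd_q1_q5": val, "excluded": False})
    ranking = pd.DataFrame(rank_rows)
    ranked = ranking[~ranking["excluded"]].copy()
    ranked["abs_smd"] = ranked["smd_q1_q5"].abs()
    ranked = ranked.sort_values("abs_smd", ascending=False, kind="stable")
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    ranking = ranking.merge(ranked[["covariate", "rank"]], on="covariate", how="left")
    keep = set(ranked.head(top_k)["covariate"])
    long = pd.DataFrame(recs)
    long["in_top_k"] = long["covariate"].isin(keep)
    return ClassificationResult(long, ranking.sort_values("rank", na_position="last"),
                                ranked.head(top_modifiers)["covariate"].tolist())


def _dichotomise(x: np.ndarray, w: np.ndarray, rule) -> tuple[np.ndarray, list[str]]:
    """Return integer level codes and level names for a modifier column."""
    if rule is None or rule == ("median",):
        cut = weighted_quantile(x, w, 0.5)[0]
        return (x > cut).astype(int), [f"<= {cut:.4g}", f"> {cut:.4g}"]
    kind = rule[0]
    if kind == "cutpoints":
        edges = list(rule[1])
        codes = np.searchsorted(edges, x, side="right")
        names = []
        lo = None
        for e in edges:
            names.append(f"<= {e:g}" if lo is None else f"({lo:g}, {e:g}]")
            lo = e
        names.append(f"> {edges[-1]:g}")
        return codes, names
    raise ValueError(f"unknown dichotomisation rule {rule!r}")


AGE_BANDS = ("cutpoints", (24, 49, 64, 74))  # <25, 25-49, 50-64, 65-74, 75+


def subgroup_gates(gamma, table: ObservationTable, modifiers: list[str],
                   weights=None, mask=None, rules: dict | None = None) -> pd.DataFrame:
    """GATEs within levels of each modifier (AIPTW on restricted samples).

    Binary covariates use their 0/1 levels; continuous covariates are
    dichotomised at the weighted median unless a rule (e.g. age bands or
    expenditure quartile cutpoints) is supplied.  Empty levels are skipped
    with a warning.
    """
    gamma = np.asarray(gamma, float)
    w = table.weights if weights is None else np.asarray(weights, float)
    mask = np.ones(len(gamma), bool) if mask is None else np.asarray(mask, bool)
    rules = rules or {}
    kinds = {m.name: m.kind for m in table.covariate_meta}
    rows = []
    for name in modifiers:
        x = table.covariates[name].to_numpy()
        if kinds.get(name) == BINARY or name in kinds and kinds[name].startswith("onehot"):
            codes, names = x.astype(int), ["0", "1"]
        else:
            codes, names = _dichotomise(x[mask], w[mask], rules.get(name))
            full = np.zeros(len(x), int)
            full[mask] = codes
            codes = full
        for lv in range(len(names)):
            idx = np.flatnonzero(mask & (codes == lv))
            if len(idx) == 0:
                logger.warning("modifier %s level %s empty; skipped", name, names[lv])
                continue
            rows.append({"modifier": name, "level": names[lv],
                         **_group_gate(gamma[idx], w[idx])})
    return pd.DataFrame(rows)


@dataclass
class BlpResult:
    coefficients: pd.DataFrame  # term, estimate, se, p (+ conventional columns)
    intercept: float
    regressor_set: str = "restricted"

    def coef(self, term: str) -> float:
        row = self.coefficients.set_index("term").loc[term]
        return float(row["estimate"])


def blp(gamma, regressors: pd.DataFrame, weights=None, mask=None,
        regressor_set: str = "restricted") -> BlpResult:
    """Best linear projection: weighted OLS of the DR scores on regressors.

    Reports heteroskedasticity-robust (HC1) standard errors as the default
    alongside conventional ones (DR scores are heteroskedastic by
    construction).  Rank-deficient designs fall back to the pseudoinverse
    with a warning.
    """
    import statsmodels.api as sm

    gamma = np.asarray(gamma, float)
    mask = np.ones(len(gamma), bool) if mask is None else np.asarray(mask, bool)
    w = np.ones(len(gamma)) if weights is None else np.asarray(weights, float)
    Xr = pd.DataFrame(regressors).loc[mask].reset_index(drop=True)
    X = sm.add_constant(Xr.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        logger.warning("rank-deficient BLP design; pseudoinverse solution")
    res = sm.WLS(gamma[mask], X, weights=w[mask]).fit()
    robust = res.get_robustcov_results(cov_type="HC1")
    terms = ["const", *Xr.columns.astype(str)]
    out = pd.DataFrame({
        "term": terms,
        "estimate": res.params,
        "se": np.asarray(robust.bse),
        "p": np.asarray(robust.pvalues),
        "se_conventional": res.bse,
        "p_conventional": res.pvalues,
    })
    return BlpResult(out, float(res.params[0]), regressor_set)
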