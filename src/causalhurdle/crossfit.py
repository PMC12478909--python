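"""Three-fold cross-fitting of nuisances, CATE forests and DR scores.

Each rotation (round) assigns the three folds distinct roles: the *nuisance*
fold trains the propensity and outcome super learners; the *cate* fold trains
the honest causal forest on nuisance-residualised data; the *score* fold
receives out-of-sample CATE predictions tau_hat(X_i) and doubly robust scores
Gamma_i.  Three rounds rotate the roles so every fold is scored exactly once,
and the assembled panel is fully out-of-sample: no row's tau_hat or Gamma
depends on any model trained on its own fold.

Three outcome models are supported: the two-part model (Y with
m_hat = m1_hat * m2_hat), the participation component (1{Y>0}) and the
consumption component (Y restricted to the Y>0 rows, with the propensity
re-estimated on that subpopulation by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .data import FoldAssignment, ObservationTable, assign_folds
from .effects import aiptw_ate, dr_score
from .forest import CausalForest, ForestParams
from .superlearner import (BaseLearnerSpec, default_library, fit_super_learner,
                           fit_two_part, predict_two_part)

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_TAGS",
    "RoundPlan",
    "CrossFitConfig",
    "RoundResult",
    "DrScorePanel",
    "plan_rounds",
    "run_round",
    "assemble",
    "cross_fit",
]

MODEL_TAGS = ("two_part", "participation", "consumption")


@dataclass(frozen=True)
class RoundPlan:
    nuisance_fold: int
    cate_fold: int
    score_fold: int
    model_tag: str

    def __post_init__(self):
        if sorted((self.nuisance_fold, self.cate_fold, self.score_fold)) != [1, 2, 3]:
            raise ValueError("round folds must be a permutation of {1,2,3}")
        if self.model_tag not in MODEL_TAGS:
            raise ValueError(f"unknown model tag {self.model_tag!r}")


def plan_rounds(models: tuple[str, ...] = MODEL_TAGS) -> list[RoundPlan]:
    """Three rotations per outcome model; each fold scored exactly once."""
    rotations = [(1, 2, 3), (2, 3, 1), (3, 1, 2)]
    return [RoundPlan(nu, ca, sc, m) for m in models for nu, ca, sc in rotations]


@dataclass
class CrossFitConfig:
    """Learner library, forest parameters and options for a cross-fit run."""

    binary_specs: list[BaseLearnerSpec] = field(
        default_factory=lambda: default_library("binary"))
    count_specs: list[BaseLearnerSpec] = field(
        default_factory=lambda: default_library("count"))
    forest_params: ForestParams = field(
        default_factory=lambda: ForestParams(num_trees=200))
    models: tuple[str, ...] = MODEL_TAGS
    sl_folds: int = 5
    consumption_propensity: str = "subset"  # or "full"
    evaluate_ensemble: bool = False  # skip the second CV pass inside rounds


@dataclass
class RoundResult:
    plan: RoundPlan
    rows: np.ndarray  # global row indices actually scored
    tau_hat: np.ndarray
    gamma: np.ndarray


class _Nuisances:
    """Super learners fitted on one nuisance fold (shared across model tags)."""

    def __init__(self, table: ObservationTable, outcome: str, nuis_rows: np.ndarray,
                 config: CrossFitConfig, seed: int):
        sub = table.subset(nuis_rows)
        d = sub.treatment
        if d.min() == d.max():
            raise ValueError("nuisance fold lacks treated or control rows; "
                             "use a larger sample")
        X = sub.covariate_matrix()
        self.e_model = fit_super_learner(
            config.binary_specs, X, d, sub.weights, n_folds=config.sl_folds,
            seed=derive_seed(seed, "e"), evaluate_ensemble=config.evaluate_ensemble)
        self.two_part = fit_two_part(
            config.binary_specs, config.count_specs, sub, outcome,
            n_folds=config.sl_folds, seed=derive_seed(seed, "m"),
            evaluate_ensemble=config.evaluate_ensemble)
        self.e_model_pos = None
        if "consumption" in config.models and config.consumption_propensity == "subset":
            pos = np.flatnonzero(sub.outcome(outcome) > 0)
            subpos = sub.subset(pos)
            if subpos.treatment.min() == subpos.treatment.max():
                raise ValueError("nuisance fold has no treated or no control "
                                 "rows among Y>0; use a larger sample")
            self.e_model_pos = fit_super_learner(
                config.binary_specs, subpos.covariate_matrix(), subpos.treatment,
                subpos.weights, n_folds=min(config.sl_folds, max(2, subpos.n // 10)),
                seed=derive_seed(seed, "e-pos"),
                evaluate_ensemble=config.evaluate_ensemble)

    def propensity(self, X, model_tag: str) -> np.ndarray:
        model = self.e_model_pos if (model_tag == "consumption"
                                     and self.e_model_pos is not None) else self.e_model
        return model.predict(X)

    def outcome_mean(self, X, model_tag: str) -> np.ndarray:
        m1, m2, m = predict_two_part(self.two_part, X)
        return {"two_part": m, "participation": m1, "consumption": m2}[model_tag]


def _run_model(table: ObservationTable, outcome: str, nuis: _Nuisances,
               plan: RoundPlan, cate_rows: np.ndarray, score_rows: np.ndarray,
               config: CrossFitConfig, seed: int) -> RoundResult:
    y_all = table.outcome(outcome).astype(float)
    if plan.model_tag == "participation":
        y_all = (y_all > 0).astype(float)
    elif plan.model_tag == "consumption":
        pos = y_all > 0
        cate_rows = cate_rows[pos[cate_rows]]
        score_rows = score_rows[pos[score_rows]]
        if len(cate_rows) == 0 or len(score_rows) == 0:
            raise ValueError("no positive-outcome rows in a fold; use a larger sample")
    X = table.covariate_matrix()
    d = table.treatment
    w = table.weights
    if d[cate_rows].min() == d[cate_rows].max():
        raise ValueError("CATE fold lacks treated or control rows; use a larger sample")

    e_cate = nuis.propensity(X[cate_rows], plan.model_tag)
    m_cate = nuis.outcome_mean(X[cate_rows], plan.model_tag)
    fp = config.forest_params
    forest = CausalForest(ForestParams(
        **{**{k: getattr(fp, k) for k in fp.__dataclass_fields__},
           "seed": derive_seed(seed, "forest", plan.model_tag, plan.score_fold)}))
    forest.fit(X[cate_rows], d[cate_rows], y_all[cate_rows], e_cate, m_cate,
               w[cate_rows])

    e_score = nuis.propensity(X[score_rows], plan.model_tag)
    m_score = nuis.outcome_mean(X[score_rows], plan.model_tag)
    tau = forest.predict(X[score_rows])
    gamma = dr_score(tau, e_score, m_score, d[score_rows], y_all[score_rows])
    return RoundResult(plan, score_rows, tau, gamma)


def run_round(table: ObservationTable, outcome: str, folds: FoldAssignment,
              plan: RoundPlan, config: CrossFitConfig, seed: int = 0) -> RoundResult:
    """One rotation for one outcome model (nuisances fitted fresh)."""
    nuis_rows = folds.rows(plan.nuisance_fold)
    nuis = _Nuisances(table, outcome, nuis_rows, config,
                      derive_seed(seed, "nuisance", plan.nuisance_fold))
    return _run_model(table, outcome, nuis, plan, folds.rows(plan.cate_fold),
                      folds.rows(plan.score_fold), config,
                      derive_seed(seed, "round", plan.nuisance_fold))


@dataclass
class DrScorePanel:
    """Assembled out-of-sample tau_hat / Gamma panel for each outcome model.

    For the consumption model the vectors are defined only on the Y>0 mask;
    other rows are NaN with mask False.
    """

    n: int
    tau_hat: dict[str, np.ndarray]
    gamma: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]
    provenance: pd.DataFrame  # row, model, round, nuisance_fold, cate_fold, score_fold
    fold_label: np.ndarray

    def ate(self, model_tag: str, weights=None):
        m = self.mask[model_tag]
        w = None if weights is None else np.asarray(weights, float)[m]
        return aiptw_ate(self.gamma[model_tag][m], w, model_tag)

    def audit(self) -> int:
        """Count of out-of-sample violations (a row whose own fold served as
        its nuisance or CATE fold). Zero for a valid panel."""
        own = self.fold_label[self.provenance["row"].to_numpy()]
        bad = ((own == self.provenance["nuisance_fold"].to_numpy())
               | (own == self.provenance["cate_fold"].to_numpy()))
        return int(bad.sum())

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for tag in self.tau_hat:
            rows = np.flatnonzero(self.mask[tag])
            frames.append(pd.DataFrame({
                "row": rows, "model": tag,
                "tau_hat": self.tau_hat[tag][rows],
                "gamma": self.gamma[tag][rows],
            }))
        df = pd.concat(frames, ignore_index=True)
        return df.merge(self.provenance, on=["row", "model"], how="left")


def assemble(partials: list[RoundResult], n: int,
             fold_assignment: FoldAssignment) -> DrScorePanel:
    """Stitch round results into a complete panel, verifying coverage and the
    out-of-sample guarantee."""
    tags = sorted({r.plan.model_tag for r in partials},
                  key=lambda t: MODEL_TAGS.index(t))
    tau = {t: np.full(n, np.nan) for t in tags}
    gam = {t: np.full(n, np.nan) for t in tags}
    mask = {t: np.zeros(n, bool) for t in tags}
    prov_rows = []
    for res in partials:
        t = res.plan.model_tag
        dup = mask[t][res.rows]
        if dup.any():
            raise ValueError(f"rows scored twice for model {t!r}: "
                             f"{res.rows[dup][:10].tolist()} ...")
        mask[t][res.rows] = True
        tau[t][res.rows] = res.tau_hat
        gam[t][res.rows] = res.gamma
        prov_rows.append(pd.DataFrame({
            "row": res.rows, "model": t,
            "nuisance_fold": res.plan.nuisance_fold,
            "cate_fold": res.plan.cate_fold,
            "score_fold": res.plan.score_fold,
        }))
    labels = fold_assignment.fold_label
    all_folds = set(np.unique(labels).tolist())
    for t in tags:
        scored_folds = {r.plan.score_fold for r in partials if r.plan.model_tag == t}
        if scored_folds != all_folds:
            raise ValueError(f"coverage gap for model {t!r}: folds "
                             f"{sorted(all_folds - scored_folds)} never scored")
        if t != "consumption" and not mask[t].all():
            # consumption coverage applies to the Y>0 mask only (in rows)
            gaps = np.flatnonzero(~mask[t])
            raise ValueError(f"coverage gap for model {t!r}: rows {gaps[:10].tolist()} ...")
    panel = DrScorePanel(n, tau, gam, mask, pd.concat(prov_rows, ignore_index=True),
                         labels)
    if panel.audit() != 0:
        raise ValueError("out-of-sample guarantee violated in assembled panel")
    return panel


def cross_fit(table: ObservationTable, outcome: str,
              config: CrossFitConfig | None = None, seed: int = 0,
              fold_assignment: FoldAssignment | None = None) -> DrScorePanel:
    """Full 3-fold cross-fit for all configured outcome models.

    Nuisance super learners are shared across the outcome models within each
    rotation (the propensity and the two-part components serve all three).
    """
    config = config or CrossFitConfig()
    folds = fold_assignment or assign_folds(table.n, 3, derive_seed(seed, "folds"))
    partials: list[RoundResult] = []
    for nu, ca, sc in [(1, 2, 3), (2, 3, 1), (3, 1, 2)]:
        nuis = _Nuisances(table, outcome, folds.rows(nu), config,
                          derive_seed(seed, "nuisance", nu))
        for tag in config.models:
            plan = RoundPlan(nu, ca, sc, tag)
            partials.append(_run_model(table, outcome, nuis, plan, folds.rows(ca),
                                       folds.rows(sc), config,
                                       derive_seed(seed, "round", nu)))
    return assemble(partials, table.n, folds)
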