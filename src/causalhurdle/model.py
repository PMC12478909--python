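"""Model/Results interface tying the full analysis together.

``CausalHurdleModel`` is constructed from an observation table (or a raw
DataFrame) and configuration; ``fit()`` executes the complete workflow —
balance diagnostics, 3-fold cross-fitted nuisance super learners, honest
causal forests, doubly robust scoring, and the heterogeneity suite — and
returns a ``CausalHurdleResults`` carrying the estimates, their uncertainties
and a ``summary()`` table.

Example
-------
>>> from causalhurdle import CausalHurdleModel, simulate
>>> table, truth = simulate.generate_dataset(simulate.paper_like_scenario(n=3000))
>>> res = CausalHurdleModel(table, outcome="visits").fit(seed=1)
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .crossfit import MODEL_TAGS, CrossFitConfig, DrScorePanel, cross_fit
from .data import CONTINUOUS, ObservationTable, TableSchema, assign_folds
from .effects import AteEstimate, balance_table, overlap_report
from .heterogeneity import (BlpResult, ClassificationResult, QuintileAssignment,
                            assign_quintiles, blp, classification_analysis,
                            quintile_difference_tests, sorted_gates, subgroup_gates)
from .superlearner import fit_super_learner

__all__ = ["CausalHurdleModel", "CausalHurdleResults"]


@dataclass
class HeterogeneityOptions:
    n_boot: int = 1000
    modifiers: list[str] | None = None  # None: data-driven top-5
    dichotomisation: dict = field(default_factory=dict)
    blp_regressors: list[str] | None = None  # None: the modifiers
    primary_model: str = "two_part"
    top_k: int = 20
    top_modifiers: int = 5


class CausalHurdleModel:
    """Heterogeneous-treatment-effect analysis of a zero-inflated count
    outcome under unconfoundedness.

    Parameters
    ----------
    table : ObservationTable
    outcome : outcome name; defaults to the table's only outcome.
    config : CrossFitConfig for the nuisance library and forest parameters.
    het : HeterogeneityOptions for the downstream summaries.
    """

    def __init__(self, table: ObservationTable, outcome: str | None = None,
                 config: CrossFitConfig | None = None,
                 het: HeterogeneityOptions | None = None):
        self.table = table
        if outcome is None:
            if len(table.outcomes) != 1:
                raise ValueError("outcome must be named when the table has several")
            outcome = next(iter(table.outcomes))
        table.outcome(outcome)  # validates
        self.outcome = outcome
        self.config = config or CrossFitConfig()
        self.het = het or HeterogeneityOptions()
        if self.het.primary_model not in self.config.models:
            raise ValueError("primary model not among configured models")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, treatment: str, outcome: str,
                       weight: str | None = None,
                       covariates: list[str] | None = None,
                       **kwargs) -> "CausalHurdleModel":
        schema = TableSchema(treatment, [outcome], weight, covariates)
        if covariates is None:
            covariates = [c for c in df.columns
                          if c not in {treatment, outcome, weight}]
        table = ObservationTable(
            df[covariates], df[treatment].to_numpy(),
            {outcome: df[outcome].to_numpy()},
            df[weight].to_numpy() if weight else None)
        return cls(table, outcome, **kwargs)

    def fit(self, seed: int = 0) -> "CausalHurdleResults":
        table, cfg, het = self.table, self.config, self.het

        # descriptive diagnostics: full-sample propensity ensemble (in-sample,
        # used only for balance/overlap reporting, never for scoring)
        e_model = fit_super_learner(cfg.binary_specs, table.covariate_matrix(),
                                    table.treatment, table.weights,
                                    n_folds=cfg.sl_folds,
                                    seed=derive_seed(seed, "balance-e"),
                                    evaluate_ensemble=True)
        e_desc = np.clip(e_model.predict(table.covariate_matrix()), 1e-6, 1 - 1e-6)
        balance = balance_table(table, e_desc)
        overlap = overlap_report(e_desc, table.treatment)

        folds = assign_folds(table.n, 3, derive_seed(seed, "folds"))
        panel = cross_fit(table, self.outcome, cfg, seed=seed, fold_assignment=folds)

        ates = {tag: panel.ate(tag, table.weights) for tag in cfg.models}

        quintiles, gates, contrasts = {}, {}, {}
        for tag in cfg.models:
            m = panel.mask[tag]
            qa = assign_quintiles(panel.tau_hat[tag][m], table.weights[m])
            quintiles[tag] = (qa, m)
            gates[tag] = sorted_gates(panel.gamma[tag][m], qa, table.weights[m])
            contrasts[tag] = quintile_difference_tests(
                panel.gamma[tag][m], qa, table.weights[m],
                n_boot=het.n_boot, seed=derive_seed(seed, "rw", tag))

        primary = het.primary_model
        qa_p, mask_p = quintiles[primary]
        sub_table = table.subset(np.flatnonzero(mask_p))
        classification = classification_analysis(sub_table, qa_p,
                                                 top_k=het.top_k,
                                                 top_modifiers=het.top_modifiers)
        modifiers = het.modifiers or classification.top_modifiers
        subgroups = subgroup_gates(panel.gamma[primary][mask_p], sub_table,
                                   modifiers, rules=het.dichotomisation)

        regressors = het.blp_regressors or modifiers
        Xr = _dichotomised_regressors(sub_table, regressors, het.dichotomisation)
        blp_res = blp(panel.gamma[primary][mask_p], Xr, sub_table.weights)

        return CausalHurdleResults(
            model=self, seed=seed, panel=panel, balance=balance, overlap=overlap,
            ates=ates, quintiles=quintiles, gates=gates, contrasts=contrasts,
            classification=classification, subgroups=subgroups, blp_result=blp_res,
            modifiers=modifiers, propensity_cv_loss=e_model.cv_loss_table)


def _dichotomised_regressors(table: ObservationTable, names: list[str],
                             rules: dict) -> pd.DataFrame:
    """BLP design: binary covariates as-is, continuous ones median-split
    (or at configured cutpoints, taking the above-cut indicator)."""
    from ._utils import weighted_quantile

    kinds = {m.name: m.kind for m in table.covariate_meta}
    out = {}
    for name in names:
        x = table.covariates[name].to_numpy()
        if kinds.get(name) == CONTINUOUS:
            rule = rules.get(name)
            cut = (weighted_quantile(x, table.weights, 0.5)[0]
                   if rule is None else rule[1][0])
            out[f"{name}_gt_{cut:.4g}"] = (x > cut).astype(float)
        else:
            out[name] = x
    return pd.DataFrame(out)


@dataclass
class CausalHurdleResults:
    """Fitted results: DR-score panel, ATEs, GATEs, tests, classification,
    subgroup GATEs and BLP coefficients."""

    model: CausalHurdleModel
    seed: int
    panel: DrScorePanel
    balance: pd.DataFrame
    overlap: dict
    ates: dict[str, AteEstimate]
    quintiles: dict[str, tuple[QuintileAssignment, np.ndarray]]
    gates: dict[str, pd.DataFrame]
    contrasts: dict[str, pd.DataFrame]
    classification: ClassificationResult
    subgroups: pd.DataFrame
    blp_result: BlpResult
    modifiers: list[str]
    propensity_cv_loss: pd.DataFrame | None = None

    def ate(self, model_tag: str | None = None) -> AteEstimate:
        return self.ates[model_tag or self.model.het.primary_model]

    def summary(self) -> str:
        lines = []
        add = lines.append
        add("Causal hurdle analysis")
        add("=" * 70)
        add(f"outcome: {self.model.outcome}   n = {self.model.table.n}   "
            f"effective n = {self.model.table.effective_n():.1f}")
        add(f"balanced covariates (|SMD| < 0.1 after IPTW): "
            f"{int((self.balance['smd_iptw'].abs() < 0.1).sum())}"
            f"/{len(self.balance)}")
        add("")
        add("Average treatment effects (AIPTW on cross-fitted DR scores)")
        add(f"{'model':<15}{'ATE':>10}{'SE':>10}{'95% CI':>24}")
        for tag, a in self.ates.items():
            add(f"{tag:<15}{a.estimate:>10.4f}{a.se:>10.4f}"
                f"{'[' + format(a.ci95[0], '.4f') + ', ' + format(a.ci95[1], '.4f') + ']':>24}")
        primary = self.model.het.primary_model
        add("")
        add(f"Sorted GATEs by CATE quintile ({primary} model)")
        for _, r in self.gates[primary].iterrows():
            add(f"  {r['group']}: {r['estimate']:.4f} (se {r['se']:.4f})")
        add("")
        add("Quintile contrasts vs Q1 (Romano-Wolf adjusted)")
        for _, r in self.contrasts[primary].iterrows():
            add(f"  {r['contrast']}: {r['estimate']:.4f} (se {r['se']:.4f}), "
                f"p_unadj {r['p_unadjusted']:.3f}, p_adj {r['p_adjusted']:.3f}")
        add("")
        add(f"Data-driven effect modifiers (top Q1-vs-Q5 SMD): "
            f"{', '.join(self.modifiers)}")
        add("")
        add("Best linear projection of DR scores (HC1 SEs)")
        for _, r in self.blp_result.coefficients.iterrows():
            add(f"  {r['term']}: {r['estimate']:.4f} (se {r['se']:.4f}, "
                f"p {r['p']:.3f})")
        return "\n".join(lines)
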