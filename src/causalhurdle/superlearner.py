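"""Cross-validated stacking ("super learner") for the nuisance models.

The treatment model e(x) and the participation component m1(x) are binary
prediction tasks; the consumption component m2(x) is a count task fitted on
the positive-outcome rows only.  Each task fits a library of heterogeneous
base learners, obtains out-of-fold predictions by K-fold cross-validation,
and combines them with an *unconstrained* ordinary-least-squares metalearner
(intercept included, weights may be negative and need not sum to one).  The
two-part outcome prediction composes the two components:

    m(x) = m1(x) * m2(x)  =  P(Y>0 | x) * E[Y | Y>0, x].

All fits use frequency weights; with integer weights every fit equals the
unweighted fit on the row-replicated data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import derive_seed, weighted_mean
from .data import ObservationTable, two_part_view

logger = logging.getLogger(__name__)

__all__ = [
    "BaseLearnerSpec",
    "EnsembleModel",
    "TwoPartEnsemble",
    "kfold_split",
    "cv_predictions",
    "fit_metalearner",
    "cv_loss",
    "fit_super_learner",
    "fit_two_part",
    "predict_two_part",
    "default_library",
    "ALLOWED_TASKS",
]

BINARY, COUNT = "binary", "count"
_EPS = 1e-12

# learner-name -> tasks it may serve (library check-marks)
ALLOWED_TASKS: dict[str, set[str]] = {
    "glm-g": {COUNT}, "glm-b": {BINARY}, "glm-p": {COUNT}, "glm-nb": {COUNT},
    "lasso-g": {COUNT}, "lasso-b": {BINARY}, "lasso-p": {COUNT}, "lasso-nb": {COUNT},
    "rf": {BINARY, COUNT}, "gbm": {BINARY, COUNT}, "nn": {BINARY, COUNT},
    "constant": {BINARY, COUNT},
}


@dataclass(frozen=True)
class BaseLearnerSpec:
    name: str
    task: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in ALLOWED_TASKS:
            raise ValueError(f"unknown learner {self.name!r}")
        if self.task not in ALLOWED_TASKS[self.name]:
            raise ValueError(f"learner {self.name!r} not available for task {self.task!r}")


def default_library(task: str, profile: str = "desk") -> list[BaseLearnerSpec]:
    """Shipped learner libraries.

    "desk" keeps the parametric, lasso and tree-ensemble members; "full" adds
    the negative-binomial and neural-network members (both fragile at small
    n); "lean" is a minimal two-member library for Monte-Carlo replicate runs.
    """
    if task == BINARY:
        names = {
            "lean": ["glm-b", "rf"],
            "desk": ["glm-b", "lasso-b", "rf", "gbm"],
            "full": ["glm-b", "lasso-b", "rf", "gbm", "nn"],
        }[profile]
    else:
        names = {
            "lean": ["glm-g", "rf"],
            "desk": ["glm-g", "glm-p", "lasso-g", "rf", "gbm"],
            "full": ["glm-g", "glm-p", "glm-nb", "lasso-g", "lasso-p", "lasso-nb",
                     "rf", "gbm", "nn"],
        }[profile]
    hp = {"rf": {"n_estimators": 200 if profile != "lean" else 50}}
    return [BaseLearnerSpec(n, task, hp.get(n, {})) for n in names]


# ----------------------------------------------------------------------
# base-learner construction
# ----------------------------------------------------------------------

class _ConstantLearner:
    """Weighted target mean; the degenerate baseline member."""

    def fit(self, X, y, sample_weight=None):
        w = np.ones(len(y)) if sample_weight is None else sample_weight
        self.mean_ = weighted_mean(y, w)
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


class _Standardised:
    """Weighted-standardise features before an inner scale-sensitive learner."""

    def __init__(self, inner):
        self.inner = inner

    def _transform(self, X):
        return (np.asarray(X, float) - self.mu_) / self.sd_

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, float)
        w = np.ones(len(X)) if sample_weight is None else np.asarray(sample_weight, float)
        sw = w.sum()
        self.mu_ = (w[:, None] * X).sum(0) / sw
        var = (w[:, None] * (X - self.mu_) ** 2).sum(0) / sw
        self.sd_ = np.sqrt(np.maximum(var, 1e-12))
        self.inner.fit(self._transform(X), y, sample_weight=sample_weight)
        return self

    def predict(self, X):
        return self.inner.predict(self._transform(X))


class _ProbWrapper:
    """Expose classifier probabilities as predictions; tolerate one-class fits."""

    def __init__(self, clf):
        self.clf = clf

    def fit(self, X, y, sample_weight=None):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            self.constant_ = float(y[0])
            return self
        self.constant_ = None
        self.clf.fit(X, y, sample_weight=sample_weight)
        return self

    def predict(self, X):
        if self.constant_ is not None:
            return np.full(len(X), self.constant_)
        proba = self.clf.predict_proba(X)
        return proba[:, list(self.clf.classes_).index(1)]


class _StatsmodelsNB:
    """Negative-binomial GLM (fixed dispersion alpha), optionally L1-penalised."""

    def __init__(self, alpha=1.0, l1=0.0):
        self.alpha, self.l1 = alpha, l1

    def fit(self, X, y, sample_weight=None):
        import statsmodels.api as sm
        Xc = sm.add_constant(np.asarray(X, float), has_constant="add")
        model = sm.GLM(np.asarray(y, float), Xc,
                       family=sm.families.NegativeBinomial(alpha=self.alpha),
                       freq_weights=sample_weight)
        if self.l1 > 0:
            self.res_ = model.fit_regularized(alpha=self.l1, L1_wt=1.0)
        else:
            self.res_ = model.fit()
        return self

    def predict(self, X):
        import statsmodels.api as sm
        Xc = sm.add_constant(np.asarray(X, float), has_constant="add")
        return np.asarray(self.res_.predict(Xc))


class _WeightlessMLP:
    """MLP member; scikit-learn's MLP ignores sample weights, so weighted fits
    fall back to unweighted training (logged once)."""

    def __init__(self, inner):
        self.inner = inner
        self._warned = False

    def fit(self, X, y, sample_weight=None):
        if sample_weight is not None and not np.allclose(sample_weight, sample_weight[0]):
            if not self._warned:
                logger.warning("nn learner ignores non-uniform sample weights")
                self._warned = True
        self.inner.fit(X, y)
        return self

    def predict(self, X):
        return self.inner.predict(X)


def build_learner(spec: BaseLearnerSpec, seed: int = 0):
    """Instantiate an unfitted learner exposing fit(X, y, sample_weight) and
    predict(X) (probabilities for binary tasks)."""
    from sklearn.ensemble import (HistGradientBoostingClassifier,
                                  HistGradientBoostingRegressor,
                                  RandomForestClassifier, RandomForestRegressor)
    from sklearn.linear_model import (LassoCV, LinearRegression,
                                      LogisticRegression, PoissonRegressor)

    hp = dict(spec.hyperparams)
    name, task = spec.name, spec.task
    if name == "constant":
        return _ConstantLearner()
    if name == "glm-g":
        return LinearRegression()
    if name == "glm-b":
        return _ProbWrapper(LogisticRegression(C=np.inf, max_iter=hp.get("max_iter", 1000)))
    if name == "glm-p":
        return PoissonRegressor(alpha=1e-12, max_iter=hp.get("max_iter", 300))
    if name == "glm-nb":
        return _StatsmodelsNB(alpha=hp.get("alpha", 1.0))
    if name == "lasso-g":
        return _Standardised(LassoCV(cv=hp.get("cv", 3), n_alphas=hp.get("n_alphas", 20),
                                     random_state=seed))
    if name == "lasso-b":
        return _ProbWrapper(_Standardised(LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=hp.get("C", 1.0), random_state=seed)))
    if name == "lasso-p":
        return _Standardised(PoissonRegressor(alpha=hp.get("alpha", 1.0),
                                              max_iter=hp.get("max_iter", 300)))
    if name == "lasso-nb":
        return _StatsmodelsNB(alpha=hp.get("alpha", 1.0), l1=hp.get("l1", 1.0))
    if name == "rf":
        kw = dict(n_estimators=hp.get("n_estimators", 200),
                  min_samples_leaf=hp.get("min_samples_leaf", 5),
                  max_depth=hp.get("max_depth"),
                  bootstrap=hp.get("bootstrap", True), random_state=seed)
        if task == BINARY:
            return _ProbWrapper(RandomForestClassifier(**kw))
        return RandomForestRegressor(**kw)
    if name == "gbm":
        kw = dict(max_iter=hp.get("max_iter", 150),
                  max_depth=hp.get("max_depth", 3),
                  learning_rate=hp.get("learning_rate", 0.1),
                  early_stopping=False, random_state=seed)
        if task == BINARY:
            return _ProbWrapper(HistGradientBoostingClassifier(**kw))
        return HistGradientBoostingRegressor(**kw)
    if name == "nn":
        from sklearn.neural_network import MLPClassifier, MLPRegressor
        kw = dict(hidden_layer_sizes=hp.get("hidden_layer_sizes", (32,)),
                  max_iter=hp.get("max_iter", 300), random_state=seed)
        if task == BINARY:
            return _ProbWrapper(_WrapProbaless(MLPClassifier(**kw)))
        return _WeightlessMLP(_Standardised(MLPRegressor(**kw)))
    raise ValueError(f"unknown learner {name!r}")


class _WrapProbaless:
    """Adapt MLPClassifier (weightless) to the sample_weight-taking interface."""

    def __init__(self, clf):
        self.clf = clf

    def fit(self, X, y, sample_weight=None):
        std = _Standardised(_Noop())
        std.fit(X, y, sample_weight=sample_weight)
        self._std = std
        self.clf.fit(std._transform(X), y)
        self.classes_ = self.clf.classes_
        return self

    def predict_proba(self, X):
        return self.clf.predict_proba(self._std._transform(X))


class _Noop:
    def fit(self, X, y, sample_weight=None):
        return self

    def predict(self, X):
        return np.zeros(len(X))


# ----------------------------------------------------------------------
# stacking machinery
# ----------------------------------------------------------------------

def kfold_split(n: int, n_folds: int, seed: int, weights=None) -> np.ndarray:
    """Random fold labels 1..K with sizes differing by at most one."""
    if not (2 <= n_folds <= n):
        raise ValueError(f"need 2 <= K <= n; got K={n_folds}, n={n}")
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=np.int64)
    labels[rng.permutation(n)] = 1 + np.arange(n) % n_folds
    return labels


def cv_predictions(specs, features, target, weights, folds, seed: int = 0,
                   ) -> tuple[np.ndarray, list[BaseLearnerSpec]]:
    """Out-of-fold prediction matrix, one column per surviving learner.

    A learner that raises in any fold is dropped with a warning rather than
    aborting the whole library.
    """
    X = np.asarray(features, float)
    y = np.asarray(target, float)
    w = np.asarray(weights, float)
    fold_ids = np.unique(folds)
    cols, survivors = [], []
    for j, spec in enumerate(specs):
        pred = np.full(len(y), np.nan)
        try:
            for k in fold_ids:
                tr, va = folds != k, folds == k
                learner = build_learner(spec, seed=derive_seed(seed, spec.name, int(k)))
                learner.fit(X[tr], y[tr], sample_weight=w[tr])
                pred[va] = learner.predict(X[va])
            if not np.all(np.isfinite(pred)):
                raise ValueError("non-finite out-of-fold predictions")
        except Exception as exc:  # drop-and-warn failure policy
            logger.warning("dropping learner %s (%s task): %s", spec.name, spec.task, exc)
            continue
        if spec.task == BINARY:
            pred = np.clip(pred, 0.0, 1.0)
        cols.append(pred)
        survivors.append(spec)
    if not cols:
        raise RuntimeError("all base learners failed")
    return np.column_stack(cols), survivors


def fit_metalearner(cv_preds, target, weights) -> tuple[float, np.ndarray]:
    """Weighted OLS of the target on out-of-fold predictions, with intercept.

    Coefficients are unconstrained (no simplex restriction).  Collinear
    columns are resolved by the minimum-norm least-squares solution.
    """
    Z = np.asarray(cv_preds, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    y = np.asarray(target, float)
    w = np.asarray(weights, float)
    A = np.column_stack([np.ones(len(y)), Z]) * np.sqrt(w)[:, None]
    b = y * np.sqrt(w)
    coef, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < A.shape[1]:
        logger.warning("collinear metalearner design (rank %d < %d); "
                       "minimum-norm solution used", rank, A.shape[1])
    return float(coef[0]), coef[1:]


def cv_loss(predictions, target, weights, task: str) -> float:
    """Weighted log loss (binary) or mean squared error (count)."""
    p = np.asarray(predictions, float)
    y = np.asarray(target, float)
    w = np.asarray(weights, float)
    if task == BINARY:
        p = np.clip(p, _EPS, 1.0 - _EPS)
        return float(-np.dot(w, y * np.log(p) + (1 - y) * np.log(1 - p)) / w.sum())
    return float(np.dot(w, (y - p) ** 2) / w.sum())


class EnsembleModel:
    """Fitted stacking ensemble for one task."""

    def __init__(self, specs, base_models, meta_intercept, meta_weights, task,
                 cv_loss_table: pd.DataFrame):
        self.specs = specs
        self.base_models = base_models
        self.meta_intercept = meta_intercept
        self.meta_weights = np.asarray(meta_weights, float)
        self.task = task
        self.cv_loss_table = cv_loss_table

    def base_predictions(self, features) -> np.ndarray:
        X = np.asarray(features, float)
        cols = [m.predict(X) for m in self.base_models]
        Z = np.column_stack(cols)
        if self.task == BINARY:
            Z = np.clip(Z, 0.0, 1.0)
        return Z

    def predict(self, features) -> np.ndarray:
        Z = self.base_predictions(features)
        out = self.meta_intercept + Z @ self.meta_weights
        if self.task == BINARY:
            out = np.clip(out, 0.0, 1.0)
        return out


def fit_super_learner(specs, features, target, weights=None, n_folds: int = 5,
                      seed: int = 0, evaluate_ensemble: bool = True) -> EnsembleModel:
    """Fit the full stack: out-of-fold predictions, OLS metalearner, base
    learners refit on all rows, and a cross-validated loss table.

    The ensemble row of the loss table comes from a second K-fold pass that
    refits the metalearner on the training folds' out-of-fold base
    predictions and scores the held-out fold (base predictions reused).
    """
    X = np.asarray(features, float)
    y = np.asarray(target, float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, float)
    folds = kfold_split(len(y), n_folds, derive_seed(seed, "sl-folds"))
    Z, survivors = cv_predictions(specs, X, y, w, folds, seed=seed)
    intercept, coefs = fit_metalearner(Z, y, w)

    sd_y = max(float(np.sqrt(np.dot(w, (y - weighted_mean(y, w)) ** 2) / w.sum())), _EPS)
    rows = []
    for j, spec in enumerate(survivors):
        sd_z = float(np.sqrt(np.dot(w, (Z[:, j] - weighted_mean(Z[:, j], w)) ** 2) / w.sum()))
        rows.append({
            "learner": spec.name,
            "loss": cv_loss(Z[:, j], y, w, spec.task),
            "coef": float(coefs[j]),
            "std_coef": float(coefs[j]) * sd_z / sd_y,
        })
    if evaluate_ensemble:
        ens_pred = np.full(len(y), np.nan)
        for k in np.unique(folds):
            tr, va = folds != k, folds == k
            b0, bw = fit_metalearner(Z[tr], y[tr], w[tr])
            ens_pred[va] = b0 + Z[va] @ bw
        if survivors[0].task == BINARY:
            ens_pred = np.clip(ens_pred, 0.0, 1.0)
        ens_loss = cv_loss(ens_pred, y, w, survivors[0].task)
    else:
        ens_loss = np.nan
    rows.insert(0, {"learner": "ensemble", "loss": ens_loss,
                    "coef": np.nan, "std_coef": np.nan})

    fitted = []
    for spec in survivors:
        learner = build_learner(spec, seed=derive_seed(seed, spec.name, "refit"))
        learner.fit(X, y, sample_weight=w)
        fitted.append(learner)
    return EnsembleModel(survivors, fitted, intercept, coefs, survivors[0].task,
                         pd.DataFrame(rows))


@dataclass
class TwoPartEnsemble:
    """Participation (binary, all rows) and consumption (count, Y>0 rows)
    ensembles for one outcome."""

    participation: EnsembleModel
    consumption: EnsembleModel
    outcome: str


def fit_two_part(specs_binary, specs_count, table: ObservationTable, outcome: str,
                 n_folds: int = 5, seed: int = 0,
                 evaluate_ensemble: bool = True) -> TwoPartEnsemble:
    view = two_part_view(table, outcome)
    if len(view.consumption_index) == 0:
        raise ValueError(f"outcome {outcome!r} has no positive rows; "
                         "cannot fit the consumption component")
    X = table.covariate_matrix()
    w = table.weights
    part = fit_super_learner(specs_binary, X, view.participation, w,
                             n_folds=n_folds, seed=derive_seed(seed, "participation"),
                             evaluate_ensemble=evaluate_ensemble)
    idx = view.consumption_index
    cons = fit_super_learner(specs_count, X[idx], view.consumption_values, w[idx],
                             n_folds=n_folds, seed=derive_seed(seed, "consumption"),
                             evaluate_ensemble=evaluate_ensemble)
    return TwoPartEnsemble(part, cons, outcome)


def predict_two_part(model: TwoPartEnsemble, features,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(m1_hat, m2_hat, m_hat) with m_hat = m1_hat * m2_hat exactly.

    m1_hat is clipped to [0,1]; negative count predictions are floored at 0.
    """
    m1 = np.clip(model.participation.predict(features), 0.0, 1.0)
    m2 = model.consumption.predict(features)
    if np.any(m2 < 0):
        logger.warning("flooring %d negative consumption predictions at 0",
                       int(np.sum(m2 < 0)))
        m2 = np.maximum(m2, 0.0)
    return m1, m2, m1 * m2
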