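"""Honest causal forest for conditional average treatment effects.

Each tree is grown on a subsample drawn without replacement, which is split
into a *structure* half and an *estimation* half (honesty): splits are chosen
using only the structure half, leaf membership is then populated with the
estimation half, so no observation influences both the partition and the
within-leaf effect estimate.

Splitting is gradient-based: within a parent node the influence-function
pseudo-outcomes

    rho_i = A_P^{-1} (Dc_i) * [ (Yc_i) - Dc_i * beta_P ]

are computed from the nuisance-centred treatment Dres_i = D_i - e_hat_i and
outcome Yres_i = Y_i - m_hat_i (Dc, Yc additionally centred within the node;
beta_P is the within-node weighted least-squares slope of Yres on Dres, and
A_P the weighted mean of Dc^2).  A split maximises the heterogeneity score

    Delta(L, R) = (sum_L w rho)^2 / W_L + (sum_R w rho)^2 / W_R
                  - imbalance_penalty * (1/W_L + 1/W_R)

subject to each child carrying at least an ``alpha`` share of the parent
weight and at least ``min_node_size`` treated AND control structure rows.

Prediction aggregates forest weights over trees: an observation i in the
same (estimation-half) leaf as the query point x receives weight
w_i / W_leaf in that tree, averaged over trees; the CATE is the weighted
residual-on-residual ratio

    tau_hat(x) = sum_i w_i(x) Dres_i Yres_i / sum_i w_i(x) Dres_i^2.

Sample weights enter every node statistic, split score, leaf weight and the
prediction ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from ._utils import derive_rng, derive_seed

__all__ = [
    "ForestParams",
    "CausalTree",
    "CausalForest",
    "node_pseudo_outcomes",
    "best_split",
    "grow_tree",
    "tune_params",
]

_TINY = 1e-12


@dataclass(frozen=True)
class ForestParams:
    """Tuning parameters of the forest (grf-style semantics).

    min_node_size is the minimum number of *both* treated and control
    structure rows required in each child of a split.
    """

    num_trees: int = 2000
    tune_trees: int = 200
    sample_fraction: float = 0.5
    mtry: int | None = None  # default: min(ceil(sqrt(p) + 20), p)
    min_node_size: int = 5
    honesty_fraction: float = 0.5
    honesty_prune_leaves: bool = True
    alpha: float = 0.05
    imbalance_penalty: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.num_trees < 1 or self.tune_trees < 1:
            raise ValueError("num_trees and tune_trees must be >= 1")
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if not 0.0 < self.honesty_fraction < 1.0:
            raise ValueError("honesty_fraction must be in (0, 1)")
        if not 0.0 <= self.alpha < 0.5:
            raise ValueError("alpha must be in [0, 0.5)")
        if self.imbalance_penalty < 0:
            raise ValueError("imbalance_penalty must be >= 0")


def node_pseudo_outcomes(d_res, y_res, weights=None) -> tuple[np.ndarray, float]:
    """Influence-function pseudo-outcomes and the node slope beta_P.

    beta_P is the weighted least-squares slope of the centred outcome
    residual on the centred treatment residual within the node; the weighted
    sum of the returned pseudo-outcomes is zero by construction.
    """
    d_res = np.asarray(d_res, float)
    y_res = np.asarray(y_res, float)
    w = np.ones(len(d_res)) if weights is None else np.asarray(weights, float)
    sw = w.sum()
    dc = d_res - np.dot(w, d_res) / sw
    yc = y_res - np.dot(w, y_res) / sw
    s_dd = np.dot(w, dc * dc)
    if s_dd <= _TINY:
        raise ValueError("node has no treatment-residual variance; not splittable")
    beta = np.dot(w, dc * yc) / s_dd
    a_p = s_dd / sw  # weight-normalised mean squared centred treatment residual
    rho = dc * (yc - dc * beta) / a_p
    return rho, float(beta)


def best_split(x_node: np.ndarray, rho: np.ndarray, w: np.ndarray, d: np.ndarray,
               feature_ids: np.ndarray, min_node_size: int, alpha: float,
               imbalance_penalty: float) -> tuple[int, float] | None:
    """Exhaustive search over candidate thresholds of the sampled features.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values of the structure rows.  Ties in the score are broken by the lowest
    feature index, then the lowest threshold.  Returns None when no
    admissible split has a positive score.
    """
    w_tot = w.sum()
    wr_tot = np.dot(w, rho)
    t_tot = int(d.sum())
    c_tot = len(d) - t_tot
    best: tuple[float, int, float] | None = None
    for col, f in sorted(zip(range(x_node.shape[1]), feature_ids), key=lambda t: t[1]):
        x = x_node[:, col]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        cut = np.flatnonzero(xs[:-1] < xs[1:])  # split after position i
        if len(cut) == 0:
            continue
        cw = np.cumsum(w[order])[cut]
        cwr = np.cumsum((w * rho)[order])[cut]
        ct = np.cumsum(d[order])[cut]
        w_l, w_r = cw, w_tot - cw
        t_l, t_r = ct, t_tot - ct
        c_l = (cut + 1) - ct
        c_r = c_tot - c_l
        ok = ((t_l >= min_node_size) & (c_l >= min_node_size)
              & (t_r >= min_node_size) & (c_r >= min_node_size)
              & (w_l >= alpha * w_tot) & (w_r >= alpha * w_tot))
        if not ok.any():
            continue
        s_l, s_r = cwr, wr_tot - cwr
        delta = s_l**2 / w_l + s_r**2 / w_r - imbalance_penalty * (1.0 / w_l + 1.0 / w_r)
        delta = np.where(ok, delta, -np.inf)
        j = int(np.argmax(delta))  # first max -> lowest threshold
        if delta[j] > _TINY and (best is None or delta[j] > best[0]):
            thr = 0.5 * (xs[cut[j]] + xs[cut[j] + 1])
            best = (float(delta[j]), int(f), float(thr))
    if best is None:
        return None
    return best[1], best[2]


@dataclass
class CausalTree:
    """One honest tree: structure arrays plus estimation-half leaf contents."""

    feature: np.ndarray  # per node; -1 for leaf
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    depth: np.ndarray
    split_sample: np.ndarray
    estimation_sample: np.ndarray
    # termination nodes (honest leaves after pruning): node id -> estimation rows
    term_rows: dict[int, np.ndarray] = field(default_factory=dict)
    # per termination node: (W, S1, S2) with S1 = sum w*Dres*Yres / W etc.
    term_stats: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    est_subtree: np.ndarray | None = None  # estimation rows in each node's subtree (counts)

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def route(self, X: np.ndarray) -> np.ndarray:
        """Termination node id for each row of X (-1 if the tree cannot score it)."""
        out = np.full(len(X), -1, dtype=np.int64)
        stack = [(0, np.arange(len(X)))]
        while stack:
            node, rows = stack.pop()
            if len(rows) == 0:
                continue
            if node in self.term_rows:
                out[rows] = node
                continue
            f = self.feature[node]
            if f < 0:
                continue  # unscorable branch (empty estimation leaf, no pruning)
            go_left = X[rows, f] <= self.threshold[node]
            stack.append((self.left[node], rows[go_left]))
            stack.append((self.right[node], rows[~go_left]))
        return out

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "split_sample": self.split_sample.tolist(),
            "estimation_sample": self.estimation_sample.tolist(),
            "term_rows": {int(k): v.tolist() for k, v in self.term_rows.items()},
        }


def grow_tree(X: np.ndarray, d_res: np.ndarray, y_res: np.ndarray, d: np.ndarray,
              w: np.ndarray, params: ForestParams, rng: np.random.Generator,
              split_records: list | None = None) -> CausalTree:
    """Grow one honest tree on a fresh subsample.

    The subsample (without replacement, size sample_fraction * N) is split
    into a structure part (honesty_fraction of it) used for recursive
    partitioning and an estimation part populating the leaves.  With
    honesty_prune_leaves, branches whose subtree holds no estimation rows are
    collapsed so every termination node is honestly populated.
    """
    n, p = X.shape
    size = max(int(round(params.sample_fraction * n)), 2)
    sub = rng.choice(n, size=size, replace=False)
    n_split = min(max(int(round(params.honesty_fraction * size)), 1), size - 1)
    split_half, est_half = sub[:n_split], sub[n_split:]
    mtry = params.mtry or min(int(np.ceil(np.sqrt(p) + 20)), p)
    mtry = min(mtry, p)

    feature, threshold, left, right, depth = [], [], [], [], []

    def new_node(dep):
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        depth.append(dep)
        return len(feature) - 1

    root = new_node(0)
    stack = [(root, split_half)]
    node_split_rows = {root: split_half}
    while stack:
        node, rows = stack.pop()
        node_split_rows[node] = rows
        dn = d[rows]
        mns = params.min_node_size
        if (len(rows) < 2 * mns * 2 or dn.sum() < 2 * mns
                or (len(rows) - dn.sum()) < 2 * mns):
            continue  # cannot satisfy min treated/control in both children
        try:
            rho, _ = node_pseudo_outcomes(d_res[rows], y_res[rows], w[rows])
        except ValueError:
            continue
        feats = rng.choice(p, size=mtry, replace=False)
        found = best_split(X[np.ix_(rows, feats)], rho, w[rows], dn.astype(np.int64),
                           feats, mns, params.alpha, params.imbalance_penalty)
        if found is None:
            continue
        f, thr = found
        if split_records is not None:
            split_records.append((f, depth[node]))
        go_left = X[rows, f] <= thr
        feature[node], threshold[node] = f, thr
        nl, nr = new_node(depth[node] + 1), new_node(depth[node] + 1)
        left[node], right[node] = nl, nr
        stack.append((nl, rows[go_left]))
        stack.append((nr, rows[~go_left]))

    tree = CausalTree(
        feature=np.asarray(feature, np.int64),
        threshold=np.asarray(threshold, float),
        left=np.asarray(left, np.int64),
        right=np.asarray(right, np.int64),
        depth=np.asarray(depth, np.int64),
        split_sample=np.sort(split_half),
        estimation_sample=np.sort(est_half),
    )
    _populate_leaves(tree, X, est_half, params.honesty_prune_leaves)
    _leaf_statistics(tree, d_res, y_res, w)
    return tree


def _populate_leaves(tree: CausalTree, X: np.ndarray, est_rows: np.ndarray,
                     prune: bool) -> None:
    """Route estimation rows; determine termination nodes.

    A termination node is a structure leaf with estimation rows, or (with
    pruning) the shallowest node at which one child subtree would be empty of
    estimation rows — collapsing that branch keeps every honest leaf
    non-empty.
    """
    node_rows: dict[int, np.ndarray] = {}
    stack = [(0, np.asarray(est_rows))]
    while stack:
        node, rows = stack.pop()
        node_rows[node] = rows
        if tree.feature[node] < 0:
            continue
        go_left = X[rows, tree.feature[node]] <= tree.threshold[node]
        stack.append((tree.left[node], rows[go_left]))
        stack.append((tree.right[node], rows[~go_left]))

    term: dict[int, np.ndarray] = {}

    def walk(node):
        rows = node_rows.get(node, np.empty(0, np.int64))
        if tree.feature[node] < 0:
            if len(rows) > 0:
                term[node] = rows
            return
        if prune and (_subtree_empty(tree, tree.left[node], node_rows)
                      or _subtree_empty(tree, tree.right[node], node_rows)):
            if len(rows) > 0:
                term[node] = rows
            return
        walk(tree.left[node])
        walk(tree.right[node])

    walk(0)
    tree.term_rows = term


def _subtree_empty(tree: CausalTree, node: int, node_rows: dict) -> bool:
    """True when no *leaf* of the subtree holds estimation rows."""
    stack = [node]
    while stack:
        nd = stack.pop()
        if tree.feature[nd] < 0:
            if len(node_rows.get(nd, ())) > 0:
                return False
        else:
            stack.extend((tree.left[nd], tree.right[nd]))
    return True


def _leaf_statistics(tree: CausalTree, d_res, y_res, w) -> None:
    stats = {}
    for node, rows in tree.term_rows.items():
        wl = w[rows]
        wsum = float(wl.sum())
        s1 = float(np.dot(wl, d_res[rows] * y_res[rows]) / wsum)
        s2 = float(np.dot(wl, d_res[rows] ** 2) / wsum)
        stats[node] = (wsum, s1, s2)
    tree.term_stats = stats


class CausalForest:
    """Honest causal-forest model.

    fit() takes covariates, treatment, outcome, nuisance predictions
    (e_hat, m_hat) and sample weights; the centred residuals are retained for
    prediction.
    """

    def __init__(self, params: ForestParams | None = None):
        self.params = params or ForestParams()

    def fit(self, X, d, y, e_hat, m_hat, weights=None) -> "CausalForest":
        X = np.asarray(X, float)
        d = np.asarray(d)
        y = np.asarray(y, float)
        n, p = X.shape
        self.X_ = X
        self.d_ = d.astype(np.int64)
        self.w_ = np.ones(n) if weights is None else np.asarray(weights, float)
        self.d_res_ = d.astype(float) - np.asarray(e_hat, float)
        self.y_res_ = y - np.asarray(m_hat, float)
        self.trees_: list[CausalTree] = []
        self._split_records: list[tuple[int, int]] = []
        rng = derive_rng(self.params.seed, "forest")
        for _ in range(self.params.num_trees):
            self.trees_.append(grow_tree(X, self.d_res_, self.y_res_, self.d_,
                                         self.w_, self.params, rng,
                                         self._split_records))
        self.variable_importance_ = self._variable_importance(p)
        return self

    # -- prediction ------------------------------------------------------

    def _accumulate(self, X: np.ndarray, oob_only: bool = False,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-row numerator/denominator of the forest CATE ratio and the
        count of contributing trees."""
        X = np.asarray(X, float)
        num = np.zeros(len(X))
        den = np.zeros(len(X))
        cnt = np.zeros(len(X))
        for tree in self.trees_:
            nodes = tree.route(X)
            if oob_only:
                inbag = np.zeros(len(X), bool)
                sub = np.concatenate([tree.split_sample, tree.estimation_sample])
                inbag[sub[sub < len(X)]] = True
                nodes = np.where(inbag, -1, nodes)
            hit = nodes >= 0
            if not hit.any():
                continue
            stats = tree.term_stats
            s1 = np.array([stats[nd][1] for nd in nodes[hit]])
            s2 = np.array([stats[nd][2] for nd in nodes[hit]])
            num[hit] += s1
            den[hit] += s2
            cnt[hit] += 1
        return num, den, cnt

    def predict(self, X) -> np.ndarray:
        """tau_hat(x) for each row of X."""
        num, den, cnt = self._accumulate(np.asarray(X, float))
        if np.any(den <= _TINY):
            bad = int(np.flatnonzero(den <= _TINY)[0])
            raise ValueError(f"CATE undefined at row {bad}: zero weighted "
                             "treatment-residual variance in all matched leaves")
        return num / den

    def predict_oob(self) -> tuple[np.ndarray, np.ndarray]:
        """Out-of-bag tau_hat on the training rows and a defined-mask."""
        num, den, cnt = self._accumulate(self.X_, oob_only=True)
        ok = den > _TINY
        tau = np.full(len(self.X_), np.nan)
        tau[ok] = num[ok] / den[ok]
        return tau, ok

    def forest_weights(self, x) -> np.ndarray:
        """Normalised forest weight of every training row for one query x."""
        x = np.asarray(x, float).reshape(1, -1)
        wvec = np.zeros(len(self.X_))
        n_contrib = 0
        for tree in self.trees_:
            node = int(tree.route(x)[0])
            if node < 0:
                continue
            rows = tree.term_rows[node]
            wsum = tree.term_stats[node][0]
            wvec[rows] += self.w_[rows] / wsum
            n_contrib += 1
        if n_contrib == 0:
            raise ValueError("no tree could score the query point")
        return wvec / n_contrib

    estimate_cate = predict

    # -- importance & tuning --------------------------------------------

    def _variable_importance(self, p: int, decay: float = 0.5,
                             max_depth: int = 4) -> np.ndarray:
        """Depth-weighted split frequencies, decaying by ``decay`` per level
        over the first ``max_depth`` levels; normalised to sum to one."""
        counts = np.zeros((max_depth, p))
        for f, dep in self._split_records:
            if dep < max_depth:
                counts[dep, f] += 1
        totals = counts.sum(axis=1, keepdims=True)
        freq = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
        weights = decay ** np.arange(max_depth)
        score = (weights[:, None] * freq).sum(axis=0)
        return score / score.sum() if score.sum() > 0 else score

    @property
    def variable_importance(self) -> np.ndarray:
        return self.variable_importance_

    def r_loss(self) -> float:
        """Out-of-bag debiased (R-) loss: weighted MSE of Yres against
        tau_oob * Dres over rows with a defined OOB prediction."""
        tau, ok = self.predict_oob()
        if not ok.any():
            return np.inf
        resid = self.y_res_[ok] - tau[ok] * self.d_res_[ok]
        return float(np.dot(self.w_[ok], resid**2) / self.w_[ok].sum())

    def to_json(self) -> str:
        return json.dumps({
            "params": {k: getattr(self.params, k) for k in
                       ("num_trees", "sample_fraction", "mtry", "min_node_size",
                        "honesty_fraction", "honesty_prune_leaves", "alpha",
                        "imbalance_penalty", "seed")},
            "trees": [t.to_dict() for t in self.trees_],
        })


def tune_params(X, d, y, e_hat, m_hat, weights=None, candidates=None,
                n_draws: int = 10, tune_trees: int = 200, seed: int = 0,
                base: ForestParams | None = None) -> ForestParams:
    """Select forest parameters by out-of-bag debiased error of small forests.

    Candidates may be given explicitly; otherwise ``n_draws`` random draws
    over grf-style ranges are evaluated.  Deterministic given the seed.
    """
    base = base or ForestParams()
    if candidates is None:
        rng = derive_rng(seed, "tune-draws")
        n = len(np.asarray(y))
        p = np.asarray(X).shape[1]
        candidates = []
        for _ in range(n_draws):
            candidates.append(replace(
                base,
                sample_fraction=float(rng.uniform(0.2, 0.5)),
                mtry=int(rng.integers(max(1, p // 4), p + 1)),
                min_node_size=int(rng.integers(1, max(2, min(16, n // 50)))),
                honesty_fraction=float(rng.uniform(0.5, 0.8)),
                alpha=float(rng.uniform(0.0, 0.25)),
                imbalance_penalty=float(rng.uniform(0.0, 2.0)),
            ))
    if len(candidates) == 1:
        return candidates[0]
    best_params, best_loss = None, np.inf
    for j, cand in enumerate(candidates):
        small = replace(cand, num_trees=tune_trees, seed=derive_seed(seed, "tune", j))
        loss = CausalForest(small).fit(X, d, y, e_hat, m_hat, weights).r_loss()
        if loss < best_loss:
            best_params, best_loss = cand, loss
    return best_params
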