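"""Observation table: the validated container shared by every analysis stage.

One row per individual; columns are covariates (binary, continuous, or members
of a one-hot group), a binary treatment indicator, one or more non-negative
integer outcomes (utilisation counts), and optional positive survey frequency
weights. All estimators downstream treat the weights as frequency weights:
``sum(w)`` plays the role of the sample size and every mean, variance and
regression is weighted accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import as_weights, kish_neff, weighted_mean, weighted_sd

__all__ = [
    "ColumnMeta",
    "ObservationTable",
    "TwoPartOutcomeView",
    "FoldAssignment",
    "TableSchema",
    "load_table",
    "write_table",
    "two_part_view",
    "weighted_mean_sd",
    "assign_folds",
]

BINARY = "binary"
CONTINUOUS = "continuous"


@dataclass(frozen=True)
class ColumnMeta:
    """Covariate column metadata.

    kind is "binary", "continuous", or "onehot-group:<group>" for columns
    belonging to a mutually exclusive indicator block.
    """

    name: str
    kind: str

    @property
    def onehot_group(self) -> str | None:
        if self.kind.startswith("onehot-group:"):
            return self.kind.split(":", 1)[1]
        return None


@dataclass(frozen=True)
class TableSchema:
    """Column-role map used when reading a delimited file."""

    treatment: str
    outcomes: Sequence[str]
    weight: str | None = None
    covariates: Sequence[str] | None = None  # None: all remaining columns
    kinds: Mapping[str, str] | None = None  # overrides for inferred kinds


class ObservationTable:
    """Validated (X, D, Y, w) container.

    Parameters
    ----------
    covariates : DataFrame of shape (n, p), numeric, no missing values.
    treatment : array of {0,1}.
    outcomes : mapping name -> array of non-negative integers.
    weights : positive array, default all ones.
    covariate_meta : optional list of ColumnMeta; kinds are inferred
        (<= 2 distinct values -> binary) when omitted.
    """

    def __init__(self, covariates: pd.DataFrame, treatment, outcomes: Mapping[str, np.ndarray],
                 weights=None, covariate_meta: Sequence[ColumnMeta] | None = None):
        covariates = pd.DataFrame(covariates).copy()
        if covariates.shape[0] < 1 or covariates.shape[1] < 1:
            raise ValueError("need at least one row and one covariate")
        if covariates.isna().any().any():
            bad = [c for c in covariates.columns if covariates[c].isna().any()]
            row = int(covariates[bad[0]].index[covariates[bad[0]].isna()][0])
            raise ValueError(f"missing value in covariate {bad[0]!r} at row {row}")
        self.covariates = covariates.astype(float)
        n = len(covariates)

        d = np.asarray(treatment)
        if d.shape != (n,):
            raise ValueError("treatment length mismatch")
        if np.any(pd.isna(d)):
            raise ValueError("missing value in treatment")
        if not np.isin(d, (0, 1)).all():
            bad = int(np.flatnonzero(~np.isin(d, (0, 1)))[0])
            raise ValueError(f"treatment must be 0/1; offending row {bad}")
        self.treatment = d.astype(np.int8)

        self.outcomes: dict[str, np.ndarray] = {}
        for name, y in outcomes.items():
            y = np.asarray(y)
            if y.shape != (n,):
                raise ValueError(f"outcome {name!r} length mismatch")
            if np.any(pd.isna(y)):
                raise ValueError(f"missing value in outcome {name!r}")
            yf = y.astype(float)
            if np.any(yf < 0) or np.any(yf != np.round(yf)):
                bad = int(np.flatnonzero((yf < 0) | (yf != np.round(yf)))[0])
                raise ValueError(f"outcome {name!r} must be a non-negative integer; row {bad}")
            self.outcomes[name] = yf.astype(np.int64)
        if not self.outcomes:
            raise ValueError("at least one outcome required")

        self.weights = as_weights(weights, n)

        if covariate_meta is None:
            covariate_meta = [ColumnMeta(c, _infer_kind(self.covariates[c].to_numpy()))
                              for c in self.covariates.columns]
        meta_names = [m.name for m in covariate_meta]
        if meta_names != list(self.covariates.columns):
            raise ValueError("covariate_meta does not match covariate columns")
        self.covariate_meta = list(covariate_meta)
        self._validate_kinds()

    def _validate_kinds(self) -> None:
        groups: dict[str, list[str]] = {}
        for m in self.covariate_meta:
            x = self.covariates[m.name].to_numpy()
            if m.kind == BINARY and not np.isin(x, (0.0, 1.0)).all():
                raise ValueError(f"binary covariate {m.name!r} contains non-0/1 values")
            g = m.onehot_group
            if g is not None:
                if not np.isin(x, (0.0, 1.0)).all():
                    raise ValueError(f"one-hot covariate {m.name!r} contains non-0/1 values")
                groups.setdefault(g, []).append(m.name)
        for g, cols in groups.items():
            if (self.covariates[cols].sum(axis=1) > 1).any():
                raise ValueError(f"one-hot group {g!r} has a row summing to > 1")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.covariates)

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def covariate_matrix(self) -> np.ndarray:
        return self.covariates.to_numpy(dtype=float)

    def outcome(self, name: str) -> np.ndarray:
        if name not in self.outcomes:
            raise KeyError(f"unknown outcome {name!r}; have {sorted(self.outcomes)}")
        return self.outcomes[name]

    def subset(self, idx) -> "ObservationTable":
        idx = np.asarray(idx)
        return ObservationTable(
            self.covariates.iloc[idx].reset_index(drop=True),
            self.treatment[idx],
            {k: v[idx] for k, v in self.outcomes.items()},
            self.weights[idx],
            self.covariate_meta,
        )

    def effective_n(self) -> float:
        return kish_neff(self.weights)

    def to_dataframe(self, schema: TableSchema | None = None) -> pd.DataFrame:
        tcol = schema.treatment if schema else "treatment"
        wcol = (schema.weight if schema else "weight") or "weight"
        df = self.covariates.copy()
        df[tcol] = self.treatment.astype(int)
        for name, y in self.outcomes.items():
            df[name] = y
        df[wcol] = self.weights
        return df


def _infer_kind(x: np.ndarray) -> str:
    return BINARY if len(np.unique(x)) <= 2 and np.isin(x, (0.0, 1.0)).all() else CONTINUOUS


@dataclass(frozen=True)
class TwoPartOutcomeView:
    """Hurdle decomposition of one outcome: participation 1{Y>0} and the
    positive counts (consumption) restricted to participants."""

    participation: np.ndarray
    consumption_index: np.ndarray
    consumption_values: np.ndarray


def two_part_view(table: ObservationTable, outcome: str) -> TwoPartOutcomeView:
    y = table.outcome(outcome)
    part = (y > 0).astype(np.int8)
    idx = np.flatnonzero(part)
    return TwoPartOutcomeView(part, idx, y[idx])


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of rows into labelled folds (1..K), optionally grouped so
    that all rows sharing a key (e.g. a household id) share a fold."""

    fold_label: np.ndarray
    seed: int
    n_folds: int = 3
    grouping_key: str | None = None

    def rows(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.fold_label == label)


def assign_folds(n: int, n_folds: int = 3, seed: int = 0,
                 group_ids: np.ndarray | None = None,
                 grouping_key: str | None = None) -> FoldAssignment:
    """Random fold assignment with sizes differing by at most one unit.

    When group_ids is given, whole groups are allocated to folds (sizes then
    differ by at most one group).
    """
    if not (2 <= n_folds <= n):
        raise ValueError(f"need 2 <= n_folds <= n, got K={n_folds}, n={n}")
    rng = np.random.default_rng(seed)
    if group_ids is None:
        units = np.arange(n)
        membership = units
    else:
        group_ids = np.asarray(group_ids)
        uniq, membership = np.unique(group_ids, return_inverse=True)
        units = np.arange(len(uniq))
    perm = rng.permutation(len(units))
    unit_fold = np.empty(len(units), dtype=np.int64)
    unit_fold[perm] = 1 + np.arange(len(units)) % n_folds
    labels = unit_fold[membership]
    return FoldAssignment(labels, seed=seed, n_folds=n_folds, grouping_key=grouping_key)


def weighted_mean_sd(values, weights) -> tuple[float, float]:
    """Frequency-weighted mean and SD (denominator sum(w) - 1).

    With integer weights these equal the plain mean/SD of the row-replicated
    sample.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return weighted_mean(values, weights), weighted_sd(values, weights)


# -- delimited-text I/O --------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def load_table(path, schema: TableSchema) -> ObservationTable:
    """Read a delimited text file (CSV/TSV by extension) into a validated table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    needed = [schema.treatment, *schema.outcomes]
    if schema.weight:
        needed.append(schema.weight)
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"schema names column {col!r} absent from {path.name}")
    if schema.covariates is None:
        cov_cols = [c for c in df.columns if c not in set(needed)]
    else:
        missing = [c for c in schema.covariates if c not in df.columns]
        if missing:
            raise ValueError(f"covariate columns absent: {missing}")
        cov_cols = list(schema.covariates)
    meta = None
    if schema.kinds:
        meta = [ColumnMeta(c, schema.kinds.get(c, _infer_kind(df[c].to_numpy(dtype=float))))
                for c in cov_cols]
    return ObservationTable(
        df[cov_cols],
        df[schema.treatment].to_numpy(),
        {o: df[o].to_numpy() for o in schema.outcomes},
        df[schema.weight].to_numpy() if schema.weight else None,
        meta,
    )


def write_table(table: ObservationTable, path, schema: TableSchema | None = None) -> None:
    """Write as delimited text; numeric columns round-trip bit-identically
    (floats are serialised with shortest round-trip repr)."""
    path = Path(path)
    table.to_dataframe(schema).to_csv(path, sep=_sep_for(path), index=False)
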