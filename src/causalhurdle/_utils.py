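"""Shared numerical helpers: seeded streams, weighted moments, effective sample size."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = [
    "derive_seed",
    "derive_rng",
    "weighted_mean",
    "weighted_var",
    "weighted_sd",
    "kish_neff",
    "weighted_quantile",
    "as_weights",
]


def derive_seed(master: int, *tags: object) -> int:
    """Derive a named child seed (< 2**31) from a master seed.

    The tag tuple is hashed with crc32 so independently named streams
    (e.g. "covariates", "treatment", ("round", 2)) never collide by accident
    and are stable across processes.
    """
    label = "/".join(str(t) for t in tags)
    h = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def derive_rng(master: int, *tags: object) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *tags))


def as_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.ones(n, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights have shape {w.shape}, expected ({n},)")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    return w


def weighted_mean(x, w) -> float:
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    sw = w.sum()
    if sw <= 0:
        raise ValueError("total weight must be positive")
    return float(np.dot(w, x) / sw)


def weighted_var(x, w, ddof: int = 1) -> float:
    """Frequency-weight variance: denominator sum(w) - ddof.

    With integer weights and ddof=1 this equals the unbiased sample variance
    of the row-replicated data, which is the convention used throughout.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    sw = w.sum()
    if sw - ddof <= 0:
        return 0.0
    mu = np.dot(w, x) / sw
    return float(np.dot(w, (x - mu) ** 2) / (sw - ddof))


def weighted_sd(x, w, ddof: int = 1) -> float:
    return float(np.sqrt(max(weighted_var(x, w, ddof=ddof), 0.0)))


def kish_neff(w) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(w, dtype=float)
    s2 = np.dot(w, w)
    if s2 <= 0:
        raise ValueError("total weight must be positive")
    return float(w.sum() ** 2 / s2)


def weighted_quantile(x, w, q) -> np.ndarray:
    """Weighted empirical quantiles (inverse of the weighted CDF).

    Uses the right-continuous weighted CDF: the quantile at level q is the
    smallest x with cumulative weight share >= q.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    cdf = np.cumsum(ws) / ws.sum()
    idx = np.searchsorted(cdf, q, side="left")
    idx = np.clip(idx, 0, len(xs) - 1)
    return xs[idx]
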