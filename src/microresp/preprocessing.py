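"""Compositional preprocessing: subset, renormalize, sqrt, standardize.

The fixed order of operations is: select a taxon subset, renormalize each row
back to a proper composition (unit L1 norm), compress dynamic range with an
elementwise square root, then center and scale each taxon using the mean and
*population* variance (divisor K) computed on the designated training samples
only. Whenever the training set changes the statistics are refit and every
sample is re-standardized.

Taxa with zero training variance are mapped to 0 (with a warning) rather than
dropped, so the feature coordinate system stays fixed across folds and trials
— a requirement for averaging classifier weight vectors later.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


def subset_and_renormalize(x: np.ndarray, subset=None, zero_policy: str = "error"):
    """Select columns ``subset`` and renormalize each row to unit L1 norm.

    ``zero_policy`` controls rows whose subset entries are all zero:
    ``"error"`` (default) raises; ``"drop"`` removes them with a warning and
    returns ``(y, kept_row_indices)`` instead of just ``y``; ``"zero"`` keeps
    them as all-zero compositions (an all-absent profile), which preserves
    row geometry for cross-validation folds.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    if subset is None:
        y = x
    else:
        idx = np.asarray(subset)
        if idx.size == 0:
            raise ValueError("taxon subset is empty")
        y = x[:, idx.astype(int)]
    if y.shape[1] == 0:
        raise ValueError("taxon subset is empty")
    norms = y.sum(axis=1)
    dead = norms == 0
    if dead.any():
        if zero_policy == "error":
            raise ValueError(
                f"row {int(np.flatnonzero(dead)[0])} has zero abundance over the "
                "selected taxa (zero L1 norm)"
            )
        if zero_policy == "drop":
            warnings.warn(
                f"dropping {int(dead.sum())} row(s) with zero abundance over the subset",
                stacklevel=2,
            )
            kept = np.flatnonzero(~dead)
            return y[kept] / norms[kept, None], kept
        if zero_policy == "zero":
            out = np.zeros_like(y, dtype=float)
            live = ~dead
            out[live] = y[live] / norms[live, None]
            return out
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    out = y / norms[:, None]
    if zero_policy == "drop":
        return out, np.arange(x.shape[0])
    return out


def sqrt_transform(y: np.ndarray) -> np.ndarray:
    """Elementwise square root (dynamic-range compression)."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("sqrt transform requires non-negative entries")
    return np.sqrt(y)


@dataclass
class TrainStats:
    """Per-taxon mean and population variance of sqrt abundances over the
    training samples (divisor K, the training-set size)."""

    mu: np.ndarray
    var: np.ndarray
    n_train: int

    def __post_init__(self) -> None:
        if np.any(self.var < 0):
            raise ValueError("variances must be non-negative")


def fit_stats(ytil: np.ndarray, train_idx) -> TrainStats:
    """Mean and population variance per taxon over training rows ``train_idx``."""
    ytil = np.asarray(ytil, dtype=float)
    idx = np.asarray(train_idx)
    if idx.size < 2:
        raise ValueError(f"need at least 2 training samples, got {idx.size}")
    sub = ytil[idx]
    mu = sub.mean(axis=0)
    var = sub.var(axis=0)  # ddof=0: divisor K
    return TrainStats(mu=mu, var=var, n_train=int(idx.size))


def standardize(ytil: np.ndarray, stats: TrainStats) -> np.ndarray:
    """Center/scale by training stats; zero-variance taxa map to 0."""
    ytil = np.asarray(ytil, dtype=float)
    if ytil.shape[1] != stats.mu.shape[0]:
        raise ValueError(
            f"feature count {ytil.shape[1]} does not match fitted stats "
            f"({stats.mu.shape[0]})"
        )
    sigma = np.sqrt(stats.var)
    degenerate = sigma == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} taxon(a) constant on the training set; "
            "standardized values set to 0",
            stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, sigma)
    z = (ytil - stats.mu) / safe
    z[:, degenerate] = 0.0
    return z


class CompositionalPreprocessor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer chaining subset -> renormalize -> sqrt ->
    standardize.

    Fit on training rows only (it learns per-taxon mean/variance of sqrt
    abundances there), then transform any rows: test samples are standardized
    with the training statistics.

    Parameters
    ----------
    subset : array-like of column indices or None
        Taxa to retain before renormalization. None keeps all columns.
    zero_policy : {"error", "drop", "zero"}
        What to do with rows that are all-zero over the subset. "drop" only
        applies during :meth:`fit`; "zero" keeps such rows as all-zero
        compositions in both fit and transform.
    """

    def __init__(self, subset=None, zero_policy: str = "error"):
        self.subset = subset
        self.zero_policy = zero_policy

    def _compress(self, X) -> np.ndarray:
        policy = "zero" if self.zero_policy == "zero" else "error"
        y = subset_and_renormalize(X, self.subset, zero_policy=policy)
        return sqrt_transform(y)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.zero_policy == "drop":
            ysub, kept = subset_and_renormalize(X, self.subset, zero_policy="drop")
            ytil = sqrt_transform(ysub)
            self.fit_rows_ = kept
        else:
            ytil = self._compress(X)
            self.fit_rows_ = np.arange(X.shape[0])
        self.stats_ = fit_stats(ytil, np.arange(ytil.shape[0]))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "stats_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, transformer was fitted with "
                f"{self.n_features_in_}"
            )
        return standardize(self._compress(X), self.stats_)
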