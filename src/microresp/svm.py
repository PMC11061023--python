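"""Linear soft-margin SVM training, prediction, and classifier averaging.

The classifier solves

    min_{w,b,xi}  (1/2) w'w + C sum_n xi_n
    s.t.          d_n (w'z_n - b) >= 1 - xi_n,   xi_n >= 0

with labels d_n in {1, -1} and decision rule sign(w'z - b); a decision value
of exactly 0 maps to class 1 deterministically. Note the bias convention:
the boundary is w'z - b = 0, so b is the *negative* of the intercept used by
scikit-learn/LIBSVM internals.

Training is delegated to LIBSVM through :class:`sklearn.svm.SVC` with a
linear kernel and a tight tolerance; the contract tested elsewhere is
optimality of the quadratic program above, not any solver detail. Slack
variables and the primal objective are reconstructed from the solution and
exposed as fitted attributes.

Averaging many trained classifiers elementwise — mean of w, mean of b —
yields the consensus hyperplane whose coefficient magnitudes later define
each taxon's decision influence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

DEFAULT_C = 10.0


def _validate_zd(Z, d=None):
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValueError("feature matrix must be 2-D (samples x features)")
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite feature values")
    if d is None:
        return Z
    d = np.asarray(d, dtype=int)
    if d.shape != (Z.shape[0],):
        raise ValueError("labels must be one per sample")
    if not set(np.unique(d)) <= {1, -1}:
        raise ValueError("labels must be in {1, -1}")
    if np.unique(d).size < 2:
        raise ValueError("training set contains a single class")
    return Z, d


def _refine_active_set(Z, d, C, w, b, alpha, eps: float = 1e-5):
    """One exact Newton/KKT step on the active set implied by (w, b).

    Samples with margin < 1 - eps keep alpha = C; samples with margin within
    eps of 1 are treated as free support vectors, and (w, b, alpha_free) are
    recomputed from the KKT equality system. Falls back to the input when the
    implied active set is inconsistent (e.g. a recomputed alpha leaves
    [0, C]) or does not improve the primal objective.
    """
    d = np.asarray(d, dtype=float)
    margins = d * (Z @ w - b)
    at_bound = margins < 1.0 - eps
    F = np.flatnonzero((np.abs(margins - 1.0) <= eps) & ~at_bound)
    U = np.flatnonzero(at_bound)
    M = Z.shape[1]
    nf = F.size
    if nf == 0:
        return w, b, alpha
    A = np.zeros((M + 1 + nf, M + 1 + nf))
    rhs = np.zeros(M + 1 + nf)
    A[:M, :M] = np.eye(M)
    A[:M, M + 1:] = -(d[F, None] * Z[F]).T
    rhs[:M] = C * (d[U, None] * Z[U]).sum(axis=0) if U.size else 0.0
    A[M, M + 1:] = d[F]
    rhs[M] = -C * d[U].sum()
    A[M + 1:, :M] = d[F, None] * Z[F]
    A[M + 1:, M] = -d[F]
    rhs[M + 1:] = 1.0
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    w2, b2, aF = sol[:M], float(sol[M]), sol[M + 1:]
    if aF.min() < -1e-8 or aF.max() > C + 1e-8:
        return w, b, alpha
    xi2 = np.maximum(0.0, 1.0 - d * (Z @ w2 - b2))
    obj2 = 0.5 * w2 @ w2 + C * xi2.sum()
    obj1 = 0.5 * w @ w + C * np.maximum(0.0, 1.0 - margins).sum()
    if obj2 > obj1 + 1e-9:
        return w, b, alpha
    alpha2 = np.zeros_like(alpha)
    alpha2[U] = C
    alpha2[F] = np.clip(aF, 0.0, C)
    return w2, b2, alpha2


class LinearMarginSVC(ClassifierMixin, BaseEstimator):
    """Linear soft-margin SVM with the w'z - b decision convention.

    Parameters
    ----------
    C : float
        Slack cost (default 10).
    tol : float
        Solver stopping tolerance (kept tight so the solution satisfies the
        optimality contract checked against an independent QP oracle).

    Attributes
    ----------
    w_ : ndarray of shape (n_features,)
        Hyperplane normal vector.
    b_ : float
        Bias; the boundary is ``w_ @ z - b_ = 0``.
    xi_ : ndarray of shape (n_train,)
        Slack of each training sample, ``max(0, 1 - d_n (w'z_n - b))``.
    objective_ : float
        Primal objective value at the solution.
    """

    def __init__(self, C: float = DEFAULT_C, tol: float = 1e-4):
        self.C = C
        self.tol = tol

    def fit(self, Z, d):
        Z, d = _validate_zd(Z, d)
        if self.C <= 0:
            raise ValueError("C must be positive")
        svc = SVC(kernel="linear", C=self.C, tol=self.tol, shrinking=False)
        svc.fit(Z, d)
        # SVC orders classes_ as [-1, 1], so decision = coef_ @ z + intercept_
        # is positive for class 1; our convention is w'z - b with b = -intercept.
        w = svc.coef_.ravel().copy()
        b = float(-svc.intercept_[0])
        # dense dual variables: svc.dual_coef_ holds d_n * alpha_n for SVs
        alpha = np.zeros(Z.shape[0])
        alpha[svc.support_] = np.abs(svc.dual_coef_.ravel())
        # SMO stops early (tol on the dual gradient); refining on the active
        # set it identified drives the KKT system to numerical precision,
        # iterating as the active-set classification sharpens
        for eps in (10 * self.tol, 1e-7, 1e-9):
            w, b, alpha = _refine_active_set(Z, d, self.C, w, b, alpha, eps=eps)
        self.w_, self.b_, self.alpha_ = w, b, alpha
        margins = d * (Z @ self.w_ - self.b_)
        self.xi_ = np.maximum(0.0, 1.0 - margins)
        self.objective_ = float(0.5 * self.w_ @ self.w_ + self.C * self.xi_.sum())
        self.classes_ = np.array([-1, 1])
        self.n_features_in_ = Z.shape[1]
        return self

    def decision_function(self, Z) -> np.ndarray:
        check_is_fitted(self, "w_")
        Z = _validate_zd(Z)
        if Z.shape[1] != self.w_.shape[0]:
            raise ValueError(
                f"feature dimension {Z.shape[1]} does not match model "
                f"dimension {self.w_.shape[0]}"
            )
        return Z @ self.w_ - self.b_

    def predict(self, Z) -> np.ndarray:
        # exactly-zero decision values map to class 1
        return np.where(self.decision_function(Z) >= 0, 1, -1)


@dataclass
class AveragedModel:
    """Elementwise average of many linear classifiers: (w*, b*).

    ``n_models`` counts the training phases that contributed (5T for T trials
    of five-fold cross-validation).
    """

    w_star: np.ndarray
    b_star: float
    n_models: int

    def decision_function(self, Z) -> np.ndarray:
        Z = _validate_zd(Z)
        if Z.shape[1] != self.w_star.shape[0]:
            raise ValueError("feature dimension does not match averaged model")
        return Z @ self.w_star - self.b_star

    def predict(self, Z) -> np.ndarray:
        return np.where(self.decision_function(Z) >= 0, 1, -1)

    @property
    def gains(self) -> np.ndarray:
        """Per-feature gain |w*_m| — the decision-influence statistic."""
        return np.abs(self.w_star)


def train(Z, d, C: float = DEFAULT_C) -> LinearMarginSVC:
    """Train one linear soft-margin SVM (thin wrapper over the estimator)."""
    return LinearMarginSVC(C=C).fit(Z, d)


def average_models(models) -> AveragedModel:
    """Average (w, b) over trained models or (w, b) pairs elementwise."""
    ws, bs = [], []
    for m in models:
        if isinstance(m, LinearMarginSVC):
            check_is_fitted(m, "w_")
            ws.append(np.asarray(m.w_, dtype=float))
            bs.append(float(m.b_))
        else:
            w, b = m
            ws.append(np.asarray(w, dtype=float))
            bs.append(float(b))
    if not ws:
        raise ValueError("no models to average")
    dim = ws[0].shape
    if any(w.shape != dim for w in ws):
        raise ValueError("models have mixed dimensionality; cannot average")
    return AveragedModel(
        w_star=np.mean(ws, axis=0), b_star=float(np.mean(bs)), n_models=len(ws)
    )
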