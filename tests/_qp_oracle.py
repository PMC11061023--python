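"""Independent quadratic-program oracle for the soft-margin linear SVM.

Solves the primal

    min_{w,b,xi}  0.5 ||w||^2 + C sum_n xi_n
    s.t.          d_n (w'z_n - b) >= 1 - xi_n,   xi_n >= 0

directly with scipy's trust-constr solver on the stacked variable
x = [w, b, xi], with analytic gradient, Hessian and constraint Jacobian.
Deliberately independent of the package's solver path: it shares no code
with the implementation under test.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, minimize


def solve_primal_qp(Z: np.ndarray, d: np.ndarray, C: float):
    """Return (w, b, xi, objective) at the QP optimum."""
    Z = np.asarray(Z, dtype=float)
    d = np.asarray(d, dtype=float)
    K, M = Z.shape
    n_var = M + 1 + K

    def objective(x):
        w, xi = x[:M], x[M + 1:]
        return 0.5 * w @ w + C * xi.sum()

    def grad(x):
        g = np.zeros(n_var)
        g[:M] = x[:M]
        g[M + 1:] = C
        return g

    hess_diag = np.zeros(n_var)
    hess_diag[:M] = 1.0
    hessian = sparse.diags(hess_diag)

    # margin constraints: d_n (w'z_n - b) + xi_n >= 1, all linear in x
    A = np.zeros((K, n_var))
    A[:, :M] = d[:, None] * Z
    A[:, M] = -d
    A[:, M + 1:] = np.eye(K)
    margin_con = LinearConstraint(A, 1.0, np.inf)
    lb = np.full(n_var, -np.inf)
    lb[M + 1:] = 0.0

    x0 = np.zeros(n_var)
    x0[M + 1:] = 1.0  # xi = 1 makes the start feasible at w = 0, b = 0
    res = minimize(
        objective, x0, jac=grad, hess=lambda x: hessian, method="trust-constr",
        bounds=Bounds(lb, np.full(n_var, np.inf)), constraints=[margin_con],
        options={"maxiter": 3000, "gtol": 1e-12, "xtol": 1e-14},
    )
    if res.status not in (1, 2):
        raise RuntimeError(f"QP oracle failed to converge: {res.message}")
    x = res.x
    # iterate the exact active-set refinement to fixed point; the first pass
    # classifies constraints from the (~1e-5 accurate) interior-point iterate
    for eps in (1e-4, 1e-7, 1e-9):
        x = _polish_active_set(Z, d, C, x, eps=eps)
    w, b, xi = x[:M], x[M], x[M + 1:]
    return w, float(b), np.maximum(xi, 0.0), float(objective(x))


def _polish_active_set(Z, d, C, x, eps=1e-5):
    """Refine an approximate solution by solving the KKT equality system of
    its active set exactly; falls back to the input if the guess fails."""
    K, M = Z.shape
    w, b, xi = x[:M], x[M], np.maximum(x[M + 1:], 0.0)
    margins = d * (Z @ w - b)
    slack_active = margins < 1.0 - eps  # xi > 0  =>  alpha = C
    on_margin = np.abs(margins - 1.0) <= eps  # free SVs, 0 <= alpha <= C
    F = np.flatnonzero(on_margin & ~slack_active)
    U = np.flatnonzero(slack_active)
    nf = F.size
    # unknowns: [w (M), b, alpha_F (nf)]
    n_unk = M + 1 + nf
    A = np.zeros((M + 1 + nf, n_unk))
    rhs = np.zeros(M + 1 + nf)
    # stationarity in w: w - sum_F alpha d z = C sum_U d z
    A[:M, :M] = np.eye(M)
    if nf:
        A[:M, M + 1:] = -(d[F, None] * Z[F]).T
    rhs[:M] = C * (d[U, None] * Z[U]).sum(axis=0) if U.size else 0.0
    # stationarity in b: sum_F alpha d = -C sum_U d
    if nf:
        A[M, M + 1:] = d[F]
    rhs[M] = -C * d[U].sum()
    # active margins: d_n (w'z_n - b) = 1 for n in F
    if nf:
        A[M + 1:, :M] = d[F, None] * Z[F]
        A[M + 1:, M] = -d[F]
        rhs[M + 1:] = 1.0
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    w2, b2, aF = sol[:M], sol[M], sol[M + 1:]
    if nf and (aF.min() < -1e-8 or aF.max() > C + 1e-8):
        return x  # active-set guess wrong; keep unpolished solution
    xi2 = np.maximum(0.0, 1.0 - d * (Z @ w2 - b2))
    obj2 = 0.5 * w2 @ w2 + C * xi2.sum()
    obj1 = 0.5 * w @ w + C * np.maximum(0.0, 1.0 - margins).sum()
    if obj2 > obj1 + 1e-9:
        return x
    out = np.empty_like(x)
    out[:M], out[M], out[M + 1:] = w2, b2, xi2
    return out


def kkt_residual(Z, d, C, w, b, alpha):
    """Max violation of the KKT conditions at (w, b) with duals ``alpha``.

    Checks stationarity (w equals the support expansion, and the bias
    gradient sums to zero), dual feasibility (alpha in [0, C]), and
    complementary slackness of the margin and box constraints.
    """
    Z = np.asarray(Z, dtype=float)
    d = np.asarray(d, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    margins = d * (Z @ w - b)
    xi = np.maximum(0.0, 1.0 - margins)
    residuals = [
        float(np.max(np.abs(w - (alpha * d) @ Z))),  # stationarity in w
        float(abs(alpha @ d)),  # stationarity in b
        float(max(0.0, -alpha.min(), alpha.max() - C)),  # 0 <= alpha <= C
        float(np.max(alpha * np.maximum(margins - 1.0, 0.0))),  # alpha (1 - margin - xi)
        float(np.max((C - alpha) * xi)),  # (C - alpha) xi
    ]
    return max(residuals)
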