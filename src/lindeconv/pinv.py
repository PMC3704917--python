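"""Pseudoinverse-family point estimators for the deconvolution problem.

Given fraction totals b and sort matrix A, the per-gene expression vector x
solves the (usually underdetermined) system A x = b with x >= 0.  Three
estimators are provided:

* ``naive_pseudoinverse`` — the Moore-Penrose minimum-2-norm solution
  A+ b with negative entries truncated at zero (truncation generally
  breaks the equality constraint, which the result's ``feasible`` flag
  reports);
* ``constrained_pseudoinverse`` — the minimum-2-norm point of the feasible
  polytope {x >= 0 : A x = b} (the maximum-likelihood estimate under an
  isotropic Gaussian prior restricted to the constraints);
* ``correlated_pseudoinverse`` — the same with a Mahalanobis objective
  x' sigma^-1 x, favouring solutions consistent with a cell-cell
  correlation model estimated from known expression patterns.

When the equality system has no non-negative solution (e.g. after noise
perturbation), the constrained variants fall back to the non-negative
least-squares minimizer of ||A x - b|| (least objective-norm among the
minimizers), with ``feasible=False``.

Implementation: non-negativity is handled by NNLS on a penalty-weighted
stacked system [w A; W] x ~ [w b; 0] (W' W the objective metric), whose
solution identifies the active set; the estimate is then polished by the
exact KKT solution of the equality-constrained problem on the free
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.optimize import nnls

from .sort_model import SortMatrix
from .expression import CorrelationModel

__all__ = [
    "DeconvResult",
    "naive_pseudoinverse",
    "constrained_pseudoinverse",
    "correlated_pseudoinverse",
]

PINV_RCOND = 1e-10      # relative singular-value cutoff for pseudoinverses
PENALTY_WEIGHT = 1e6    # equality-penalty weight in the stacked NNLS system


@dataclass
class DeconvResult:
    """Point estimate of per-cell expression for one gene."""

    estimate: np.ndarray
    method: str
    residual: float          # ||A @ estimate - b||_2
    feasible: bool           # equality satisfied within tolerance

    def __post_init__(self):
        self.estimate = np.asarray(self.estimate, dtype=float)


def _as_array(A) -> np.ndarray:
    if isinstance(A, SortMatrix):
        return A.A
    return np.atleast_2d(np.asarray(A, dtype=float))


def _check_dims(A: np.ndarray, b: np.ndarray):
    if b.ndim != 1 or b.shape[0] != A.shape[0]:
        raise ValueError(f"b has shape {b.shape}, expected ({A.shape[0]},)")


def _feasible(A: np.ndarray, x: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    res = float(np.linalg.norm(A @ x - b))
    nb = np.linalg.norm(b)
    return res, res <= (1e-6 * nb if nb > 0 else 1e-9)


def naive_pseudoinverse(A, b) -> DeconvResult:
    """Minimum-2-norm solution A+ b with negatives truncated at zero."""
    Aa = _as_array(A)
    b = np.asarray(b, dtype=float)
    _check_dims(Aa, b)
    x = np.linalg.pinv(Aa, rcond=PINV_RCOND) @ b
    x = np.maximum(x, 0.0)
    res, feas = _feasible(Aa, x, b)
    return DeconvResult(x, "naive_pseudoinverse", res, feas)


def _min_qnorm_on_support(A: np.ndarray, b: np.ndarray, free: np.ndarray,
                          Minv_chol: np.ndarray | None) -> np.ndarray | None:
    """Exact minimizer of x' M x subject to A x = b restricted to the free
    support (x zero elsewhere); least-squares / least-norm when equality is
    unattainable.  For M = I this is pinv(A_F) b; in general the KKT system
    x_F = M_FF^-1 A_F' lambda with A_F M_FF^-1 A_F' lambda = b."""
    x = np.zeros(A.shape[1])
    if not free.any():
        return x
    Af = A[:, free]
    if Minv_chol is None:
        x[free] = np.linalg.pinv(Af, rcond=PINV_RCOND) @ b
        return x
    # objective metric M = W' W with W = Minv_chol (cholesky of sigma^-1)
    Wf = Minv_chol[:, free]
    Mff = Wf.T @ Wf
    try:
        S = np.linalg.inv(Mff)
    except np.linalg.LinAlgError:
        return None
    K = Af @ S @ Af.T
    lam = np.linalg.pinv(K, rcond=PINV_RCOND) @ b
    x[free] = S @ Af.T @ lam
    return x


def _constrained_solve(A: np.ndarray, b: np.ndarray, W: np.ndarray | None,
                       method: str) -> DeconvResult:
    n = A.shape[1]
    Wmat = np.eye(n) if W is None else W
    scale = max(np.abs(A).max(), 1e-30)
    w = PENALTY_WEIGHT * np.abs(Wmat).max() / scale
    C = np.vstack([w * A, Wmat])
    d = np.concatenate([w * b, np.zeros(n)])
    x_pen, _ = nnls(C, d, maxiter=10 * max(C.shape))
    res_pen, feas_pen = _feasible(A, x_pen, b)

    # polish: exact KKT solve on the detected support
    thresh = 1e-9 * max(x_pen.max(), 1.0)
    x_pol = _min_qnorm_on_support(A, b, x_pen > thresh, W)
    if x_pol is not None and x_pol.min() >= -1e-10:
        res_pol, feas_pol = _feasible(A, np.maximum(x_pol, 0.0), b)
        if res_pol <= res_pen * (1 + 1e-9) + 1e-12:
            x = np.maximum(x_pol, 0.0)
            return DeconvResult(x, method, res_pol, feas_pol)
    return DeconvResult(x_pen, method, res_pen, feas_pen)


def constrained_pseudoinverse(A, b) -> DeconvResult:
    """Minimum-2-norm point of {x >= 0 : A x = b}; falls back to the
    non-negative least-squares minimizer when equality is infeasible."""
    Aa = _as_array(A)
    b = np.asarray(b, dtype=float)
    _check_dims(Aa, b)
    return _constrained_solve(Aa, b, None, "constrained_pseudoinverse")


def correlated_pseudoinverse(A, b, model: CorrelationModel) -> DeconvResult:
    """Minimizer of x' sigma^-1 x subject to A x = b, x >= 0 — the
    maximum-likelihood point under a Gaussian prior with the given
    cell-cell correlation."""
    Aa = _as_array(A)
    b = np.asarray(b, dtype=float)
    _check_dims(Aa, b)
    if model.n_cells != Aa.shape[1]:
        raise ValueError("correlation model size does not match cell count")
    try:
        Sinv = np.linalg.inv(model.sigma)
        W = np.linalg.cholesky((Sinv + Sinv.T) / 2).T  # upper, W'W = sigma^-1
    except np.linalg.LinAlgError as e:
        raise ValueError("correlation matrix is singular; use shrinkage > 0") from e
    return _constrained_solve(Aa, b, W, "correlated_pseudoinverse")
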