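"""Expectation-propagation posterior approximation over the feasible polytope.

The set of expression patterns consistent with the measurements,
{x >= 0 : A x = b}, is a convex polytope; treating it as a uniform
posterior, EP approximates it with a multivariate Gaussian whose marginals
give per-cell point estimates with uncertainty.

Construction: a broad Gaussian prior N(0, tau I) is combined with one
univariate Gaussian *site* per cell standing in for the indicator
x_i >= 0, and the resulting Gaussian is conditioned exactly on the linear
equalities A x = b.  Each sweep updates all sites in parallel by
truncated-normal moment matching on their cavity distributions.  Working
quantities are put on a relative scale (divided by the gene's total
expression) and a small offset (default 1e-3) is added to every cell so the
polytope has interior; the offset is subtracted from the returned mean.

The undamped iteration occasionally diverges (numerically invalid cavities),
in which case :class:`EPDivergenceError` is raised naming the sweep.  The
damped variant instead halves its step size and restarts the sweep from the
last valid state, and always returns a result — at the cost of more sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy.special import erfcx

from .sort_model import SortMatrix

__all__ = ["EPResult", "EPDivergenceError", "ep_deconvolve", "ep_group_summary"]


class EPDivergenceError(RuntimeError):
    """Raised by undamped EP when a sweep produces an invalid update."""

    def __init__(self, sweep: int, detail: str = ""):
        self.sweep = sweep
        super().__init__(f"EP diverged at sweep {sweep}" + (f": {detail}" if detail else ""))


@dataclass
class EPResult:
    """Gaussian approximation of the feasible region for one gene."""

    mean: np.ndarray
    sd: np.ndarray
    covariance: np.ndarray | None
    converged: bool
    iterations: int
    final_step: float
    offset_removed: bool = True

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)


def _tn_moments(m: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of N(m, v) truncated to [0, inf).

    Uses the scaled complementary error function for a stable hazard
    lam = phi(alpha)/Phi(alpha) at any alpha = m/sqrt(v).
    """
    s = np.sqrt(v)
    alpha = m / s
    lam = np.sqrt(2.0 / np.pi) / erfcx(-alpha / np.sqrt(2.0))
    mean = m + s * lam
    var = v * (1.0 - lam * (lam + alpha))
    return mean, np.maximum(var, 1e-300)


def _posterior(A: np.ndarray, b: np.ndarray, prior_prec: float,
               site_tau: np.ndarray, site_nu: np.ndarray, jitter_rel: float):
    """Marginals of N restricted to A x = b given diagonal precision sites."""
    p = prior_prec + site_tau
    su = 1.0 / p                       # unconstrained marginal variances
    h = site_nu * su                   # unconstrained mean
    ASu = A * su                       # m x n
    K = ASu @ A.T
    tr = np.trace(K)
    K[np.diag_indices_from(K)] += jitter_rel * max(tr / K.shape[0], 1e-30)
    cK = sla.cho_factor(K, lower=True, check_finite=False)
    w = sla.cho_solve(cK, b - A @ h, check_finite=False)
    mu = h + ASu.T @ w
    V = sla.cho_solve(cK, A, check_finite=False)       # K^-1 A
    sigma2 = su - su**2 * np.einsum("ij,ij->j", A, V)
    return mu, sigma2, su, cK, ASu


def ep_deconvolve(A, b, *, prior_scale: float = 100.0, offset: float = 1e-3,
                  damped: bool = True, max_iter: int = 200, tol: float = 1e-6,
                  keep_covariance: bool = True, total_expression: float | None = None,
                  seed: int | None = None) -> EPResult:
    """Approximate the feasible region {x >= 0 : A x = b} with a Gaussian.

    Parameters
    ----------
    prior_scale
        The prior on each (relative) cell expression is N(0, prior_scale *
        total), with the gene's total expression normalised to 1; default
        variance 100 x total.
    offset
        Added to each cell's relative expression before iteration (keeping
        the polytope interior non-empty) and subtracted from the returned
        mean.
    damped
        Use the step-halving variant that always returns a result; when
        False, numerical failures raise :class:`EPDivergenceError`.
    total_expression
        Override the gene total used for the relative scale.  By default the
        all-cells fraction measurement is used when the sort matrix carries
        one, otherwise sum(b)/rank(A).
    seed
        Accepted for interface uniformity; the algorithm is deterministic.

    Notes
    -----
    The returned mean may be slightly negative near zero — it is the mean of
    a Gaussian approximation, not a truncated point estimate.
    """
    sort = A if isinstance(A, SortMatrix) else None
    Aa = sort.A if sort is not None else np.atleast_2d(np.asarray(A, dtype=float))
    b = np.asarray(b, dtype=float)
    if b.shape != (Aa.shape[0],):
        raise ValueError(f"b has shape {b.shape}, expected ({Aa.shape[0]},)")
    if b.min() < 0:
        raise ValueError("fraction measurements must be non-negative")
    m, n = Aa.shape

    if total_expression is None:
        idx = sort.all_row_index() if sort is not None else None
        if idx is not None and b[idx] > 0:
            total = float(b[idx])
        else:
            rank = np.linalg.matrix_rank(Aa)
            total = float(b.sum() / max(rank, 1))
    else:
        total = float(total_expression)
    if total <= 0:
        total = 1.0

    b_work = b / total + offset * (Aa @ np.ones(n))
    prior_prec = 1.0 / prior_scale   # prior variance = prior_scale x (relative total 1)

    tau = np.zeros(n)
    nu = np.zeros(n)
    step = 1.0
    converged = False
    it = 0
    prev = (tau.copy(), nu.copy())

    for it in range(1, max_iter + 1):
        try:
            mu, sigma2, su, cK, ASu = _posterior(Aa, b_work, prior_prec, tau, nu, 1e-8)
        except np.linalg.LinAlgError as e:
            if not damped:
                raise EPDivergenceError(it, "posterior factorization failed") from e
            tau, nu = prev
            step *= 0.5
            if step < 1e-8:
                break
            continue
        bad = (~np.isfinite(sigma2)) | (sigma2 <= 0)
        prec_cav = np.where(bad, np.nan, 1.0 / np.maximum(sigma2, 1e-300) - tau)
        bad |= ~np.isfinite(prec_cav) | (prec_cav <= 1e-12)
        if bad.any():
            if not damped:
                raise EPDivergenceError(it, f"{int(bad.sum())} invalid cavity variance(s)")
            tau, nu = prev
            step *= 0.5
            if step < 1e-8:
                break
            continue
        v_cav = 1.0 / prec_cav
        m_cav = (mu / sigma2 - nu) * v_cav
        m_hat, v_hat = _tn_moments(m_cav, v_cav)
        tau_new = np.maximum(1.0 / v_hat - prec_cav, 0.0)  # log-concave site
        nu_new = m_hat / v_hat - m_cav * prec_cav
        d_tau = tau_new - tau
        d_nu = nu_new - nu
        if not (np.all(np.isfinite(d_tau)) and np.all(np.isfinite(d_nu))):
            if not damped:
                raise EPDivergenceError(it, "non-finite site update")
            tau, nu = prev
            step *= 0.5
            if step < 1e-8:
                break
            continue
        prev = (tau.copy(), nu.copy())
        tau = tau + step * d_tau
        nu = nu + step * d_nu
        # relative change: site precisions for boundary-pinned cells grow
        # without bound, so an absolute criterion would never trigger
        delta = max((np.abs(step * d_tau) / (1.0 + np.abs(tau))).max(initial=0.0),
                    (np.abs(step * d_nu) / (1.0 + np.abs(nu))).max(initial=0.0))
        if delta < tol:
            converged = True
            break

    mu, sigma2, su, cK, ASu = _posterior(Aa, b_work, prior_prec, tau, nu, 1e-8)
    sigma2 = np.maximum(sigma2, 0.0)
    cov = None
    if keep_covariance:
        cov = (np.diag(su) - ASu.T @ sla.cho_solve(cK, ASu, check_finite=False)) * total**2
        cov = (cov + cov.T) / 2

    mean = (mu - offset) * total
    sd = np.sqrt(sigma2) * total
    return EPResult(mean, sd, cov, converged, it, step)


def ep_group_summary(result: EPResult, mask: np.ndarray,
                     statistic: str = "total") -> tuple[float, float]:
    """Mean and sd of the total (or average) expression over a group of
    cells, propagating the full EP covariance: for the total,
    m = sum_i mu_i and v = 1' Sigma_group 1 over the masked cells.

    Group-level summaries are typically much narrower than per-cell
    marginals because strongly anticorrelated cells (low expression here vs
    high expression there) cancel in the sum.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    if result.covariance is None:
        raise ValueError("group summaries require keep_covariance=True")
    k = int(mask.sum())
    m = float(result.mean[mask].sum())
    v = float(result.covariance[np.ix_(mask, mask)].sum())
    if statistic == "average":
        m /= k
        v /= k**2
    elif statistic != "total":
        raise ValueError(f"unknown statistic {statistic!r}")
    return m, float(np.sqrt(max(v, 0.0)))
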