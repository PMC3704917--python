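"""Hit-and-run MCMC over the feasible polytope, with convergence diagnostics.

Uncertainty for the pseudoinverse estimators comes from sampling the
polytope {x >= 0 : A x = b} under a uniform model: every expression
pattern consistent with the measurements is equally plausible.  Each step
draws a uniformly random direction in the null space of A, intersects the
line through the current point with the non-negativity constraints, and
jumps to a uniform point on the resulting feasible segment — a random-
directions sampler guaranteed to mix on a convex body.

Cells estimated at zero by the constrained pseudoinverse are omitted from
sampling (their coordinates are pinned at zero); without this restriction
the sampler can be stuck on a face where no movement is possible.

Defaults mirror a production run (ten million burn-in and kept iterations,
thinning to every 1,000th draw); small problems mix well with far fewer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from .pinv import constrained_pseudoinverse
from .sort_model import SortMatrix

__all__ = ["SampleSummary", "sample_feasible", "potential_scale_reduction"]

OMIT_REL_THRESHOLD = 1e-8  # constrained-pinv estimate below this x max => omitted


@dataclass
class SampleSummary:
    """Moments of the uniform distribution on the feasible polytope."""

    mean: np.ndarray
    sd: np.ndarray
    n_kept: int
    omitted: np.ndarray               # cells pinned at zero
    rhat: np.ndarray | None = None    # per-cell potential scale reduction
    chains: np.ndarray | None = None  # (n_chains, n_kept_per_chain, n_cells)
    point_region: bool = False        # feasible set is a single point


def _hit_and_run_chain(N: np.ndarray, x0_active: np.ndarray, n_steps: int,
                       thin: int, n_burn: int, rng: np.random.Generator) -> np.ndarray:
    """Run one chain on the active coordinates; returns thinned post-burn-in
    draws (n_kept x n_active)."""
    k = N.shape[1]
    x = x0_active.copy()
    kept = []
    for step in range(1, n_burn + n_steps + 1):
        z = rng.standard_normal(k)
        d = N @ z
        nd = np.linalg.norm(d)
        if nd == 0:
            continue
        d /= nd
        moving = np.abs(d) > 1e-14
        if not moving.any():
            continue
        ratios = -x[moving] / d[moving]
        pos = d[moving] > 0
        lo = ratios[pos].max(initial=-np.inf)
        hi = ratios[~pos].min(initial=np.inf)
        if not np.isfinite(lo) or not np.isfinite(hi):
            raise RuntimeError("feasible region is unbounded along a sampled direction")
        if hi > lo:
            x = x + rng.uniform(lo, hi) * d
            np.maximum(x, 0.0, out=x)
        if step > n_burn and (step - n_burn) % thin == 0:
            kept.append(x.copy())
    return np.array(kept) if kept else np.empty((0, len(x)))


def sample_feasible(A, b, x0: np.ndarray | None = None, *,
                    n_burn: int = 10_000_000, n_iter: int = 10_000_000,
                    thin: int = 1000, n_chains: int = 1,
                    seed: int | None = None, keep_chains: bool = False,
                    omit: np.ndarray | None = None,
                    feas_tol: float = 1e-6) -> SampleSummary:
    """Sample {x >= 0 : A x = b} uniformly by hit-and-run.

    Parameters
    ----------
    x0
        Feasible starting point; defaults to the constrained pseudoinverse
        estimate.  Must satisfy the constraints within ``feas_tol``
        (relative to ||b||).
    omit
        Boolean mask of cells to pin at zero.  Defaults to cells whose
        constrained-pinv estimate is (relatively) zero.
    n_chains
        Independent chains from jittered starts; with >= 2 chains the
        per-cell Gelman-Rubin statistic is computed.
    """
    Aa = A.A if isinstance(A, SortMatrix) else np.atleast_2d(np.asarray(A, dtype=float))
    b = np.asarray(b, dtype=float)
    m, n = Aa.shape
    rng = np.random.default_rng(seed)

    if x0 is None:
        x0 = constrained_pseudoinverse(Aa, b).estimate
    x0 = np.asarray(x0, dtype=float)
    nb = np.linalg.norm(b)
    if np.linalg.norm(Aa @ x0 - b) > feas_tol * max(nb, 1.0) or x0.min() < -1e-10:
        raise ValueError("x0 is not feasible for A x = b, x >= 0")
    x0 = np.maximum(x0, 0.0)

    if omit is None:
        omit = x0 <= OMIT_REL_THRESHOLD * max(x0.max(), 1e-30)
    omit = np.asarray(omit, dtype=bool)
    active = ~omit

    N = null_space(Aa[:, active]) if active.any() else np.empty((0, 0))
    if N.size == 0 or N.shape[1] == 0:
        sd = np.zeros(n)
        return SampleSummary(x0.copy(), sd, 0, omit, point_region=True)

    per_chain = max(n_iter // thin, 1)
    chains = []
    for c in range(n_chains):
        start = x0[active].copy()
        if c > 0:  # diversify starts with a short prefix walk
            start = _hit_and_run_chain(N, start, 1, 1, 50, rng)
            start = start[-1] if len(start) else x0[active].copy()
        draws = _hit_and_run_chain(N, start, per_chain * thin, thin, n_burn, rng)
        chains.append(draws)
    kept = min(len(c) for c in chains)
    chains_arr = np.stack([c[:kept] for c in chains]) if kept else np.zeros((n_chains, 0, int(active.sum())))

    full = np.zeros((n_chains, kept, n))
    full[:, :, active] = chains_arr
    pooled = full.reshape(-1, n)
    mean = pooled.mean(axis=0) if len(pooled) else x0.copy()
    sd = pooled.std(axis=0, ddof=1) if len(pooled) > 1 else np.zeros(n)
    sd[omit] = 0.0
    mean[omit] = 0.0

    rhat = None
    if n_chains >= 2 and kept >= 2:
        rhat = np.full(n, np.nan)
        rhat_active = potential_scale_reduction(chains_arr)
        rhat[active] = rhat_active
    return SampleSummary(mean, sd, int(n_chains * kept), omit, rhat=rhat,
                         chains=full if keep_chains else None)


def potential_scale_reduction(chains: np.ndarray) -> np.ndarray:
    """Per-coordinate Gelman-Rubin potential scale reduction R-hat.

    ``chains`` has shape (n_chains, n_samples, n_coords) (a 2-D input is
    treated as a single coordinate).  R-hat compares the between-chain
    variance of the chain means with the mean within-chain variance,
    including the (n-1)/n finite-sample correction; values near 1 indicate
    the chains are sampling the same distribution.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    if chains.ndim != 3 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    n = chains.shape[1]
    chain_means = chains.mean(axis=1)                      # (chains, coords)
    W = chains.var(axis=1, ddof=1).mean(axis=0)            # within
    B_over_n = chain_means.var(axis=0, ddof=1)             # between / n
    var_plus = (n - 1) / n * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    rhat[(W == 0) & (B_over_n == 0)] = 1.0
    return rhat
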