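"""Synthetic expression patterns and the shrunken cell-cell correlation model.

Three synthetic families are used to benchmark deconvolution:

* lineage on/off patterns — one gene per qualifying sublineage (or per
  symmetric sublineage pair), "on" cells drawn from a bright distribution
  and "off" cells from a dim one, with a stored boolean truth mask;
* correlated patterns — multivariate normal draws whose covariance mimics
  the lineage-structured correlation of real expression data;
* a gamma-noise variant of the on/off patterns for non-normal noise.

All emitted expression is non-negative (negative draws are truncated to
zero, as a physical expression level cannot be negative).

On the default on/off parameterization: the bright ("on") distribution is
N(mean 10, variance 11) and the dim ("off") distribution N(mean 0,
variance 1), so that expressing cells outrank silent ones — the convention
every downstream AUC computation assumes.  The switch
``literal_paper_parameterization`` swaps the two for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lineage import LineageTree, SymmetryMap, sublineage_roots, symmetric_pair_sublineages

__all__ = [
    "ExpressionMatrix",
    "CorrelationModel",
    "truncate_negative",
    "shrunken_correlation",
    "simulate_correlated_patterns",
    "simulate_lineage_patterns",
    "perturb_expression_noise",
    "DEFAULT_ON_PARAMS",
    "DEFAULT_OFF_PARAMS",
]

# normal on/off defaults: (mean, variance)
DEFAULT_ON_PARAMS = (10.0, 11.0)
DEFAULT_OFF_PARAMS = (0.0, 1.0)


@dataclass
class ExpressionMatrix:
    """Genes x cells non-negative expression, with optional boolean truth
    masks for on/off designs (truth[g, j] marks cell j as expressing gene g).
    """

    X: np.ndarray
    gene_ids: list[str]
    cell_names: list[str]
    truth: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape != (len(self.gene_ids), len(self.cell_names)):
            raise ValueError("expression shape inconsistent with gene/cell labels")
        if self.X.size and self.X.min() < 0:
            raise ValueError("expression must be non-negative")
        if self.truth is not None:
            self.truth = np.atleast_2d(np.asarray(self.truth, dtype=bool))
            if self.truth.shape != self.X.shape:
                raise ValueError("truth mask shape must match expression")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.gene_ids, columns=self.cell_names)

    def truth_frame(self) -> pd.DataFrame:
        if self.truth is None:
            raise ValueError("this expression matrix has no truth masks")
        return pd.DataFrame(self.truth.astype(int), index=self.gene_ids,
                            columns=self.cell_names)


@dataclass
class CorrelationModel:
    """Shrunken cell-cell correlation: sigma = (1-lam) * Rhat + lam * I."""

    sigma: np.ndarray
    shrinkage: float

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = self.sigma.shape[0]
        if self.sigma.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")

    @property
    def n_cells(self) -> int:
        return self.sigma.shape[0]


def truncate_negative(X: np.ndarray) -> np.ndarray:
    """Elementwise max(x, 0): negative expression values are truncated."""
    return np.maximum(np.asarray(X, dtype=float), 0.0)


def shrunken_correlation(X, shrinkage: float = 0.05) -> CorrelationModel:
    """Shrunken estimate of the cell-cell correlation across genes.

    The sample correlation Rhat treats cells as variables and genes as
    observations; the returned matrix is the convex combination
    (1 - shrinkage) * Rhat + shrinkage * I, which is positive definite for
    any shrinkage > 0 when Rhat is rank-deficient only.  Cells with zero
    variance across genes get zero correlation with everything (diagonal 1)
    and a warning.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    mat = X.X if isinstance(X, ExpressionMatrix) else np.atleast_2d(np.asarray(X, float))
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 genes to estimate correlation")
    sd = mat.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} cell(s) have zero variance across "
                      "genes; their correlations are set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(mat, rowvar=False)
    R[~np.isfinite(R)] = 0.0
    np.fill_diagonal(R, 1.0)
    n = R.shape[0]
    sigma = (1.0 - shrinkage) * R + shrinkage * np.eye(n)
    return CorrelationModel(sigma, shrinkage)


def simulate_correlated_patterns(model: CorrelationModel, n_genes: int = 200,
                                 seed: int | None = None,
                                 cell_names: list[str] | None = None) -> ExpressionMatrix:
    """Draw expression patterns from MVN(0, sigma) and truncate negatives,
    producing random patterns whose cell-cell correlation structure mimics
    the model (default 200 synthetic genes)."""
    rng = np.random.default_rng(seed)
    w, V = np.linalg.eigh(model.sigma)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError(f"covariance is not PSD; eigenvalues range "
                         f"[{w.min():.3e}, {w.max():.3e}] — increase shrinkage")
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)  # sigma = L L^T
    Z = rng.standard_normal((n_genes, model.n_cells))
    X = truncate_negative(Z @ L.T)
    names = cell_names or [f"cell_{j}" for j in range(model.n_cells)]
    return ExpressionMatrix(X, [f"corr_{g:04d}" for g in range(n_genes)], names)


def _draw(shape_kind: str, params: tuple[float, float], size: int,
          rng: np.random.Generator) -> np.ndarray:
    if shape_kind == "normal":
        mean, var = params
        return rng.normal(mean, np.sqrt(var), size)
    if shape_kind == "gamma":
        shape, scale = params
        return rng.gamma(shape, scale, size)
    raise ValueError(f"unknown noise kind {shape_kind!r}")


def simulate_lineage_patterns(tree: LineageTree, sym: SymmetryMap | None = None,
                              mode: str = "one", min_cells: int = 5,
                              noise: str = "normal",
                              on_params: tuple[float, float] | None = None,
                              off_params: tuple[float, float] | None = None,
                              *,
                              literal_paper_parameterization: bool = False,
                              count_terminal_only: bool = False,
                              seed: int | None = None) -> ExpressionMatrix:
    """Lineage-blockwise on/off expression patterns.

    ``mode="one"`` emits one gene per sublineage with at least ``min_cells``
    cells; ``mode="two_symmetric"`` emits one gene per left-right symmetric
    sublineage pair where both sides qualify.  On-cells and off-cells are
    drawn i.i.d. from the two configured distributions (normal params are
    (mean, variance); gamma params are (shape, scale), off defaulting to
    Gamma(1, 1)); negatives are truncated to zero and the on-mask is stored
    as the gene's truth mask.
    """
    rng = np.random.default_rng(seed)
    if noise == "normal":
        on_p = on_params or DEFAULT_ON_PARAMS
        off_p = off_params or DEFAULT_OFF_PARAMS
        if literal_paper_parameterization:
            on_p, off_p = off_p, on_p
    elif noise == "gamma":
        on_p = on_params or (10.0, 1.0)
        off_p = off_params or (1.0, 1.0)
    else:
        raise ValueError(f"unknown noise kind {noise!r}")

    if mode == "one":
        roots = sublineage_roots(tree, min_cells, count_terminal_only=count_terminal_only)
        masks = [tree.subtree_mask(r) for r in roots]
        ids = [f"lin_{r}" for r in roots]
    elif mode == "two_symmetric":
        if sym is None:
            raise ValueError("mode='two_symmetric' requires a SymmetryMap")
        from .lineage import _qualifying
        ok = _qualifying(tree, min_cells, count_terminal_only)
        masks, ids = [], []
        for left, right in sym:
            if ok[tree.index[left]] and ok[tree.index[right]]:
                masks.append(tree.subtree_mask(left) | tree.subtree_mask(right))
                ids.append(f"pair_{left}_{right}")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n = tree.n_cells
    if not masks:
        warnings.warn("no qualifying sublineages; returning an empty expression matrix")
        return ExpressionMatrix(np.zeros((0, n)), [], list(tree.names),
                                truth=np.zeros((0, n), dtype=bool))
    X = np.empty((len(masks), n))
    truth = np.zeros((len(masks), n), dtype=bool)
    for g, mask in enumerate(masks):
        row = _draw(noise, off_p, n, rng)
        row[mask] = _draw(noise, on_p, int(mask.sum()), rng)
        X[g] = row
        truth[g] = mask
    return ExpressionMatrix(truncate_negative(X), ids, list(tree.names), truth=truth)


def perturb_expression_noise(X, s: float, seed: int | None = None) -> np.ndarray:
    """Multiplicative per-cell expression noise: each expression value is
    scaled by an independent N(1, s^2) draw (negatives truncated to zero).

    This emulates biological variability between embryos — the pattern an
    individual embryo actually expresses differs cell-by-cell from the
    consensus pattern — so fraction measurements taken on the noisy embryo
    remain internally consistent while the recovered pattern is scored
    against the consensus.
    """
    if s < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    arr = X.X if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    return truncate_negative(arr * rng.normal(1.0, s, size=arr.shape))
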