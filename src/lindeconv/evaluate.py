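"""Accuracy metrics, uncertainty calibration, resolution matrices, and the
benchmark harness for fraction-count and noise sweeps.

Two complementary accuracies are scored per gene: classification accuracy
of on/off calls via the area under the ROC curve (the probability that a
random expressing cell outranks a random non-expressing cell), and
quantitative accuracy via the Pearson correlation between the true and
deconvolved patterns.  The model resolution matrix A+ A describes which
cells a fraction design can distinguish: it approaches the identity as
linearly independent fractions are added, and off-diagonal blocks flag
cells whose estimates are blurred together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .ep import EPDivergenceError, ep_deconvolve
from .expression import (CorrelationModel, ExpressionMatrix,
                         perturb_expression_noise)
from .lineage import LineageTree
from .pinv import (PINV_RCOND, constrained_pseudoinverse, correlated_pseudoinverse,
                   naive_pseudoinverse)
from .sort_model import (SortMatrix, build_sort_matrix, perturb_drop_cells,
                         perturb_flip_lineage_entries, perturb_measurement_noise)

__all__ = [
    "DegenerateTruthError",
    "roc_auc",
    "pearson_accuracy",
    "Calibration",
    "calibration_z",
    "resolution_matrix",
    "expression_weighted_resolution",
    "run_benchmark",
    "summarize_benchmark",
    "compare_methods",
]


class DegenerateTruthError(ValueError):
    """Truth labels are all-positive or all-negative; AUC is undefined."""


def roc_auc(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mann-Whitney AUC (midrank tie handling) of predictions against
    boolean truth labels."""
    truth = np.asarray(truth, dtype=bool)
    pred = np.asarray(pred, dtype=float)
    if truth.all() or not truth.any():
        raise DegenerateTruthError("need at least one positive and one negative label")
    return float(roc_auc_score(truth, pred))


def pearson_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Pearson correlation between a deconvolved and a true pattern."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(pred, truth).statistic)


@dataclass
class Calibration:
    """Raw and reporting-clipped z-scores of truth against a prediction."""

    raw: np.ndarray
    clipped: np.ndarray


def calibration_z(truth: np.ndarray, mean: np.ndarray, sd: np.ndarray,
                  clip: float = 5.0) -> Calibration:
    """z = (truth - mean) / sd per cell, measuring how far the true value
    sits in the predictive distribution.  Cells with sd = 0 give z = 0 when
    the mean is exact and +/-inf (reported at +/-clip) otherwise; clipping
    affects only the ``clipped`` view."""
    truth = np.asarray(truth, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("sd must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (truth - mean) / sd
    exact = (sd == 0) & (truth == mean)
    z[exact] = 0.0
    return Calibration(z, np.clip(z, -clip, clip))


def resolution_matrix(A) -> np.ndarray:
    """Model resolution matrix R = A+ A: the orthogonal projector onto the
    row space of the sort matrix.  R = I exactly when A has full column
    rank; off-diagonal structure shows which cells are conflated."""
    Aa = A.A if isinstance(A, SortMatrix) else np.atleast_2d(np.asarray(A, dtype=float))
    return np.linalg.pinv(Aa, rcond=PINV_RCOND) @ Aa


def expression_weighted_resolution(R: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Resolution matrix with column j scaled by the expression x_j; dark
    off-diagonal blocks flag potentially conflated expression predictions
    for the particular gene."""
    R = np.asarray(R, dtype=float)
    x = np.asarray(x, dtype=float)
    if R.shape[1] != x.shape[0]:
        raise ValueError("dimension mismatch between R and x")
    return R * x[None, :]


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

_POINT_METHODS = {
    "naive": lambda A, b, **kw: naive_pseudoinverse(A, b).estimate,
    "constrained": lambda A, b, **kw: constrained_pseudoinverse(A, b).estimate,
}


def _deconvolve(method: str, A: SortMatrix, b: np.ndarray,
                correlation_model: CorrelationModel | None,
                ep_kwargs: dict) -> tuple[np.ndarray, bool]:
    """Returns (estimate, converged)."""
    if method in _POINT_METHODS:
        return _POINT_METHODS[method](A, b), True
    if method == "correlated":
        if correlation_model is None:
            raise ValueError("method 'correlated' needs a correlation_model")
        return correlated_pseudoinverse(A, b, correlation_model).estimate, True
    if method in ("ep", "ep-damped"):
        res = ep_deconvolve(A, b, damped=(method == "ep-damped"),
                            keep_covariance=False, **ep_kwargs)
        return res.mean, res.converged
    raise ValueError(f"unknown method {method!r}")


def _select_fractions(intensities: pd.DataFrame, order: list[str], count: int,
                      exclude: str | None, tree: LineageTree,
                      include_all: bool, binarize: bool) -> SortMatrix:
    chosen: list[str] = []
    for rep in order:
        if rep == exclude:
            continue  # leave-gene-out: replaced by the next reporter on the list
        chosen.append(rep)
        if len(chosen) == count:
            break
    return build_sort_matrix(intensities, chosen, include_all=include_all,
                             binarize=binarize, tree=tree)


def run_benchmark(tree: LineageTree, expression: ExpressionMatrix,
                  intensities: pd.DataFrame, fraction_order: list[str],
                  counts: list[int], methods: list[str] = ("naive",),
                  noise: dict | None = None, *,
                  include_all: bool = True, binarize: bool = False,
                  leave_gene_out: bool = True,
                  correlation_model: CorrelationModel | None = None,
                  ep_kwargs: dict | None = None,
                  auc_threshold: float | None = None,
                  seed: int | None = None) -> pd.DataFrame:
    """Score deconvolution methods per gene over fraction counts.

    For each (method, count): build the sort matrix from the first ``count``
    reporters of ``fraction_order`` (applying the leave-gene-out
    substitution when the evaluated gene is itself a sort marker), simulate
    fraction totals, optionally apply a noise perturbation, deconvolve each
    gene with the *unperturbed* matrix, and score AUC and Pearson r against
    the truth.

    ``noise`` is a dict: ``{"kind": "flip"|"drop", "n_entries": int}``
    perturbs the simulation sort matrix; ``{"kind": "measurement", "s": sd}``
    scales each fraction total by an N(1, s^2) draw;
    ``{"kind": "expression", "s": sd}`` scales each *per-cell* expression
    value before the fractions are measured (biological variability between
    individuals — the benchmark still scores against the consensus
    pattern).  AUC truth comes from the
    expression truth masks when present, else from thresholding the true
    pattern at ``auc_threshold`` (AUC is skipped when neither exists).

    Per-gene failures (EP divergence, degenerate truth) are logged in the
    returned long-format table, never aborting the sweep.
    """
    ep_kwargs = ep_kwargs or {}
    rng = np.random.default_rng(seed)
    rows = []
    noise_label = "none" if noise is None else "_".join(str(v) for v in noise.values())
    for count in counts:
        if count > len(fraction_order):
            raise ValueError(f"count {count} exceeds the {len(fraction_order)} "
                             "reporters in fraction_order")
        base_sort = _select_fractions(intensities, fraction_order, count, None,
                                      tree, include_all, binarize)
        for g in range(expression.n_genes):
            gene = expression.gene_ids[g]
            x_true = expression.X[g]
            sort = base_sort
            if leave_gene_out and gene in fraction_order[:count]:
                sort = _select_fractions(intensities, fraction_order, count, gene,
                                         tree, include_all, binarize)
            # simulate measurements with the (optionally perturbed) matrix,
            # deconvolve with the clean one
            sim_sort = sort
            gene_seed = int(rng.integers(2**31))
            if noise and noise["kind"] == "flip":
                sim_sort, _ = perturb_flip_lineage_entries(sort, tree,
                                                           noise["n_entries"], gene_seed)
            elif noise and noise["kind"] == "drop":
                sim_sort, _ = perturb_drop_cells(sort, tree, noise["n_entries"], gene_seed)
            x_sim = x_true
            if noise and noise["kind"] == "expression":
                x_sim = perturb_expression_noise(x_true, noise["s"], gene_seed)
            b = sim_sort.A @ x_sim
            if noise and noise["kind"] == "measurement":
                b = perturb_measurement_noise(b, noise["s"], gene_seed)

            for method in methods:
                rec = {"method": method, "n_fractions": count, "noise": noise_label,
                       "gene": gene, "auc": np.nan, "pearson": np.nan,
                       "converged": True, "failed": False}
                try:
                    est, conv = _deconvolve(method, sort, b, correlation_model, ep_kwargs)
                    rec["converged"] = conv
                    if expression.truth is not None:
                        labels = expression.truth[g]
                    elif auc_threshold is not None:
                        labels = x_true > auc_threshold
                    else:
                        labels = None
                    if labels is not None and labels.any() and not labels.all():
                        rec["auc"] = roc_auc(est, labels)
                    if np.ptp(est) > 0 and np.ptp(x_true) > 0:
                        rec["pearson"] = pearson_accuracy(est, x_true)
                except EPDivergenceError:
                    rec["failed"] = True
                    rec["converged"] = False
                rows.append(rec)
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Mean per-gene scores and failure counts per (method, count, noise)."""
    def _agg(g: pd.DataFrame) -> pd.Series:
        ok = g[~g["failed"]]
        return pd.Series({
            "mean_auc": ok["auc"].mean(),
            "mean_pearson": ok["pearson"].mean(),
            "n_failed": int(g["failed"].sum()),
            "n_genes": len(g),
        })
    grouped = table.groupby(["method", "n_fractions", "noise"], sort=True)
    return grouped.apply(_agg, include_groups=False).reset_index()


def compare_methods(table: pd.DataFrame, metric: str = "auc", alpha: float = 0.05,
                    n_tests: int | None = None) -> pd.DataFrame:
    """Pairwise paired t-tests between methods at each fraction count, with
    Bonferroni correction across ``n_tests`` comparisons (default: the
    number of comparisons actually run)."""
    from itertools import combinations
    out = []
    for count, sub in table[~table["failed"]].groupby("n_fractions"):
        pivot = sub.pivot_table(index="gene", columns="method", values=metric)
        pivot = pivot.dropna()
        for m1, m2 in combinations(pivot.columns, 2):
            t, p = stats.ttest_rel(pivot[m1], pivot[m2])
            out.append({"n_fractions": count, "method_a": m1, "method_b": m2,
                        "t": float(t), "p": float(p)})
    df = pd.DataFrame(out)
    if df.empty:
        return df
    k = n_tests if n_tests is not None else len(df)
    df["p_bonferroni"] = np.minimum(df["p"] * k, 1.0)
    df["significant"] = df["p_bonferroni"] < alpha
    return df
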