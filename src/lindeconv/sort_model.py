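"""Sort matrices and simulated fraction measurements.

A *fraction* is one FACS-purified population of cells defined by a
fluorescent reporter (cells expressing it, cells not expressing it, or all
cells).  The sort matrix A (fractions x cells) holds the probability that
each cell ends up in each fraction; measured expression of a gene in a
fraction is then the linear combination b = A x of its per-cell expression.

Reporter on/off calls come from a two-component logistic model of
background-subtracted fluorescence intensity: "off" cells have intensity
~ N(0, 1000^2) and "on" cells ~ N(2000, 1000^2) with equal class priors,
which yields probabilistic sort-matrix entries in (0, 1).

Three experimental-noise perturbations are provided: systematic sort errors
(flipping whole sublineage blocks of a fraction), loss of cells during
dissociation/sorting (zeroing sublineage columns in every fraction), and
multiplicative measurement noise on the fraction totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .lineage import LineageTree, sublineages

__all__ = [
    "Fraction",
    "SortMatrix",
    "FractionMeasurements",
    "OFF_MEAN", "ON_MEAN", "INTENSITY_SD",
    "intensity_to_on_probability",
    "build_sort_matrix",
    "binary_sort_matrix",
    "simulate_reporter_intensities",
    "simulate_measurements",
    "perturb_flip_lineage_entries",
    "perturb_drop_cells",
    "perturb_measurement_noise",
]

OFF_MEAN = 0.0
ON_MEAN = 2000.0
INTENSITY_SD = 1000.0


@dataclass(frozen=True)
class Fraction:
    """Metadata for one sort-matrix row."""
    reporter: str
    polarity: str  # "positive", "negative", or "all"

    def __post_init__(self):
        if self.polarity not in ("positive", "negative", "all"):
            raise ValueError(f"invalid polarity {self.polarity!r}")

    @property
    def label(self) -> str:
        if self.polarity == "all":
            return "all"
        sign = "+" if self.polarity == "positive" else "-"
        return f"{self.reporter}{sign}"


@dataclass
class SortMatrix:
    """Fractions x cells membership-probability matrix with row metadata."""

    A: np.ndarray
    fractions: list[Fraction]
    cell_names: list[str]

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise ValueError("A must be 2-D (fractions x cells)")
        if self.A.shape != (len(self.fractions), len(self.cell_names)):
            raise ValueError(
                f"shape {self.A.shape} inconsistent with {len(self.fractions)} "
                f"fractions x {len(self.cell_names)} cells")
        if np.any(~np.isfinite(self.A)) or self.A.min() < 0 or self.A.max() > 1:
            raise ValueError("sort-matrix entries must be finite and in [0, 1]")

    @property
    def n_fractions(self) -> int:
        return self.A.shape[0]

    @property
    def n_cells(self) -> int:
        return self.A.shape[1]

    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.fractions]

    def all_row_index(self) -> int | None:
        """Index of the all-cells fraction, if present."""
        for i, f in enumerate(self.fractions):
            if f.polarity == "all":
                return i
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.labels, columns=self.cell_names)


@dataclass
class FractionMeasurements:
    """Genes x fractions matrix of (simulated or observed) totals."""

    b: np.ndarray
    gene_ids: list[str]
    fraction_labels: list[str]

    def __post_init__(self):
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        if self.b.shape != (len(self.gene_ids), len(self.fraction_labels)):
            raise ValueError("measurement shape inconsistent with labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.b, index=self.gene_ids, columns=self.fraction_labels)


def intensity_to_on_probability(intensity) -> np.ndarray | float:
    """Posterior P(on | intensity) under the equal-prior two-Gaussian model.

    With equal variances the posterior is logistic in the intensity:
    log-odds = (mu_on - mu_off) * (x - (mu_on + mu_off)/2) / sigma^2.
    Strictly increasing; 0.5 at the midpoint intensity (1,000 a.u.).
    """
    x = np.asarray(intensity, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("intensities must be finite")
    logodds = (ON_MEAN - OFF_MEAN) * (x - 0.5 * (ON_MEAN + OFF_MEAN)) / INTENSITY_SD**2
    p = expit(logodds)
    return float(p) if np.isscalar(intensity) else p


def build_sort_matrix(intensities: pd.DataFrame,
                      reporters: list[str] | None = None,
                      *,
                      include_negative: bool = False,
                      include_all: bool = True,
                      binarize: bool = False,
                      tree: LineageTree | None = None) -> SortMatrix:
    """Build a sort matrix from a cells x reporters intensity table.

    Rows: an optional leading all-cells fraction, then per reporter a
    positive fraction of on-probabilities (optionally thresholded at 0.5
    when ``binarize``), and, when ``include_negative``, the complementary
    negative fraction 1 - p.

    If ``tree`` is given the intensity rows are aligned to its cell index;
    otherwise the table's row order defines the columns.
    """
    if reporters is None:
        reporters = list(intensities.columns)
    unknown = [r for r in reporters if r not in intensities.columns]
    if unknown:
        raise KeyError(f"unknown reporters: {unknown}")
    if tree is not None:
        missing = [n for n in tree.names if n not in intensities.index]
        if missing:
            raise ValueError(f"intensity table missing {len(missing)} cells, e.g. {missing[:5]}")
        intensities = intensities.loc[tree.names]
    cell_names = list(intensities.index)

    rows, meta = [], []
    if include_all:
        rows.append(np.ones(len(cell_names)))
        meta.append(Fraction("all", "all"))
    for rep in reporters:
        p = intensity_to_on_probability(intensities[rep].to_numpy())
        if binarize:
            p = (p >= 0.5).astype(float)
        rows.append(p)
        meta.append(Fraction(rep, "positive"))
        if include_negative:
            rows.append(1.0 - p)
            meta.append(Fraction(rep, "negative"))
    return SortMatrix(np.vstack(rows), meta, cell_names)


def binary_sort_matrix(patterns: np.ndarray, reporter_names: list[str],
                       cell_names: list[str], *,
                       include_negative: bool = False,
                       include_all: bool = True) -> SortMatrix:
    """Build a binary sort matrix directly from boolean reporter patterns
    (reporters x cells), bypassing the intensity model."""
    P = np.asarray(patterns, dtype=float)
    rows, meta = [], []
    if include_all:
        rows.append(np.ones(P.shape[1]))
        meta.append(Fraction("all", "all"))
    for name, row in zip(reporter_names, P):
        rows.append(row)
        meta.append(Fraction(name, "positive"))
        if include_negative:
            rows.append(1.0 - row)
            meta.append(Fraction(name, "negative"))
    return SortMatrix(np.vstack(rows), meta, cell_names)


def _reporter_masks(tree: LineageTree, n_reporters: int, rng: np.random.Generator,
                    max_sublineages: int, min_cells: int,
                    sym=None) -> np.ndarray:
    """Boolean on-masks (reporters x cells) for lineage-patterned reporters:
    each is the union of one to ``max_sublineages`` random sublineages, never
    covering the whole tree.  When a symmetry map is given the building
    blocks are symmetric sublineage *pairs* (expression in mirror-image body
    positions, as real reporters typically show)."""
    if sym is not None:
        from .lineage import symmetric_pair_sublineages
        masks = symmetric_pair_sublineages(tree, sym, min_cells)
    else:
        masks = sublineages(tree, min_cells)
    masks = [m for m in masks if not m.all()]
    if not masks:
        raise ValueError("no proper sublineages of the requested size")
    out = np.zeros((n_reporters, tree.n_cells), dtype=bool)
    for k in range(n_reporters):
        while True:
            n_lin = rng.integers(1, max_sublineages + 1)
            on = np.zeros(tree.n_cells, dtype=bool)
            for idx in rng.choice(len(masks), size=min(n_lin, len(masks)), replace=False):
                on |= masks[idx]
            if not on.all():
                break
        out[k] = on
    return out


def simulate_reporter_intensities(tree: LineageTree, n_reporters: int,
                                  seed: int | None = None,
                                  *,
                                  max_sublineages: int = 3,
                                  min_cells: int = 2) -> pd.DataFrame:
    """Simulate per-cell fluorescence for reporter strains whose expression
    is lineage-patterned: each reporter is "on" in the union of one to
    ``max_sublineages`` random sublineages (each with at least ``min_cells``
    cells), emulating lineage-traced reporter data.  Intensities are drawn
    from the bimodal model (off ~ N(0, 1000^2), on ~ N(2000, 1000^2)).

    Returns a cells x reporters table indexed by tree cell names.
    """
    rng = np.random.default_rng(seed)
    on = _reporter_masks(tree, n_reporters, rng, max_sublineages, min_cells)
    cols = {f"reporter_{k:03d}": rng.normal(np.where(on[k], ON_MEAN, OFF_MEAN),
                                            INTENSITY_SD)
            for k in range(n_reporters)}
    return pd.DataFrame(cols, index=tree.names)


def simulate_reporter_strains(tree: LineageTree, n_reporters: int,
                              seed: int | None = None,
                              *,
                              sym=None,
                              max_sublineages: int = 3,
                              min_cells: int = 5):
    """Simulate a panel of reporter strains together with their own
    expression patterns — the synthetic analogue of a measured reporter
    expression dataset, where the genes being deconvolved are the very
    reporters available as sort markers.

    Returns ``(intensities, expression)``: a cells x reporters fluorescence
    table (bimodal intensity model) and an :class:`ExpressionMatrix` whose
    gene ids equal the reporter names, with on-cells drawn from the bright
    on/off expression distribution and the reporter masks stored as truth.

    Pass the tree's symmetry map as ``sym`` to make each reporter's
    expression left-right symmetric (built from symmetric sublineage pairs),
    as real lineage-traced reporters typically are.
    """
    from .expression import (DEFAULT_OFF_PARAMS, DEFAULT_ON_PARAMS,
                             ExpressionMatrix, truncate_negative)
    rng = np.random.default_rng(seed)
    on = _reporter_masks(tree, n_reporters, rng, max_sublineages, min_cells, sym=sym)
    names = [f"reporter_{k:03d}" for k in range(n_reporters)]
    intens = pd.DataFrame(
        {names[k]: rng.normal(np.where(on[k], ON_MEAN, OFF_MEAN), INTENSITY_SD)
         for k in range(n_reporters)},
        index=tree.names)
    mu_on, var_on = DEFAULT_ON_PARAMS
    mu_off, var_off = DEFAULT_OFF_PARAMS
    X = rng.normal(mu_off, np.sqrt(var_off), on.shape)
    X[on] = rng.normal(mu_on, np.sqrt(var_on), int(on.sum()))
    expr = ExpressionMatrix(truncate_negative(X), names, list(tree.names), truth=on)
    return intens, expr


def simulate_measurements(sort: SortMatrix, X) -> FractionMeasurements:
    """Noise-free fraction totals b = A x for every gene (linear mixing)."""
    from .expression import ExpressionMatrix  # local import to avoid a cycle
    if isinstance(X, ExpressionMatrix):
        mat, gene_ids = X.X, list(X.gene_ids)
    else:
        mat = np.atleast_2d(np.asarray(X, dtype=float))
        gene_ids = [f"gene_{i}" for i in range(mat.shape[0])]
    if mat.shape[1] != sort.n_cells:
        raise ValueError(f"expression has {mat.shape[1]} cells, sort matrix {sort.n_cells}")
    return FractionMeasurements(mat @ sort.A.T, gene_ids, sort.labels)


# ---------------------------------------------------------------------------
# noise perturbations
# ---------------------------------------------------------------------------

def perturb_flip_lineage_entries(sort: SortMatrix, tree: LineageTree,
                                 n_entries: int, seed: int | None = None
                                 ) -> tuple[SortMatrix, int]:
    """Systematic sort error: repeatedly pick a random (fraction, sublineage)
    and replace each entry a in that block with 1 - a, until at least
    ``n_entries`` entries have been perturbed.  Returns the perturbed matrix
    and the number of entries actually flipped (counting repeats)."""
    if n_entries < 0:
        raise ValueError("n_entries must be >= 0")
    rng = np.random.default_rng(seed)
    A = sort.A.copy()
    masks = sublineages(tree, 1)
    flipped = 0
    while flipped < n_entries:
        i = rng.integers(sort.n_fractions)
        mask = masks[rng.integers(len(masks))]
        A[i, mask] = 1.0 - A[i, mask]
        flipped += int(mask.sum())
    return SortMatrix(A, list(sort.fractions), list(sort.cell_names)), flipped


def perturb_drop_cells(sort: SortMatrix, tree: LineageTree,
                       n_entries: int, seed: int | None = None
                       ) -> tuple[SortMatrix, int]:
    """Cell loss during dissociation/FACS: pick random sublineages and zero
    their columns in every fraction (including the all-cells row) until at
    least ``n_entries`` entries have been zeroed (dropped cells x fractions).
    Returns the perturbed matrix and the entry count."""
    if n_entries < 0:
        raise ValueError("n_entries must be >= 0")
    rng = np.random.default_rng(seed)
    A = sort.A.copy()
    masks = sublineages(tree, 1)
    dropped = np.zeros(sort.n_cells, dtype=bool)
    while dropped.sum() * sort.n_fractions < n_entries:
        dropped |= masks[rng.integers(len(masks))]
    A[:, dropped] = 0.0
    return SortMatrix(A, list(sort.fractions), list(sort.cell_names)), \
        int(dropped.sum()) * sort.n_fractions


def perturb_measurement_noise(measurements, s: float, seed: int | None = None):
    """Multiplicative measurement noise: each fraction total is multiplied by
    an independent N(1, s^2) draw; negative products are clamped to zero
    (fraction totals are physically non-negative)."""
    if s < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(measurements, FractionMeasurements):
        noisy = measurements.b * rng.normal(1.0, s, size=measurements.b.shape)
        return FractionMeasurements(np.maximum(noisy, 0.0),
                                    list(measurements.gene_ids),
                                    list(measurements.fraction_labels))
    arr = np.asarray(measurements, dtype=float)
    return np.maximum(arr * rng.normal(1.0, s, size=arr.shape), 0.0)
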