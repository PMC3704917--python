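"""Invariant cell-lineage trees.

The deconvolution model assumes an organism whose development follows an
invariant lineage: every individual executes the same pedigree of cell
divisions, so a cell is fully identified by its lineage history (for the
C. elegans embryo, 1,341 cells of which 671 are terminal).  This module
represents such pedigrees, enumerates sublineages (a cell plus all of its
descendants) and left-right symmetric sublineage pairs, and generates
synthetic mirrored trees so the full pipeline can run without external data.

Cells are ordered deterministically (depth-first from the root, children in
lexicographic name order); that order defines the columns of every sort
matrix and expression matrix downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LineageError",
    "LineageTree",
    "SymmetryMap",
    "load_lineage",
    "load_symmetry",
    "generate_synthetic_lineage",
    "sublineages",
    "sublineage_roots",
    "symmetric_pair_sublineages",
    "lineage_mask",
]


class LineageError(ValueError):
    """Structural problem in a lineage table (cycle, orphan, duplicate...)."""


@dataclass(frozen=True)
class SymmetryMap:
    """Pairs of sublineage roots occupying mirror-image body positions.

    Each pair ``(left_root, right_root)`` names two disjoint sublineages;
    for synthetic mirrored trees the two sides have identical topology.
    """

    pairs: tuple[tuple[str, str], ...]

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self):
        return len(self.pairs)


class LineageTree:
    """A rooted cell pedigree with a deterministic cell-to-column index.

    Parameters
    ----------
    records
        Iterable of ``(name, parent, terminal)`` tuples.  Exactly one record
        must have ``parent`` of ``None``/empty (the root).  Terminal cells
        are leaves of the pedigree; internal cells must have children.
    """

    def __init__(self, records: Iterable[tuple[str, str | None, bool]]):
        recs = [(str(n), (None if p in (None, "") or (isinstance(p, float) and np.isnan(p)) else str(p)), bool(t))
                for n, p, t in records]
        if not recs:
            raise LineageError("empty lineage table")
        names = [n for n, _, _ in recs]
        seen: set[str] = set()
        for n in names:
            if n in seen:
                raise LineageError(f"duplicate cell name {n!r}")
            seen.add(n)
        self._parent: dict[str, str | None] = {}
        self._terminal: dict[str, bool] = {}
        children: dict[str, list[str]] = {n: [] for n in names}
        roots = []
        for n, p, t in recs:
            self._parent[n] = p
            self._terminal[n] = t
            if p is None:
                roots.append(n)
            else:
                if p not in seen:
                    raise LineageError(f"cell {n!r} references unknown parent {p!r}")
                children[p].append(n)
        if len(roots) != 1:
            raise LineageError(f"expected exactly one root, found {len(roots)}: {roots[:5]}")
        self.root: str = roots[0]
        self._children = {n: sorted(c) for n, c in children.items()}

        # Depth-first index from the root; also detects unreachable cells,
        # which is how a cycle among non-root cells manifests.
        order: list[str] = []
        stack = [self.root]
        while stack:
            cell = stack.pop()
            order.append(cell)
            stack.extend(reversed(self._children[cell]))
        if len(order) != len(names):
            unreachable = sorted(set(names) - set(order))
            raise LineageError(
                f"{len(unreachable)} cell(s) unreachable from root "
                f"(cycle or detached subtree), e.g. {unreachable[:5]}")
        for n in names:
            if not self._terminal[n] and not self._children[n]:
                raise LineageError(f"internal (non-terminal) cell {n!r} has no children")

        self.names: list[str] = order
        self.index: dict[str, int] = {n: i for i, n in enumerate(order)}

    # -- basic queries ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.names)

    @property
    def n_terminal(self) -> int:
        return sum(self._terminal[n] for n in self.names)

    def parent(self, name: str) -> str | None:
        return self._parent[name]

    def children(self, name: str) -> list[str]:
        return self._children[name]

    def is_terminal(self, name: str) -> bool:
        return self._terminal[name]

    def __contains__(self, name: str) -> bool:
        return name in self.index

    def __len__(self) -> int:
        return len(self.names)

    # -- subtree machinery ------------------------------------------------
    def subtree_names(self, root_name: str) -> list[str]:
        if root_name not in self.index:
            raise LineageError(f"unknown cell {root_name!r}")
        out, stack = [], [root_name]
        while stack:
            c = stack.pop()
            out.append(c)
            stack.extend(self._children[c])
        return out

    def subtree_mask(self, root_name: str) -> np.ndarray:
        """Boolean mask over the cell index, true on the rooted sublineage."""
        mask = np.zeros(self.n_cells, dtype=bool)
        for c in self.subtree_names(root_name):
            mask[self.index[c]] = True
        return mask

    def subtree_sizes(self) -> np.ndarray:
        """Number of cells (root + internal + terminal) in every sublineage."""
        sizes = np.ones(self.n_cells, dtype=int)
        for name in reversed(self.names):  # reverse DFS: children before parents
            i = self.index[name]
            for c in self._children[name]:
                sizes[i] += sizes[self.index[c]]
        return sizes

    def terminal_counts(self) -> np.ndarray:
        """Number of terminal cells in every sublineage."""
        counts = np.array([1 if self._terminal[n] else 0 for n in self.names])
        for name in reversed(self.names):
            i = self.index[name]
            for c in self._children[name]:
                counts[i] += counts[self.index[c]]
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell": self.names,
            "parent": [self._parent[n] or "" for n in self.names],
            "terminal": [int(self._terminal[n]) for n in self.names],
        })


def load_lineage(source: str | Path | pd.DataFrame) -> LineageTree:
    """Read a lineage parent table (TSV columns ``cell``, ``parent``,
    ``terminal``; empty parent marks the root) into a :class:`LineageTree`.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t", dtype={"cell": str, "parent": str})
    missing = {"cell", "parent", "terminal"} - set(df.columns)
    if missing:
        raise LineageError(f"lineage table missing columns: {sorted(missing)}")
    return LineageTree(
        (row.cell, row.parent, bool(int(row.terminal)))
        for row in df.itertuples(index=False))


def load_symmetry(source: str | Path | pd.DataFrame) -> SymmetryMap:
    """Read a symmetry table (TSV columns ``left_root``, ``right_root``)."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t", dtype=str)
    missing = {"left_root", "right_root"} - set(df.columns)
    if missing:
        raise LineageError(f"symmetry table missing columns: {sorted(missing)}")
    return SymmetryMap(tuple((l, r) for l, r in zip(df["left_root"], df["right_root"])))


# ---------------------------------------------------------------------------
# synthetic trees
# ---------------------------------------------------------------------------

def _grow_side(prefix: str, n_leaves: int, depth_jitter: int, rng: np.random.Generator,
               records: list[tuple[str, str | None, bool]], parent: str) -> list[str]:
    """Recursively grow one body side; returns the relative suffixes of all
    nodes (used to mirror the other side).  Children are named with the
    Sulston-style anterior/posterior suffixes 'a' and 'p'."""
    records.append((prefix, parent, n_leaves == 1))
    suffixes = [""]
    if n_leaves == 1:
        return suffixes
    half = n_leaves // 2
    if depth_jitter > 0 and n_leaves > 2:
        half = int(np.clip(half + rng.integers(-depth_jitter, depth_jitter + 1), 1, n_leaves - 1))
    for child, k in (("a", half), ("p", n_leaves - half)):
        sub = _grow_side(prefix + child, k, depth_jitter, rng, records, prefix)
        suffixes.extend(child + s for s in sub)
    return suffixes


def generate_synthetic_lineage(n_leaf_pairs: int, depth_jitter: int = 0,
                               seed: int | None = None) -> tuple[LineageTree, SymmetryMap]:
    """Generate a mirrored binary lineage: two topologically identical
    subtrees ("L" and "R") hanging off the root "P0".

    With ``depth_jitter == 0`` each side is a balanced binary tree with
    ``n_leaf_pairs`` terminal cells (hence ``2*(2*n_leaf_pairs - 1) + 1``
    cells in total); positive jitter randomises the split sizes, producing
    trees of uneven depth while keeping the two sides mirror images.
    The symmetry map pairs every left-side cell with its mirror.
    """
    if n_leaf_pairs < 1:
        raise ValueError("n_leaf_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str | None, bool]] = [("P0", None, False)]
    left_records: list[tuple[str, str | None, bool]] = []
    suffixes = _grow_side("L", n_leaf_pairs, depth_jitter, rng, left_records, "P0")
    records.extend(left_records)
    # mirror: identical topology, names prefixed R
    for name, parent, term in left_records:
        records.append(("R" + name[1:], "P0" if parent == "P0" else "R" + parent[1:], term))
    tree = LineageTree(records)
    pairs = tuple(("L" + s, "R" + s) for s in suffixes)
    return tree, SymmetryMap(pairs)


# ---------------------------------------------------------------------------
# sublineage enumeration
# ---------------------------------------------------------------------------

def _qualifying(tree: LineageTree, min_cells: int, count_terminal_only: bool) -> np.ndarray:
    sizes = tree.terminal_counts() if count_terminal_only else tree.subtree_sizes()
    return sizes >= min_cells


def sublineage_roots(tree: LineageTree, min_cells: int = 1, *,
                     count_terminal_only: bool = False) -> list[str]:
    """Names of cells whose rooted sublineage contains >= ``min_cells`` cells
    (all cells by default; ``count_terminal_only`` switches the convention to
    counting terminal cells only), in tree-index order."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    ok = _qualifying(tree, min_cells, count_terminal_only)
    return [n for n in tree.names if ok[tree.index[n]]]


def sublineages(tree: LineageTree, min_cells: int = 1, *,
                count_terminal_only: bool = False) -> list[np.ndarray]:
    """One boolean cell-mask per sublineage with >= ``min_cells`` cells,
    ordered by tree index of the sublineage root."""
    return [tree.subtree_mask(r)
            for r in sublineage_roots(tree, min_cells, count_terminal_only=count_terminal_only)]


def symmetric_pair_sublineages(tree: LineageTree, sym: SymmetryMap, min_cells: int = 1, *,
                               count_terminal_only: bool = False) -> list[np.ndarray]:
    """One mask (union of both sides) per symmetric pair where each side's
    sublineage contains >= ``min_cells`` cells."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    ok = _qualifying(tree, min_cells, count_terminal_only)
    out = []
    for left, right in sym:
        for name in (left, right):
            if name not in tree.index:
                raise LineageError(f"symmetry pair references unknown cell {name!r}")
        if ok[tree.index[left]] and ok[tree.index[right]]:
            out.append(tree.subtree_mask(left) | tree.subtree_mask(right))
    return out


def lineage_mask(tree: LineageTree, root_name: str) -> np.ndarray:
    """Boolean mask true exactly on the sublineage rooted at ``root_name``."""
    return tree.subtree_mask(root_name)
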