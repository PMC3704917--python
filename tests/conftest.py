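"""Shared fixtures: small reference trees, the worked 5x16 example system,
and session-scoped benchmark setups reused by the slower end-to-end tests."""

import numpy as np
import pytest

import lindeconv as ld

# The worked example: an all-cells fraction plus four binary reporters over
# 16 cells, whose rows successively bisect the cell set.
FIG_ROWS = np.array([
    [1] * 16,
    [1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
    [1, 1, 1, 1, 0, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0, 0],
    [0, 0, 1, 1, 0, 0, 1, 1, 0, 0, 1, 1, 0, 0, 1, 1],
    [1, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0],
], dtype=float)


@pytest.fixture(scope="session")
def fig_system() -> np.ndarray:
    return FIG_ROWS.copy()


@pytest.fixture(scope="session")
def tree15():
    """Mirrored tree with 4 leaf pairs: 15 cells, 8 terminal."""
    tree, sym = ld.generate_synthetic_lineage(4, seed=0)
    return tree, sym


@pytest.fixture(scope="session")
def tree31():
    """Mirrored tree with 8 leaf pairs: 31 cells (two 15-cell sides)."""
    tree, sym = ld.generate_synthetic_lineage(8, seed=0)
    return tree, sym


@pytest.fixture(scope="session")
def bench255():
    """Scaled-down recovery benchmark: 255-cell mirrored lineage,
    one-lineage on/off patterns, 60 candidate reporters, greedy ordering."""
    tree, sym = ld.generate_synthetic_lineage(64, seed=11)
    expr = ld.simulate_lineage_patterns(tree, sym, mode="one", min_cells=5, seed=12)
    intens = ld.simulate_reporter_intensities(tree, 60, seed=13)
    ordering = ld.greedy_select(list(intens.columns), intens, tree, expr, k=50)
    return {"tree": tree, "sym": sym, "expr": expr, "intens": intens,
            "order": ordering.reporters, "ordering": ordering}


@pytest.fixture(scope="session")
def noise_bench1363():
    """Noise-robustness benchmark at the dimensions of the real embryonic
    lineage: 1,363-cell mirrored tree, 123 left-right symmetric reporter
    strains serving as both sort markers and evaluated genes, 30
    greedy-selected fractions."""
    tree, sym = ld.generate_synthetic_lineage(341, seed=11)
    intens, expr = ld.simulate_reporter_strains(tree, 123, seed=13, sym=sym)
    one_lin = ld.simulate_lineage_patterns(tree, sym, mode="one", min_cells=5, seed=12)
    ordering = ld.greedy_select(list(intens.columns), intens, tree, one_lin, k=30)
    return {"tree": tree, "sym": sym, "expr": expr, "intens": intens,
            "order": ordering.reporters}
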