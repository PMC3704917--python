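"""Sort-matrix construction, measurement simulation, noise perturbations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lindeconv as ld
from lindeconv.sort_model import SortMatrix, Fraction


def _binary_intensities(rows: np.ndarray, cell_names) -> pd.DataFrame:
    """Intensities that binarize cleanly: on cells at 2000, off at 0."""
    return pd.DataFrame(
        {f"rep{i}": np.where(rows[i] > 0, 2000.0, 0.0) for i in range(len(rows))},
        index=cell_names)


class TestOnProbability:
    def test_midpoint_is_half(self):
        assert ld.intensity_to_on_probability(1000.0) == pytest.approx(0.5)

    def test_density_ratio_values(self):
        # log-odds = (2000*x - 2e6) / 1e6
        assert ld.intensity_to_on_probability(2000.0) == pytest.approx(
            1 / (1 + np.exp(-2)), abs=1e-12)
        assert ld.intensity_to_on_probability(0.0) == pytest.approx(
            1 / (1 + np.exp(2)), abs=1e-12)

    def test_strictly_increasing_and_bounded(self):
        xs = np.linspace(-5000, 8000, 200)
        ps = ld.intensity_to_on_probability(xs)
        assert (np.diff(ps) > 0).all()
        assert ps.min() > 0 and ps.max() < 1

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ld.intensity_to_on_probability(np.nan)


class TestBuildSortMatrix:
    def test_reproduces_printed_example(self, fig_system):
        cells = [f"c{i:02d}" for i in range(16)]
        intens = _binary_intensities(fig_system[1:], cells)
        sort = ld.build_sort_matrix(intens, binarize=True)
        np.testing.assert_array_equal(sort.A, fig_system)
        assert sort.fractions[0].polarity == "all"
        assert all(f.polarity == "positive" for f in sort.fractions[1:])

    def test_uniform_intensity_gives_half(self):
        intens = pd.DataFrame({"r": np.full(6, 1000.0)}, index=list("abcdef"))
        sort = ld.build_sort_matrix(intens, include_all=False)
        np.testing.assert_allclose(sort.A[0], 0.5)

    def test_negative_row_is_complement(self):
        rng = np.random.default_rng(0)
        intens = pd.DataFrame({"r": rng.normal(1000, 800, 10)},
                              index=[f"c{i}" for i in range(10)])
        sort = ld.build_sort_matrix(intens, include_negative=True, include_all=False)
        np.testing.assert_allclose(sort.A[0] + sort.A[1], 1.0)
        assert sort.fractions[1].polarity == "negative"

    def test_unknown_reporter(self):
        intens = pd.DataFrame({"r": [0.0]}, index=["a"])
        with pytest.raises(KeyError):
            ld.build_sort_matrix(intens, ["ghost"])

    def test_tree_alignment_mismatch(self, tree15):
        tree, _ = tree15
        intens = pd.DataFrame({"r": [0.0, 1.0]}, index=["x", "y"])
        with pytest.raises(ValueError, match="missing"):
            ld.build_sort_matrix(intens, tree=tree)

    def test_entries_validated(self):
        with pytest.raises(ValueError):
            SortMatrix(np.array([[1.5]]), [Fraction("r", "positive")], ["a"])


class TestSimulateMeasurements:
    def test_identity_returns_expression(self):
        sort = ld.binary_sort_matrix(np.eye(4), [f"r{i}" for i in range(4)],
                                     list("abcd"), include_all=False)
        x = np.array([[3.0, 0.0, 1.0, 2.0]])
        meas = ld.simulate_measurements(sort, x)
        np.testing.assert_allclose(meas.b[0], x[0])

    def test_printed_system_single_cell(self, fig_system):
        cells = [f"c{i:02d}" for i in range(16)]
        sort = SortMatrix(fig_system, [Fraction("all", "all")] +
                          [Fraction(f"r{i}", "positive") for i in range(4)], cells)
        x = np.zeros(16)
        x[0] = 1.0  # the first cell
        meas = ld.simulate_measurements(sort, x[None, :])
        np.testing.assert_allclose(meas.b[0], [1, 1, 1, 0, 1])

    def test_zero_expression_zero_measurement(self, fig_system):
        sort = SortMatrix(fig_system, [Fraction("all", "all")] +
                          [Fraction(f"r{i}", "positive") for i in range(4)],
                          [f"c{i:02d}" for i in range(16)])
        meas = ld.simulate_measurements(sort, np.zeros((1, 16)))
        np.testing.assert_array_equal(meas.b, 0.0)

    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_linearity(self, seed, c):
        rng = np.random.default_rng(seed)
        A = rng.random((3, 6))
        sort = SortMatrix(A, [Fraction(f"r{i}", "positive") for i in range(3)],
                          [f"c{i}" for i in range(6)])
        x, y = rng.random(6), rng.random(6)
        bx = ld.simulate_measurements(sort, x[None]).b[0]
        by = ld.simulate_measurements(sort, y[None]).b[0]
        bxy = ld.simulate_measurements(sort, (x + y)[None]).b[0]
        bcx = ld.simulate_measurements(sort, (c * x)[None]).b[0]
        np.testing.assert_allclose(bxy, bx + by, atol=1e-12)
        np.testing.assert_allclose(bcx, c * bx, atol=1e-9)

    def test_single_cell_signatures_of_printed_system(self, fig_system):
        # noise-free b for a single-cell pattern IS the cell's fraction
        # signature, so two unit vectors are distinguishable exactly when
        # their signatures differ (brute force over all 16 x 16 pairs)
        for i in range(16):
            for j in range(16):
                bi, bj = fig_system[:, i], fig_system[:, j]
                same_sig = (bi == bj).all()
                assert np.array_equal(fig_system @ np.eye(16)[i], bi)
                assert same_sig == np.allclose(bi, bj)
        # the first cell's signature is unique, so its pattern is exactly
        # identifiable (the feasible set is a single point)
        sig0 = fig_system[:, 0]
        assert sum((fig_system[:, j] == sig0).all() for j in range(16)) == 1


@pytest.fixture()
def probabilistic_sort(tree15):
    tree, _ = tree15
    intens = ld.simulate_reporter_intensities(tree, 4, seed=5)
    return tree, ld.build_sort_matrix(intens, tree=tree)


class TestPerturbations:
    def test_flip_zero_entries_unchanged(self, probabilistic_sort):
        tree, sort = probabilistic_sort
        out, n = ld.perturb_flip_lineage_entries(sort, tree, 0, seed=1)
        np.testing.assert_array_equal(out.A, sort.A)
        assert n == 0

    def test_flip_is_involution(self, probabilistic_sort):
        # the same seed picks the same (fraction, sublineage) blocks, so
        # applying the perturbation twice restores the original entries
        tree, sort = probabilistic_sort
        once, n1 = ld.perturb_flip_lineage_entries(sort, tree, 10, seed=7)
        twice, n2 = ld.perturb_flip_lineage_entries(once, tree, 10, seed=7)
        assert n1 == n2
        np.testing.assert_allclose(twice.A, sort.A, atol=1e-12)

    def test_flip_binary_block_changes_only_block_entries(self, tree15):
        tree, _ = tree15
        rows = np.vstack([np.ones(15), np.zeros(15)])
        sort = ld.binary_sort_matrix(rows[1:2], ["r"], tree.names)
        out, n = ld.perturb_flip_lineage_entries(sort, tree, 1, seed=0)
        changed = (out.A != sort.A).sum()
        assert changed == n >= 1
        assert out.A.min() >= 0 and out.A.max() <= 1

    def test_flip_counts_reach_budget(self, probabilistic_sort):
        tree, sort = probabilistic_sort
        _, n = ld.perturb_flip_lineage_entries(sort, tree, 25, seed=3)
        assert n >= 25

    def test_drop_zero_unchanged(self, probabilistic_sort):
        tree, sort = probabilistic_sort
        out, n = ld.perturb_drop_cells(sort, tree, 0, seed=1)
        np.testing.assert_array_equal(out.A, sort.A)
        assert n == 0

    def test_drop_zeroes_whole_columns(self, probabilistic_sort):
        tree, sort = probabilistic_sort
        out, n = ld.perturb_drop_cells(sort, tree, 8, seed=2)
        dropped_cols = (out.A == 0).all(axis=0)
        assert n == dropped_cols.sum() * sort.n_fractions >= 8
        untouched = ~dropped_cols
        np.testing.assert_array_equal(out.A[:, untouched], sort.A[:, untouched])

    def test_measurement_noise_zero_sd_identity(self):
        b = np.array([[1.0, 2.0, 3.0]])
        out = ld.perturb_measurement_noise(b, 0.0, seed=0)
        np.testing.assert_array_equal(out, b)

    def test_measurement_noise_reproducible_and_nonnegative(self):
        b = np.full((5, 4), 2.0)
        a1 = ld.perturb_measurement_noise(b, 1.5, seed=9)
        a2 = ld.perturb_measurement_noise(b, 1.5, seed=9)
        np.testing.assert_array_equal(a1, a2)
        assert a1.min() >= 0

    def test_measurement_noise_is_mean_one_multiplicative(self):
        # empirical mean of b'/b over 1e5 draws ~ 1 within 3 standard errors
        # (s small enough that clamping at zero is negligible)
        b = np.ones((1, 100_000))
        s = 0.25
        out = ld.perturb_measurement_noise(b, s, seed=11)
        se = s / np.sqrt(b.size)
        assert abs(out.mean() - 1.0) < 3 * se


class TestReporterSimulation:
    def test_intensity_table_aligned_to_tree(self, tree15):
        tree, _ = tree15
        intens = ld.simulate_reporter_intensities(tree, 5, seed=1)
        assert list(intens.index) == tree.names
        assert intens.shape == (15, 5)

    def test_strains_share_masks_between_intensity_and_expression(self, tree15):
        tree, sym = tree15
        intens, expr = ld.simulate_reporter_strains(tree, 6, seed=2, sym=sym,
                                                    min_cells=2)
        assert list(expr.gene_ids) == list(intens.columns)
        # on-cells should be bright in intensity: check rank agreement
        for k, rep in enumerate(intens.columns):
            on = expr.truth[k]
            assert intens[rep].to_numpy()[on].mean() > intens[rep].to_numpy()[~on].mean()

    def test_symmetric_strains_have_mirror_symmetric_truth(self, tree31):
        tree, sym = tree31
        _, expr = ld.simulate_reporter_strains(tree, 8, seed=3, sym=sym, min_cells=2)
        mirror = {l: r for l, r in sym.pairs}
        for g in range(expr.n_genes):
            for left, right in mirror.items():
                li, ri = tree.index[left], tree.index[right]
                assert expr.truth[g, li] == expr.truth[g, ri]
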