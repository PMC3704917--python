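"""Accuracy metrics, calibration, resolution matrices, benchmark harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lindeconv as ld
from lindeconv.evaluate import DegenerateTruthError, summarize_benchmark


def brute_force_auc(pred, truth):
    """Pair-counting reference: concordant pairs + half the ties, over all
    (positive, negative) pairs."""
    pos = pred[truth]
    neg = pred[~truth]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert ld.roc_auc(np.array([3.0, 2.0, 1.0]),
                          np.array([True, True, False])) == 1.0

    def test_worked_three_point_example(self):
        # one concordant and one discordant positive-negative pair
        assert ld.roc_auc(np.array([0.9, 0.8, 0.3]),
                          np.array([True, False, True])) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.integers(0, 4, size=30).astype(float)  # ties guaranteed
        truth = rng.random(30) < 0.4
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        assert ld.roc_auc(pred, truth) == pytest.approx(
            brute_force_auc(pred, truth), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.normal(size=25)
        truth = rng.random(25) < 0.5
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        a1 = ld.roc_auc(pred, truth)
        a2 = ld.roc_auc(np.exp(2.0 * pred), truth)  # strictly monotone map
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_degenerate_truth_rejected(self):
        with pytest.raises(DegenerateTruthError):
            ld.roc_auc(np.array([1.0, 2.0]), np.array([True, True]))


class TestPearson:
    def test_identical_and_negated(self):
        x = np.array([1.0, 4.0, 2.0, 7.0])
        assert ld.pearson_accuracy(x, x) == pytest.approx(1.0)
        assert ld.pearson_accuracy(-x, x) == pytest.approx(-1.0)

    def test_three_point_closed_form(self):
        # r = 1 / sqrt(28/27) for (1,2,3) vs (1,2,4)
        r = ld.pearson_accuracy(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0]))
        assert r == pytest.approx(np.sqrt(27 / 28), abs=1e-10)
        assert r == pytest.approx(0.9820, abs=5e-5)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            ld.pearson_accuracy(np.ones(4), np.arange(4.0))


class TestCalibrationZ:
    def test_exact_and_two_sigma(self):
        cal = ld.calibration_z(np.array([1.0, 5.0]), np.array([1.0, 3.0]),
                               np.array([0.5, 1.0]))
        np.testing.assert_allclose(cal.raw, [0.0, 2.0])

    def test_zero_sd_cases(self):
        cal = ld.calibration_z(np.array([2.0, 3.0]), np.array([2.0, 2.0]),
                               np.array([0.0, 0.0]))
        assert cal.raw[0] == 0.0
        assert np.isinf(cal.raw[1])
        assert cal.clipped[1] == 5.0  # reported at the +/-5 boundary

    def test_clip_affects_reporting_only(self):
        cal = ld.calibration_z(np.array([100.0]), np.array([0.0]), np.array([1.0]))
        assert cal.raw[0] == 100.0
        assert cal.clipped[0] == 5.0


class TestResolutionMatrix:
    def test_full_rank_square_gives_identity(self):
        rng = np.random.default_rng(0)
        A = rng.random((5, 5)) + np.eye(5)
        np.testing.assert_allclose(ld.resolution_matrix(A), np.eye(5), atol=1e-8)

    def test_single_pooled_fraction(self):
        np.testing.assert_allclose(ld.resolution_matrix(np.array([[1.0, 1.0]])),
                                   [[0.5, 0.5], [0.5, 0.5]])

    @pytest.mark.parametrize("seed", range(5))
    def test_projector_properties(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.random((rng.integers(2, 6), rng.integers(4, 10)))
        R = ld.resolution_matrix(A)
        np.testing.assert_allclose(R, R.T, atol=1e-9)
        np.testing.assert_allclose(R @ R, R, atol=1e-9)
        eig = np.linalg.eigvalsh(R)
        assert np.all((np.abs(eig) < 1e-8) | (np.abs(eig - 1) < 1e-8))
        assert np.trace(R) == pytest.approx(np.linalg.matrix_rank(A), abs=1e-6)

    def test_expression_weighting(self):
        R = ld.resolution_matrix(np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]]))
        x = np.array([2.0, 0.0, 1.0])
        W = ld.expression_weighted_resolution(R, x)
        np.testing.assert_allclose(W, R * x[None, :])
        np.testing.assert_allclose(W.sum(axis=1), R @ x)
        e1 = np.zeros(3); e1[0] = 1.0
        W1 = ld.expression_weighted_resolution(R, e1)
        assert (W1[:, 1:] == 0).all()

    def test_resolution_approaches_identity_with_more_fractions(self, tree31):
        # adding linearly independent fractions moves the projector toward
        # the identity: ||R - I||_F = sqrt(n - rank A) for a projector
        tree, _ = tree31
        masks = np.array([m.astype(float) for m in ld.sublineages(tree, 1)])
        err = []
        for m in (8, 16, 31):
            R = ld.resolution_matrix(masks[:m])
            err.append(np.linalg.norm(R - np.eye(31)))
            assert err[-1] == pytest.approx(np.sqrt(31 - m), abs=1e-8)
        assert err[0] > err[1] > err[2]
        assert err[2] < 1e-8  # all 31 masks are linearly independent


@pytest.fixture(scope="module")
def small_setup():
    tree, sym = ld.generate_synthetic_lineage(8, seed=1)  # 31 cells
    expr = ld.simulate_lineage_patterns(tree, sym, min_cells=3, seed=2)
    intens = ld.simulate_reporter_intensities(tree, 12, seed=3)
    return tree, expr, intens, list(intens.columns)


class TestRunBenchmark:
    def test_full_rank_noise_free_recovers_exactly(self, tree31):
        # all 31 sublineage masks as binary fractions: fully determined
        tree, sym = tree31
        masks = np.array([m.astype(float) for m in ld.sublineages(tree, 1)])
        sort = ld.binary_sort_matrix(masks, [f"f{i}" for i in range(31)],
                                     tree.names, include_all=False)
        expr = ld.simulate_lineage_patterns(tree, sym, min_cells=3, seed=4)
        for g in range(expr.n_genes):
            est = ld.naive_pseudoinverse(sort, sort.A @ expr.X[g]).estimate
            np.testing.assert_allclose(est, expr.X[g], atol=1e-8)

    def test_per_gene_table_structure(self, small_setup):
        tree, expr, intens, order = small_setup
        table = ld.run_benchmark(tree, expr, intens, order, [4, 8],
                                 ["naive", "constrained"], seed=0)
        assert len(table) == expr.n_genes * 2 * 2
        assert set(table.method) == {"naive", "constrained"}
        summary = summarize_benchmark(table)
        assert len(summary) == 4
        assert (summary.n_failed == 0).all()

    def test_accuracy_improves_with_fraction_count(self, small_setup):
        tree, expr, intens, order = small_setup
        table = ld.run_benchmark(tree, expr, intens, order, [3, 12], ["naive"], seed=1)
        summary = summarize_benchmark(table).set_index("n_fractions")
        assert summary.loc[12, "mean_auc"] >= summary.loc[3, "mean_auc"] - 0.01

    def test_ep_failures_counted_not_fatal(self, small_setup, monkeypatch):
        tree, expr, intens, order = small_setup
        import lindeconv.evaluate as ev
        real = ev.ep_deconvolve
        calls = {"n": 0}

        def flaky(A, b, **kw):
            calls["n"] += 1
            if calls["n"] == 1:
                raise ld.EPDivergenceError(3)
            return real(A, b, **kw)

        monkeypatch.setattr(ev, "ep_deconvolve", flaky)
        table = ld.run_benchmark(tree, expr, intens, order, [6], ["ep"], seed=2)
        assert table.failed.sum() == 1
        summary = summarize_benchmark(table)
        assert summary.n_failed.iloc[0] == 1
        assert np.isfinite(summary.mean_auc.iloc[0])

    def test_leave_gene_out_substitutes_next_fraction(self, small_setup):
        tree, expr, intens, order = small_setup
        # rename the first gene to collide with the first reporter
        expr2 = ld.ExpressionMatrix(expr.X.copy(), list(expr.gene_ids),
                                    list(expr.cell_names), truth=expr.truth)
        expr2.gene_ids[0] = order[0]
        table = ld.run_benchmark(tree, expr2, intens, order, [4], ["naive"], seed=3)
        assert len(table) == expr.n_genes  # the gene is scored, not dropped

    def test_measurement_noise_degrades_accuracy(self, small_setup):
        tree, expr, intens, order = small_setup
        clean = ld.run_benchmark(tree, expr, intens, order, [10], ["naive"], seed=4)
        noisy = ld.run_benchmark(tree, expr, intens, order, [10], ["naive"],
                                 noise={"kind": "measurement", "s": 1.0}, seed=4)
        assert noisy.auc.mean() < clean.auc.mean()

    def test_compare_methods_bonferroni(self, small_setup):
        tree, expr, intens, order = small_setup
        table = ld.run_benchmark(tree, expr, intens, order, [6],
                                 ["naive", "constrained"], seed=5)
        cmp = ld.compare_methods(table, metric="pearson", n_tests=24)
        assert len(cmp) == 1
        assert (cmp.p_bonferroni >= cmp.p - 1e-12).all()
        assert (cmp.p_bonferroni <= 1.0).all()
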