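# lindeconv

Deconvolution of per-cell gene expression from genome-wide measurements on
overlapping, FACS-sorted cell populations defined on an invariant cell
lineage.

## The problem

In organisms with an invariant developmental lineage — the C. elegans
embryo, with its stereotyped pedigree of 1,341 cells (671 terminal), is the
canonical case — a fluorescent reporter whose expressing cells are known
from lineage tracing defines a sortable population ("fraction") whose exact
cellular composition is known in advance.  RNA-seq on m such fractions
measures, for every gene, the totals

```
b = A x ,   x ≥ 0
```

where `x` is the unknown expression of the gene in each of the n cells and
`A` (the *sort matrix*, m × n, entries in [0, 1]) says which cells are in
which fraction.  With far fewer fractions than cells the system is
underdetermined: the feasible expression patterns form a convex polytope
`{x ≥ 0 : Ax = b}`, and the job of this package is to pick good point
estimates from it, quantify how large it is, and tell you how many (and
which) fractions you need for a target resolution.

It is aimed at computational biologists planning or analysing
sorted-population expression experiments on organisms with known lineages,
and at anyone who needs careful tooling for non-negative underdetermined
linear inverse problems with uncertainty.

## What's inside

| Module | Contents |
| --- | --- |
| `lindeconv.lineage` | lineage trees, sublineage/symmetric-pair enumeration, synthetic mirrored trees |
| `lindeconv.sort_model` | logistic intensity → on-probability model, sort matrices, measurement simulation, sort-error / missing-cell / measurement-noise perturbations |
| `lindeconv.expression` | synthetic pattern generators (one-lineage, symmetric-pair, correlated-MVN, gamma variant), shrunken cell–cell correlation |
| `lindeconv.pinv` | naive / constrained / correlation-weighted pseudoinverse estimators |
| `lindeconv.ep` | expectation propagation over the feasible polytope (damped and undamped), lineage-group summaries |
| `lindeconv.sampling` | hit-and-run MCMC over the polytope, Gelman–Rubin R̂ |
| `lindeconv.evaluate` | AUC / Pearson scoring, z-score calibration, resolution matrices, benchmark harness |
| `lindeconv.selection` | greedy reporter ordering for experiment design |
| `lindeconv.cli` / `lindeconv.pipeline` | `lindeconv` command-line tool and YAML-configured end-to-end runs |

## Worked example

Fully synthetic, no data files needed: generate a 63-cell mirrored lineage,
simulate 30 lineage-patterned reporter strains, greedily pick 20 sort
fractions, and deconvolve one gene expressed in a single 7-cell sublineage.

```python
import lindeconv as ld

tree, sym = ld.generate_synthetic_lineage(16, seed=0)        # 63-cell lineage
expr = ld.simulate_lineage_patterns(tree, sym, mode="one", min_cells=5, seed=1)
intens = ld.simulate_reporter_intensities(tree, 30, seed=2)  # 30 reporter strains
order = ld.greedy_select(list(intens.columns), intens, tree, expr, k=20)
sort = ld.build_sort_matrix(intens, order.reporters, tree=tree)

gene = expr.gene_ids.index("lin_Laa")       # expression in one 7-cell sublineage
b = sort.A @ expr.X[gene]                   # noise-free fraction totals
res = ld.ep_deconvolve(sort, b)             # Gaussian posterior approximation

on = expr.truth[gene]
print(f"fractions used: {sort.n_fractions}   EP converged: {res.converged}")
print(f"classification AUC: {ld.roc_auc(res.mean, on):.3f}")
print(f"Pearson r vs truth: {ld.pearson_accuracy(res.mean, expr.X[gene]):.3f}")
m, s = ld.ep_group_summary(res, ld.lineage_mask(tree, "Laa"))
print(f"total expression in sublineage Laa: {m:.1f} +/- {s:.1f} "
      f"(simulated truth {expr.X[gene][on].sum():.1f})")
```

Output:

```
fractions used: 21   EP converged: True
classification AUC: 1.000
Pearson r vs truth: 0.984
total expression in sublineage Laa: 71.5 +/- 1.0 (simulated truth 73.1)
```

Reading it: with 21 fractions over 63 cells the on/off call is perfect
(AUC 1 — every expressing cell outranks every silent one), the quantitative
pattern correlates at r = 0.98, and the *sublineage-level* total carries a
tight error bar — summing the EP mean and covariance over a lineage cancels
the strong per-cell anticorrelations, which is how confident lineage-level
calls emerge from blurry per-cell ones.

The same flow is available from the shell:

```sh
lindeconv make-lineage --n-leaf-pairs 16 --seed 0 \
    --out-lineage lineage.tsv --out-symmetry symmetry.tsv
lindeconv make-expression --lineage lineage.tsv --min-cells 5 --out expr.tsv
lindeconv make-sortmatrix --lineage lineage.tsv --simulate-reporters 30 --out sort.tsv
lindeconv simulate-fractions --sort-matrix sort.tsv --expression expr.tsv --out meas.tsv
lindeconv deconvolve --sort-matrix sort.tsv --measurements meas.tsv \
    --method ep-damped --out est.tsv --out-sd sd.tsv
```

See `docs/methods.md` for the estimators, the synthetic-data models and all
numerical choices.

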