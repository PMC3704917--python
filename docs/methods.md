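# Methods

## The model

An invariant developmental lineage (the C. elegans embryo is the motivating
case: 1,341 cells, 671 of them terminal) lets overlapping cell populations be
defined at single-cell resolution: a fluorescent reporter whose expressing
cells are known from lineage tracing defines, via FACS, a *fraction* — a
purified population whose exact cellular composition is known.  Measuring a
gene's total expression in m such fractions gives

    A x = b,   x >= 0,

where x is the unknown per-cell expression (length n), b the fraction totals,
and A the m x n *sort matrix* of membership probabilities in [0, 1].  With
m << n the system is underdetermined; the solutions form a convex polytope
whose size expresses the residual uncertainty.

Sort-matrix entries come from a two-Gaussian logistic model of
background-subtracted reporter fluorescence: off-cells ~ N(0, 1000²) a.u.,
on-cells ~ N(2000, 1000²), equal priors, so
P(on | intensity) = logistic((μ₁−μ₀)(x − (μ₀+μ₁)/2)/σ²).  Entries may be
binarized at 0.5 for idealized designs.

## Estimators

* **Naive pseudoinverse** — x̂ = max(A⁺b, 0) with A⁺ the SVD pseudoinverse
  (relative singular-value cutoff 1e-10).  Truncation generally breaks
  A x̂ = b; the result records a `feasible` flag and the residual.
* **Constrained pseudoinverse** — the minimum-2-norm point of
  {x ≥ 0 : A x = b}; equivalently the ML estimate under x ~ N(0, I)
  restricted to the constraints.  Implemented as NNLS on the stacked system
  [wA; W] x ≈ [wb; 0] (penalty weight w = 1e6 on the equalities), followed by
  an exact KKT polish on the detected active set; when the equality system
  has no non-negative solution the NNLS fallback returns the non-negative
  least-squares minimizer (least objective-norm among minimizers) with
  `feasible=False`.  Verified against exhaustive active-set enumeration on
  all small instances.
* **Correlated pseudoinverse** — minimizes xᵀΣ⁻¹x under the same
  constraints, Σ a *shrunken correlation*: Σ = (1−λ)R̂ + λI with R̂ the
  sample cell-cell correlation across genes and λ = 0.05 by default.
* **Expectation propagation (EP)** — approximates the uniform distribution
  on the polytope with a Gaussian.  One univariate Gaussian site per cell
  represents the x_i ≥ 0 indicator; sites are updated in parallel each sweep
  by truncated-normal moment matching on their cavity distributions, and the
  Gaussian is conditioned exactly on A x = b (jitter 1e-8 x trace scale).
  The problem is solved on a relative scale (b divided by the gene's total,
  taken from the all-cells fraction, or Σb/rank(A) when absent); the prior on
  each relative expression is N(0, 100 x total), and an offset of 1e-3 is
  added to every cell before iteration and subtracted from the returned mean,
  keeping the polytope interior non-empty.  Convergence: maximum *relative*
  natural-parameter change < 1e-6 (default), at most 200 sweeps — relative,
  because site precisions of boundary-pinned cells grow without bound while
  the posterior moments are long since stationary.  The
  *damped* variant halves its step size on any numerically invalid update and
  always returns a result; the undamped variant raises a divergence error
  naming the sweep.  Cavity precisions are floored at 1e-12; site precisions
  are clipped non-negative (valid because the truncation factor is
  log-concave).
* **Hit-and-run sampling** — uncertainty for the pseudoinverse estimators.
  Each step draws a uniformly random direction in the null space of A
  (precomputed once by SVD), intersects the line with x ≥ 0, and jumps to a
  uniform point of the feasible segment.  Cells at zero in the constrained
  estimate (below 1e-8 of the maximum) are pinned at zero, since on that
  face no movement is possible.  Defaults mirror a production run (1e7
  burn-in, 1e7 iterations, thinning 1000); tests and the bundled experiments
  use 1e4–1e5-scale chains, which mix well on small polytopes.  Convergence
  is monitored by the Gelman-Rubin potential scale reduction
  R̂ = sqrt(((n−1)/n W + B/n)/W) across ≥ 2 chains.

Group-level summaries (total or average expression over a sublineage)
propagate the full EP covariance: strongly anticorrelated cells cancel in
the sum, so lineage-level calls are much sharper than per-cell marginals.

## Experiment design

The *resolution matrix* R = A⁺A (an orthogonal projector; ‖R − I‖_F =
sqrt(n − rank A)) shows which cells a fraction design conflates; weighting
its columns by an expression pattern highlights the conflations that matter
for a particular gene.  `greedy_select` orders candidate reporters by
repeatedly adding the one that most improves mean Pearson correlation of
(by default naive-pseudoinverse) deconvolution over an evaluation pattern
set, starting from the all-cells baseline fraction; ties keep the earlier
candidate, making the ordering deterministic.

## Synthetic data

The generators emulate the study conditions end to end with no external
data:

* **Lineage** — two mirror-image binary subtrees under a common root;
  `n_leaf_pairs` terminal-cell pairs (jitter randomizes split sizes without
  changing counts).  Cell order is depth-first with lexicographic children,
  fixing sort-matrix columns.
* **One-lineage / two-symmetric-lineage patterns** — one gene per sublineage
  (or symmetric sublineage pair) with ≥ 5 cells; on-cells ~ N(10, 11),
  off-cells ~ N(0, 1), negatives truncated to zero, truth masks stored.
  (A `literal_paper_parameterization` switch swaps the two distributions;
  the default keeps expressing cells brighter, the convention every AUC
  assumes.)  A gamma variant uses off ~ Gamma(1, 1) with a configurable
  on-distribution.
* **Correlated patterns** — MVN(0, Σ) draws (truncated at zero) from a
  shrunken correlation model, mimicking patterns with realistic cell-cell
  correlation; 200 genes by default.
* **Reporter strains** — per-cell fluorescence from the bimodal intensity
  model for reporters expressed in unions of 1–3 random sublineages;
  `simulate_reporter_strains` additionally emits the reporters' own
  expression patterns so the measured-reporter benchmark design (the genes
  being deconvolved are the sort markers themselves, with the leave-gene-out
  substitution) can be reproduced.  With a symmetry map the building blocks
  are symmetric sublineage pairs, reflecting the left-right symmetric
  expression typical of real reporters.

What the generators do **not** model: RNA-seq count noise (negative
binomial), amplification bias, temporal dynamics, FACS gating physics,
doublets.  Passing benchmarks therefore demonstrate correctness of the
inference machinery under the stated noise models, not performance on any
particular real dataset.

## Noise models

Three perturbations probe robustness (simulation uses the perturbed inputs,
deconvolution the clean sort matrix):

* **Systematic sort error** — random (fraction, sublineage) blocks have
  entries α replaced by 1−α until a budget of entries is perturbed.
* **Missing cells** — random sublineages zeroed in *all* fractions.
* **Expression noise** — every per-cell expression value multiplied by an
  independent N(1, s²) draw before fractions are measured (biological
  variability between individuals; predictions are scored against the
  consensus pattern).  A measurement-level variant multiplying the fraction
  totals themselves is also provided (`perturb_measurement_noise`, negatives
  clamped at zero); it is far more destructive, since errors on totals
  cannot be reconciled with any single underlying pattern.

## Benchmark scales

The bundled experiments run on one CPU in minutes: parameter-recovery
sweeps use a 255-cell mirrored lineage (one-lineage patterns, 30–50
greedy-selected fractions); noise robustness uses a 1,363-cell lineage —
the generator's closest size to the real embryonic lineage — with 123
symmetric reporter strains evaluated as genes, preserving the
fraction-to-cell ratio that governs how sharply the design localizes
expression.  That ratio matters: with missing-cell noise, a high-resolution
design correctly pushes dropped cells to the bottom ranks (an unavoidable
AUC cost), while at realistic blur a dropped cell's estimate is supported
by its indistinguishable neighbours — notably its left-right mirror — and
accuracy degrades much less.

## Numerical choices and degenerate inputs

* Pseudoinverse rank cutoff 1e-10 (relative); feasibility tolerance
  1e-6·‖b‖.
* Truncated-normal moments via the scaled complementary error function
  (stable for any cavity z-score).
* Genes whose truth labels are degenerate (all on / all off) are skipped in
  AUC scoring; constant vectors are skipped in Pearson scoring; EP
  divergences are counted per gene (`n_failed`) without aborting a sweep.
* Zero-variance cells get zero correlation (diagonal 1) in the shrunken
  estimator, with a warning.
* `calibration_z` reports sd = 0 cells as z = 0 when exact and ±clip
  (default 5) otherwise, keeping raw values alongside the clipped view.

## Known limitations

* The undamped EP variant is, in this implementation, stable on every
  problem we generate (its divergence path is exercised only synthetically);
  the damped variant exists for parity and for pathological inputs.
* Hit-and-run requires a bounded polytope (an all-cells or equivalent
  pooled fraction guarantees this); unbounded directions raise an error.
* The correlated pseudoinverse needs a strictly positive-definite Σ —
  use shrinkage > 0.
* Greedy selection is a heuristic: its objective trace need not be
  monotone, and no optimality guarantee is claimed.
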