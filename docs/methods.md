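# Methods

This note records the modelling assumptions, numerical choices and open
design decisions behind `netimpute`, in the order the pipeline runs.

## Scales and centering

Matrices are genes × cells throughout. Counts are normalized to one million
per cell (RPM-style), log2-transformed with a pseudocount of 1 (so zeros
stay exactly zero), and centered gene-wise. The centers are plain row means
over **all** cells, zeros included; they are stored and added back after
imputation. Whether the original procedure's centers included zero entries
is ambiguous; including them is the literal reading of "across all cells"
and is distinct, deliberately, from the Baseline imputer's detected-only
mean. Re-centered values below 0 are clamped to 0 (log2 of non-negative
expression cannot be negative); clamping is the only lossy step and only
affects imputed entries. Post-imputation values are no longer guaranteed to
sum to the same total per cell; re-normalization is left to the caller.

## Network training (`network_inference`)

Each gene is an independent regression problem: its deviation on the
deviations of all other genes (plus, optionally, its own copy-number state,
which enters the candidate pool like any predictor but is never used at
imputation time). Selection is stability selection over LASSO:

* **Subsampling** — complementary pairs: 50 random splits of the samples
  into two disjoint halves give `n_subsamples = 100` half-samples.
* **Per-subsample selection** — predictors are standardized within the
  half-sample and the first `q` variables to enter the LARS–LASSO path are
  counted as selected. Truncating the path at `q` entries is the exact
  "smallest λ with ≤ q active variables" rule, computed without a λ grid.
* **Budget `q`** — default `max(ceil(sqrt(pfer·(2·cutoff−1)·p)), ceil(sqrt(p)))`.
  The first term is the Meinshausen–Bühlmann per-family-error bound solved
  for `q`; at small candidate pools (p ≈ 100) it degenerates to q ≤ 1,
  which cannot express targets with several true predictors, so a √p floor
  is applied. The implied error bound `q²/((2·cutoff−1)p)` is reported by
  `StabilityParams.pfer_bound`; under the global null the realized false
  selection rate is far below it (≈ 0.1 predictors/target at p = 100,
  n = 200).
* **Thresholding** — selection frequency ≥ `cutoff` (default 0.6) defines
  the stable support; per-family error rate default 0.05.
* **Refit and pruning** — coefficients are re-estimated by OLS on the
  unstandardized deviations (no intercept: the data are centered), so
  stored coefficients act directly on deviations. Because `q` can exceed a
  target's true in-degree, the stable support can contain redundant proxies
  — variables correlated with the target only through shared predictors;
  their partial coefficients given the real predictors are ≈ 0. Backward
  elimination at two-sided level `prune_alpha = 1e-3` removes them; set
  `prune_alpha=None` for the plain refit. An optional randomized-LASSO
  weight (`weakness` < 1) is available but off by default — in our tests it
  did not reduce proxy selection, whereas pruning did.

Zero-variance targets yield empty models rather than errors. Training is
embarrassingly parallel over targets; per-target RNG streams are spawned
from the global seed, so results are bit-reproducible.

`randomize_network` re-draws predictor identities (all edges, or a
fraction) while keeping coefficients and per-target edge counts — the
negative control for "does the network's wiring matter?".

## Imputation solvers (`network_imputation`)

"Unmeasured" means exactly-zero in the input; no attempt is made to
distinguish technical dropouts from biological zeros (a boolean-mask hook
can exempt entries). Per cell, the unmeasured genes with at least one model
predictor form the solve set; the system (I − Aⁿ)·Yⁿ = F is solved by

* **pseudoinverse** — `numpy.linalg.pinv` with relative singular-value
  cutoff `max(dim)·eps` by default (exposed as `pinv_rcond`); defined even
  when I − Aⁿ is singular, returning the minimum-norm least-squares
  solution; or
* **iterative** — Y⁽¹⁾ = F (measured predictors only), then
  Y⁽ᵏ⁾ = Aⁿ·Y⁽ᵏ⁻¹⁾ + F, stopping when the maximum absolute change drops
  below `tolerance` (default 1e-4) or after `max_iterations` (default 50)
  rounds. The cap is part of the method contract; the last iterate is
  returned even if unconverged, with a flag rather than an exception. The
  reported iteration count is the round at which the returned value was
  first attained. The update re-predicts **all** unmeasured genes each
  round (genes without dropout predictors are fixed points of the update,
  so this coincides with only re-predicting genes with dropout predictors
  at convergence).

When every per-cell Aⁿ has spectral radius < 1 the two solvers agree to
solver tolerance; this is verified against an independent dense
`numpy.linalg.solve` oracle in the acceptance checks. Unmeasured genes with
no (nonempty) model keep their zeros; unmeasured genes whose predictors
contribute nothing are imputed at their center.

## Baseline (`baseline_imputation`)

Zeros are replaced by the gene's mean over cells where it was detected
(nonzero), computed on the matrix as given — in benchmarks, the masked
matrix, never side information. Genes never detected stay zero. Filling
with a constant can only shrink per-gene variance, and it is exactly
optimal for genes whose expression does not vary across cells.

## Masking (`masking`)

* **Uniform per gene** — exactly `floor(fraction · n_quantified)` entries
  per gene, drawn uniformly without replacement (floor makes benchmark
  sparsity reproducible; the reference settings are 35% for
  hESC/Smart-seq3-like data, 8–10% for sparser droplet data). A per-cell
  variant swaps the roles of genes and cells (30% in the reference
  setting).
* **Model-based** — a cubic smoothing spline (`scipy`'s least-squares
  spline) of per-gene zero-fraction on per-gene mean log2 expression, knots
  at the interior deciles (10%…90%) of the mean-expression distribution,
  duplicate abscissae averaged, linear extrapolation beyond the data range,
  predictions clamped to [0, 1]. Each quantified entry of gene *g* is then
  masked by an independent Bernoulli draw at the gene's predicted dropout
  probability. Whether the original fit used log or linear mean expression
  is unstated; log2 is used here.

Per-gene (per-cell) RNG substreams are keyed by the identifier, not the row
position, so masks are independent of gene order. Structural zeros are
never masked, and `masked + coords` reconstructs the original exactly.

## Evaluation (`evaluation`)

All scoring is restricted to masked coordinates imputed with a nonzero
value by **every** compared method (the common set). Per gene:

* **Pearson r** between original and imputed values, requiring ≥ 10 common
  entries and non-constant values on both sides (the constancy test is
  relative, std ≤ 1e-12·scale, because an imputed constant row can carry
  float noise). Ineligible genes are absent, not zero-filled.
* **MSE** — mean squared imputation error, any gene with ≥ 1 entry.
* **Expression quartiles** of per-gene mean expression, computed on the
  masked matrix, Q1 lowest, ties broken by gene order.
* **Top performers** — within 0.1 of the best correlation, or within 5% of
  the per-gene MSE range of the best; genes where all methods qualify are
  background-only.

## Per-gene selection and ensemble (`ensemble`)

`split_cells` holds out 30% of cells (70% train); datasets under 150 cells
train on 98% so enough masked entries remain per gene (the reference used
98% for a ~100-cell dataset; the 150 threshold is this package's choice,
exposed as a parameter). The training split is masked (uniform per-gene),
every registered method imputes it, and each gene is assigned the method
with the highest per-gene correlation on the common entries. Exact ties
break by priority Network > other adapters in registration order >
Baseline; genes with no usable correlation default to Baseline. The final
imputation re-runs the needed methods on the full matrix and takes each
gene's row from its assigned method (re-running on the full matrix, rather
than reusing training-split imputations, is the cleaner contract; the
held-out cells are available for reporting generalization). External tools
plug in through `MethodAdapter` (same-shape in/out contract); a failing
adapter is dropped with a warning, never an abort.

## Synthetic data (`synthetic_data`)

The generator reproduces the structure the model assumes, with defaults
chosen as a realistic, learnable regime: 100 genes, 300 bulk samples, 200
cells, edge density 0.05, coefficient magnitudes 0.5–1.5 with random sign,
model-error sd 0.3, per-gene means uniform on 1–8 log2 units, logistic
dropout (midpoint 3, slope 1 — ≈ 30% dropout overall, concentrated on
lowly expressed genes). Two topologies:

* `tf_target` (default) — a layered regulator→target topology: the first
  30% of genes are upstream regulators with outgoing edges only. The
  adjacency is nilpotent, so the system is always stable, coefficients keep
  their drawn magnitudes, and a target's optimal predictor set is exactly
  its parents — the regime in which support recovery is statistically
  identifiable. Parentless genes get innovation sd `source_sd = 1.0`
  (their variation is driven from outside the modeled system); regulated
  genes keep `noise_sd = 0.3` as the model error.
* `random` — Erdős–Rényi wiring with feedback allowed, rescaled to spectral
  radius ≤ 0.8. Used for solver stress tests, where cycles and
  near-singular per-cell systems are the point. Note that under feedback
  the regression oracle is the Markov blanket (parents, children,
  co-parents), not the directed parent set, so edge recovery against the
  generating adjacency is not a meaningful benchmark in this mode.

Bulk deviations are exact draws Y = (I − A)⁻¹ε; single cells add per-gene
means and clamp at 0 (with the default mean range ≈ 2% of truth entries
clamp; they behave as structural zeros). A `constant_fraction` of genes is
made flat — zero deviation, incoming edges ignored during simulation but
retained in the returned network — giving genes for which network
imputation is deliberately mis-specified and the Baseline is optimal. The
dropout generator is logistic precisely so that the cubic-spline dropout
model in `masking` is tested against an independent functional form.

What the generator does **not** emulate: count noise (no Poisson/NB layer;
truth lives directly on the log2 scale), batch effects, doublets, cell
subpopulations, and realistic library-size variation. Passing benchmarks on
this generator therefore demonstrates correctness of the algebra, the
selection machinery and the comparative logic — not performance on any
particular real dataset.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run: solver agreement on 20
random recurrent networks (200 genes × 50 cells each); network recovery on
3 seeds of the default 100-gene/300-sample configuration; the null control
on 20 targets at 100 genes × 200 samples; and the masking benchmark on 3
seeds of 100 genes × 200 cells with half constant genes. These sizes keep a
full run around two minutes on one CPU while leaving all comparisons
well-powered.

## Known limitations

* Technical dropouts are equated with exact zeros; a measured-but-low value
  is never revisited, and biological zeros are imputed if the network can
  reach them (use the mask hook to exempt entries).
* Gene-wise centers are computed on the observed (dropout-laden) matrix, so
  centers of high-dropout genes are biased low; this cancels in per-gene
  correlation but not in MSE, and varying measured-predictor sets propagate
  that bias cell-dependently — visible as the Network method's weaker MSE
  on sparse genes.
* The stability-selection error bound is loose at small p; interpret
  `pfer_bound` as a ceiling, not an estimate.
* The iterative solver's 50-iteration default cap can return unconverged
  values for near-unstable per-cell systems; check `ImputationStats`.
* Training assumes the bulk data's gene–gene relationships transfer to the
  cells being imputed; a mismatched network degrades gracefully toward the
  randomized-network control, but nothing in the package detects the
  mismatch.
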