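# netimpute

Regulatory-network-based dropout imputation for single-cell RNA-seq, with
masking benchmarks and per-gene adaptive method selection.

## The problem

Single-cell RNA sequencing misses many genes that are actually expressed:
incomplete RNA capture records them as zeros ("dropouts"), and lowly
expressed genes — including many transcriptional regulators — are hit
hardest. Most imputation methods estimate missing values from the dataset at
hand, by averaging over transcriptomically similar cells. That fails exactly
where imputation matters most: genes detected in few cells, datasets with
few similar cells.

`netimpute` takes a different route: it learns quantitative gene–gene
relationships from *external* bulk expression data and uses them to predict
each dropout from the measured genes in the same cell. It also ships a
deliberately simple reference — imputing each gene's zeros with its mean
over the cells where it was detected ("Baseline") — which is surprisingly
hard to beat for genes with little cell-to-cell variation. Because no single
method wins for every gene, the package chooses the best method *per gene*
by masking-based cross-validation and assembles an ensemble imputation.

## The model

Expression is library-size normalized, log2-transformed with a pseudocount
of 1, and centered gene-wise; the model works on deviations *y* from each
gene's mean. Training on bulk data fits, for every gene *i*, a sparse linear
model

  yᵢ = αᵢ·cᵢ + Σ_{j≠i} αᵢⱼ·yⱼ + εᵢ

(with optional copy-number term cᵢ, used in training only), selecting
predictors by LASSO with stability selection (cutoff 0.6, per-family error
rate 0.05) and re-estimating coefficients by least squares on the stable
support. The αᵢⱼ form a directed weighted network **A**.

At imputation time each cell's genes are split into measured (nonzero) and
unmeasured (zero) parts. With F = Aᵐ·Yᵐ the fixed contribution of measured
predictors, the unmeasured deviations solve

  Yⁿ = Aⁿ·Yⁿ + F,

computed either as the Moore–Penrose pseudoinverse solution
(I − Aⁿ)⁺·F or by fixed-point iteration (start at F, at most 50
iterations). Imputed deviations are re-centered with the stored gene means;
measured values are never changed.

Benchmarks mask quantified entries (uniformly per gene/cell, or with an
expression-dependent cubic-spline dropout model) and score each method per
gene by Pearson correlation and mean squared error on the masked entries
that all methods imputed.

## Worked example

Everything below is synthetic and self-contained (no downloads):

```python
import numpy as np
from netimpute import *

cfg = SimulationConfig(n_genes=60, n_cells=150, n_samples=300, seed=42)
network = generate_network(cfg)
truth, observed = simulate_cells(network, cfg)
print(f"observed matrix: {observed.n_genes} genes x {observed.n_cells} cells, "
      f"{observed.sparsity():.1%} zeros")

masked = mask_uniform_per_gene(observed, fraction=0.35, seed=0)
print(f"masked {masked.n_masked} quantified entries for benchmarking")

imputations = {
    "Network": impute_matrix(masked.masked, network),
    "Baseline": baseline_impute(masked.masked),
}
coords = common_imputed_entries(masked, imputations)
corr = per_gene_correlation(masked, imputations["Network"], coords)
mse = {m: per_gene_mse(masked, imp, coords) for m, imp in imputations.items()}
print(f"{len(coords)} masked entries imputed by all methods")
print(f"Network per-gene correlation: median {np.median(list(corr.values())):.3f} "
      f"over {len(corr)} eligible genes")
print(f"median per-gene MSE: Network {np.median(list(mse['Network'].values())):.3f}, "
      f"Baseline {np.median(list(mse['Baseline'].values())):.3f}")

methods = [network_adapter(network), baseline_adapter()]
assignment = evaluate_methods(observed, methods, seed=0)
print(f"per-gene method choice: {assignment.counts()} "
      f"(unlisted genes default to {assignment.default_method})")
combined = ensemble_impute(observed, methods, assignment)
print(f"ensemble output sparsity: {combined.sparsity():.1%} "
      f"(input {observed.sparsity():.1%})")
```

prints

```
observed matrix: 60 genes x 150 cells, 30.2% zeros
masked 2166 quantified entries for benchmarking
1232 masked entries imputed by all methods
Network per-gene correlation: median 0.222 over 30 eligible genes
median per-gene MSE: Network 8.935, Baseline 3.007
per-gene method choice: {'Network': 28} (unlisted genes default to Baseline)
ensemble output sparsity: 0.6% (input 30.2%)
```

Reading this: about a third of the entries are dropouts. On the masked
ground truth the network-based method recovers cell-to-cell variation
(median per-gene r ≈ 0.22; Baseline, which imputes a constant per gene, has
no correlation by construction) while Baseline has the lower squared error
overall — the classic trade-off the per-gene selector exploits. The
cross-validation assigns the network method to the 28 genes it tracks best
and leaves the rest to Baseline; the ensemble fills nearly all zeros.

The same pipeline is scriptable from the shell:

```
netimpute simulate --seed 42 --out-dir sim/
netimpute train sim/bulk_deviations.tsv --seed 1 --out sim/trained.tsv
netimpute impute sim/observed.tsv --scale log2 --network sim/trained.tsv \
    --method ensemble --out sim/imputed.tsv
```

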