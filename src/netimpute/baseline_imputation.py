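"""Baseline imputation: fill zeros with the gene's detected-cell mean.

Each zero entry of a gene is replaced by the average of that gene's nonzero
log2 expression values across all cells.  Genes never detected stay all-zero
and nonzero entries are untouched.  Despite its simplicity this is a strong
reference method: the all-cells mean is a robust estimator exactly when a
gene is rarely detected or varies little between cells.
"""

from __future__ import annotations

import numpy as np

from .data_model import ExpressionMatrix


def detected_means(matrix: ExpressionMatrix) -> np.ndarray:
    """Per-gene mean over nonzero entries (0 for never-detected genes).

    Distinct from the centering convention of :mod:`netimpute.data_model`,
    which averages over all cells including zeros.
    """
    values = matrix.values
    nonzero = values != 0
    counts = nonzero.sum(axis=1)
    sums = values.sum(axis=1)
    means = np.zeros(matrix.n_genes)
    has = counts > 0
    means[has] = sums[has] / counts[has]
    return means


def baseline_impute(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each zero with the gene's mean over cells where it was detected."""
    if matrix.scale != "log2":
        raise ValueError(f"baseline imputation expects log2 scale, got {matrix.scale!r}")
    means = detected_means(matrix)
    out = matrix.values.copy()
    zero = out == 0
    out[zero] = np.broadcast_to(means[:, None], out.shape)[zero]
    return ExpressionMatrix(out, matrix.gene_ids, matrix.cell_ids, "log2")
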