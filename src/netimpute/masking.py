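"""Masking procedures for imputation benchmarking.

Masking deliberately zeroes quantified (nonzero) entries while recording
their original values, so imputed values can later be compared against
ground truth.  Two schemes are provided:

* uniform — a fixed fraction of each gene's (or each cell's) quantified
  entries is zeroed, positions drawn uniformly without replacement;
* model-based — an expression-dependent scheme emulating the downsampling
  character of real dropout: each gene's dropout probability is predicted
  from its mean expression by a cubic spline fitted to the observed
  zero-fraction-vs-mean relationship, and quantified entries are masked by
  independent Bernoulli draws at that gene-specific probability.

Per-gene random substreams are derived from the gene identifier, so the
masking pattern of one gene does not depend on the order or presence of
other genes.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LSQUnivariateSpline

from .data_model import ExpressionMatrix

MaskCoords = list[tuple[str, str, float]]


@dataclass
class MaskedDataset:
    """Original matrix, masked matrix, and the ledger of hidden entries."""

    original: ExpressionMatrix
    masked: ExpressionMatrix
    coords: MaskCoords
    scheme: str
    seed: int

    def __post_init__(self) -> None:
        if len({(g, c) for g, c, _ in self.coords}) != len(self.coords):
            raise ValueError("duplicate masked coordinates")

    @property
    def n_masked(self) -> int:
        return len(self.coords)

    def restore(self) -> ExpressionMatrix:
        """Rebuild the original matrix from masked + coords (exact)."""
        out = self.masked.copy()
        gi = out.gene_index()
        ci = {c: j for j, c in enumerate(out.cell_ids)}
        for g, c, v in self.coords:
            out.values[gi[g], ci[c]] = v
        return out


def _gene_rng(seed: int, key: str) -> np.random.Generator:
    # substream keyed by the identifier, not its position
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(key.encode())]))


def mask_uniform_per_gene(
    matrix: ExpressionMatrix, fraction: float, seed: int = 0
) -> MaskedDataset:
    """Zero exactly floor(fraction * n_quantified) entries of every gene."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    masked = matrix.values.copy()
    coords: MaskCoords = []
    for i, gene in enumerate(matrix.gene_ids):
        quant = np.flatnonzero(matrix.values[i] != 0)
        k = math.floor(fraction * quant.size)
        if k == 0:
            continue
        rng = _gene_rng(seed, gene)
        hit = rng.choice(quant, size=k, replace=False)
        for j in np.sort(hit):
            coords.append((gene, matrix.cell_ids[j], float(matrix.values[i, j])))
            masked[i, j] = 0.0
    return MaskedDataset(
        matrix.copy(),
        ExpressionMatrix(masked, matrix.gene_ids, matrix.cell_ids, matrix.scale),
        coords,
        "uniform_gene",
        seed,
    )


def mask_uniform_per_cell(
    matrix: ExpressionMatrix, fraction: float, seed: int = 0
) -> MaskedDataset:
    """Zero exactly floor(fraction * n_quantified) genes in every cell."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    masked = matrix.values.copy()
    coords: MaskCoords = []
    for j, cell in enumerate(matrix.cell_ids):
        quant = np.flatnonzero(matrix.values[:, j] != 0)
        k = math.floor(fraction * quant.size)
        if k == 0:
            continue
        rng = _gene_rng(seed, cell)
        hit = rng.choice(quant, size=k, replace=False)
        for i in np.sort(hit):
            coords.append((matrix.gene_ids[i], cell, float(matrix.values[i, j])))
            masked[i, j] = 0.0
    return MaskedDataset(
        matrix.copy(),
        ExpressionMatrix(masked, matrix.gene_ids, matrix.cell_ids, matrix.scale),
        coords,
        "uniform_cell",
        seed,
    )


@dataclass
class DropoutModel:
    """Cubic spline mapping per-gene mean log2 expression -> dropout fraction.

    Knots sit at the interior deciles (10%..90%) of the mean-expression
    distribution.  Beyond the fitted range the spline is extended linearly
    from the boundary (value and slope at the outermost data points), and
    all predictions are clamped to [0, 1].
    """

    spline: LSQUnivariateSpline
    x_min: float
    x_max: float

    def predict(self, mean_expression: np.ndarray | float) -> np.ndarray:
        x = np.atleast_1d(np.asarray(mean_expression, dtype=float))
        y = np.empty_like(x)
        inside = (x >= self.x_min) & (x <= self.x_max)
        y[inside] = self.spline(x[inside])
        lo = x < self.x_min
        if lo.any():
            y[lo] = self.spline(self.x_min) + self.spline.derivative()(self.x_min) * (
                x[lo] - self.x_min
            )
        hi = x > self.x_max
        if hi.any():
            y[hi] = self.spline(self.x_max) + self.spline.derivative()(self.x_max) * (
                x[hi] - self.x_max
            )
        return np.clip(y, 0.0, 1.0)

    @property
    def knots(self) -> np.ndarray:
        return self.spline.get_knots()


def _mean_log2(matrix: ExpressionMatrix) -> np.ndarray:
    means = matrix.values.mean(axis=1)
    if matrix.scale == "log2":
        return means
    return np.log2(means + 1.0)


def fit_dropout_model(matrix: ExpressionMatrix) -> DropoutModel:
    """Model each gene's zero-fraction as a cubic spline in its mean expression.

    The fraction of cells where a gene was not captured (zero in the data)
    is regressed on the gene's mean log2 expression, with knots at each
    interior 10% quantile of the mean-expression distribution.
    """
    x = _mean_log2(matrix)
    y = (matrix.values == 0).mean(axis=1)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    # average the zero-fraction over genes with identical means: the spline
    # fit requires strictly increasing abscissae
    ux, inverse = np.unique(xs, return_inverse=True)
    if ux.size < 20:
        raise ValueError(
            f"need >= 20 genes with distinct mean expression, got {ux.size}"
        )
    uy = np.bincount(inverse, weights=ys) / np.bincount(inverse)
    knots = np.quantile(ux, np.arange(1, 10) / 10.0)
    knots = np.unique(knots)
    # Schoenberg-Whitney: keep knots strictly inside the data range
    knots = knots[(knots > ux[0]) & (knots < ux[-1])]
    spline = LSQUnivariateSpline(ux, uy, t=knots, k=3)
    return DropoutModel(spline, float(ux[0]), float(ux[-1]))


def mask_model_based(
    matrix: ExpressionMatrix, model: DropoutModel, seed: int = 0
) -> MaskedDataset:
    """Mask each quantified entry with its gene's predicted dropout probability.

    For every nonzero entry of gene g a Bernoulli(1 - p_g) draw decides
    whether the value survives (1) or is masked to zero (0), with
    p_g = clamp(model(mean_g), 0, 1).
    """
    p = model.predict(_mean_log2(matrix))
    masked = matrix.values.copy()
    coords: MaskCoords = []
    for i, gene in enumerate(matrix.gene_ids):
        quant = np.flatnonzero(matrix.values[i] != 0)
        if quant.size == 0 or p[i] == 0:
            continue
        rng = _gene_rng(seed, gene)
        hit = quant[rng.random(quant.size) < p[i]]
        for j in hit:
            coords.append((gene, matrix.cell_ids[j], float(matrix.values[i, j])))
            masked[i, j] = 0.0
    return MaskedDataset(
        matrix.copy(),
        ExpressionMatrix(masked, matrix.gene_ids, matrix.cell_ids, matrix.scale),
        coords,
        "model_based",
        seed,
    )
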