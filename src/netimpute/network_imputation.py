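"""Network-based dropout imputation.

For each cell, expression deviations Y satisfy Y = A Y under the trained
regulatory model.  Splitting genes into measured (nonzero in the input) and
unmeasured (zero) parts, the unmeasured deviations solve

    Y_n = A_n Y_n + F,     F = A_m Y_m,

where A_n / A_m are the unmeasured-target rows of the adjacency restricted
to unmeasured / measured predictor columns.  Two solvers are provided:

* ``pseudoinverse`` — the minimum-norm least-squares solution
  ``(I - A_n)^+ F`` via Moore-Penrose pseudoinversion, defined even when
  ``I - A_n`` is singular;
* ``iterative`` — fixed-point iteration ``Y_n <- A_n Y_n + F`` starting
  from ``Y_n = F`` (measured predictors only), capped at 50 iterations.

Measured values are never altered: only entries that are exactly zero in
the input are filled in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import CenteredMatrix, ExpressionMatrix, center_genes, log_transform, uncenter
from .network_inference import RegulatoryNetwork

logger = logging.getLogger(__name__)


@dataclass
class SolverConfig:
    """Solver choice and numerical controls.

    ``tolerance`` is the max-absolute-change stopping rule of the iterative
    solver; ``pinv_rcond`` is the relative singular-value cutoff of the
    pseudoinverse (``None`` uses a machine-precision-scaled default).
    """

    method: str = "pseudoinverse"
    max_iterations: int = 50
    tolerance: float = 1e-4
    pinv_rcond: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("pseudoinverse", "iterative"):
            raise ValueError("method must be 'pseudoinverse' or 'iterative'")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class CellPartition:
    """Measured/unmeasured split of one cell against a network.

    ``solve_idx`` are the positions (into ``gene_ids``) of unmeasured genes
    that have at least one network predictor — the genes the solvers
    actually determine.  Unmeasured genes outside ``solve_idx`` have no
    model and are left at zero by the imputers.
    """

    gene_ids: list[str]
    measured_idx: np.ndarray
    unmeasured_idx: np.ndarray
    solve_idx: np.ndarray
    a_n: np.ndarray
    fixed_contribution: np.ndarray


def _index_models(network: RegulatoryNetwork, gene_ids: list[str]):
    """Precompute, per target present in gene_ids, predictor index/coef arrays."""
    idx = {g: i for i, g in enumerate(gene_ids)}
    rows: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for target, model in network.models.items():
        if target not in idx or not model.coefficients:
            continue
        pj = [idx[p] for p in model.coefficients if p in idx]
        if not pj:
            continue
        coefs = [model.coefficients[p] for p in model.coefficients if p in idx]
        rows[idx[target]] = (np.array(pj, dtype=int), np.array(coefs, dtype=float))
    return rows


def partition_cell(
    cell_deviations: np.ndarray,
    original_cell: np.ndarray,
    network: RegulatoryNetwork,
    gene_ids: list[str],
    _rows: dict | None = None,
) -> CellPartition:
    """Split one cell into measured and unmeasured genes and assemble A_n, F.

    A gene is unmeasured iff its original (pre-centering) value is exactly
    zero.  F accumulates contributions from measured predictors only;
    unmeasured predictors without a model contribute nothing.
    """
    cell_deviations = np.asarray(cell_deviations, dtype=float)
    original_cell = np.asarray(original_cell, dtype=float)
    unmeasured = np.flatnonzero(original_cell == 0)
    measured = np.flatnonzero(original_cell != 0)
    rows = _rows if _rows is not None else _index_models(network, gene_ids)
    solve_idx = np.array([i for i in unmeasured if i in rows], dtype=int)
    pos = {g: k for k, g in enumerate(solve_idx)}
    measured_set = set(measured.tolist())

    n = solve_idx.size
    a_n = np.zeros((n, n))
    f = np.zeros(n)
    for k, i in enumerate(solve_idx):
        pj, coefs = rows[i]
        for j, c in zip(pj, coefs):
            if j in measured_set:
                f[k] += c * cell_deviations[j]
            elif j in pos:
                a_n[k, pos[j]] = c
            # unmeasured predictor without a model: stays at deviation 0
    return CellPartition(list(gene_ids), measured, unmeasured, solve_idx, a_n, f)


def solve_pseudoinverse(partition: CellPartition, config: SolverConfig | None = None) -> np.ndarray:
    """Minimum-norm least-squares solution of (I - A_n) x = F."""
    config = config or SolverConfig()
    n = partition.solve_idx.size
    if n == 0:
        return np.zeros(0)
    m = np.eye(n) - partition.a_n
    rcond = config.pinv_rcond if config.pinv_rcond is not None else max(m.shape) * np.finfo(float).eps
    return np.linalg.pinv(m, rcond=rcond) @ partition.fixed_contribution


def solve_iterative(
    partition: CellPartition, config: SolverConfig | None = None
) -> tuple[np.ndarray, int, bool]:
    """Fixed-point iteration for (I - A_n) x = F.

    Iteration 1 predicts every unmeasured gene from measured predictors only
    (x = F); each later round re-predicts from the previous iterate.  Stops
    when the largest absolute change drops below ``tolerance`` or after
    ``max_iterations`` rounds, returning the last iterate either way.  The
    reported iteration count is the round at which the returned value was
    first attained (an exact fixed point detected at round k was already
    reached at round k-1).
    """
    config = config or SolverConfig(method="iterative")
    f = partition.fixed_contribution
    if f.size == 0:
        return np.zeros(0), 0, True
    x = f.copy()
    if not partition.a_n.any():
        return x, 1, True
    n_iter = 1
    converged = False
    while n_iter < config.max_iterations:
        x_new = partition.a_n @ x + f
        n_iter += 1
        delta = float(np.max(np.abs(x_new - x)))
        x = x_new
        if delta < config.tolerance:
            converged = True
            if delta == 0.0:
                n_iter -= 1
            break
    return x, n_iter, converged


@dataclass
class ImputationStats:
    """Per-run convergence bookkeeping from :func:`impute_matrix`."""

    n_cells: int = 0
    n_imputed_entries: int = 0
    n_unimputable_entries: int = 0
    iterations: list[int] = field(default_factory=list)
    n_unconverged_cells: int = 0


def impute_matrix(
    matrix: ExpressionMatrix,
    network: RegulatoryNetwork,
    config: SolverConfig | None = None,
    stats: ImputationStats | None = None,
) -> ExpressionMatrix:
    """Impute every zero entry the network can reach; measured values untouched.

    The matrix is log2-transformed if given on the normalized scale, centered
    gene-wise, solved per cell, re-centered with the stored means and clamped
    at zero.  Genes without a (nonempty) model keep their zeros.
    """
    config = config or SolverConfig()
    if matrix.scale == "counts":
        raise ValueError("impute_matrix expects normalized or log2 input")
    if matrix.scale == "normalized":
        matrix = log_transform(matrix)
    if not set(matrix.gene_ids) & set(network.gene_universe):
        raise ValueError("no genes shared between matrix and network")

    centered = center_genes(matrix)
    rows = _index_models(network, matrix.gene_ids)
    out = matrix.values.copy()
    stats = stats if stats is not None else ImputationStats()
    stats.n_cells = matrix.n_cells

    for c in range(matrix.n_cells):
        original = matrix.values[:, c]
        part = partition_cell(
            centered.deviations[:, c], original, network, matrix.gene_ids, _rows=rows
        )
        stats.n_unimputable_entries += part.unmeasured_idx.size - part.solve_idx.size
        if part.solve_idx.size == 0:
            continue
        if config.method == "iterative":
            dev, n_iter, converged = solve_iterative(part, config)
            stats.iterations.append(n_iter)
            if not converged:
                stats.n_unconverged_cells += 1
        else:
            dev = solve_pseudoinverse(part, config)
        imputed = np.maximum(dev + centered.centers[part.solve_idx], 0.0)
        out[part.solve_idx, c] = imputed
        stats.n_imputed_entries += part.solve_idx.size

    if stats.n_unconverged_cells:
        logger.info(
            "%d/%d cells hit the iteration cap (%d)",
            stats.n_unconverged_cells, matrix.n_cells, config.max_iterations,
        )
    return ExpressionMatrix(out, matrix.gene_ids, matrix.cell_ids, "log2")


def predict_single_gene(
    gene: str,
    sample_deviations: dict[str, float],
    network: RegulatoryNetwork,
    copy_number: float | None = None,
) -> float:
    """Predict one gene's deviation from its network predictors in a sample.

    Used for bulk validation: predicted-vs-observed deviations across samples
    quantify the network's predictive power per gene.  Predictors absent from
    the sample contribute nothing.
    """
    model = network.models.get(gene)
    if model is None:
        raise KeyError(f"gene {gene!r} has no model in the network")
    pred = 0.0
    for p, coef in model.coefficients.items():
        pred += coef * sample_deviations.get(p, 0.0)
    if copy_number is not None and model.cnv_coefficient is not None:
        pred += model.cnv_coefficient * copy_number
    return pred
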