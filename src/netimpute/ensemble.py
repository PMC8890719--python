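"""Per-gene adaptive method selection and ensemble imputation.

No imputation method wins on every gene: network-based imputation excels
where a gene's variation is driven by well-trained predictors, while the
detected-cell mean is hard to beat for genes with little cell-to-cell
variation or few observations.  The ensemble therefore chooses a method
*per gene* by masking-based cross-validation on a training split of the
cells, and assembles the final imputation gene-wise from each gene's
winner, defaulting to Baseline when no decision can be made.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .baseline_imputation import baseline_impute
from .data_model import ExpressionMatrix
from .evaluation import common_imputed_entries, per_gene_correlation
from .masking import mask_uniform_per_gene
from .network_imputation import SolverConfig, impute_matrix
from .network_inference import RegulatoryNetwork

logger = logging.getLogger(__name__)

BASELINE = "Baseline"
NETWORK = "Network"

SMALL_DATASET_CELLS = 150      # below this, train on 98% of cells
SMALL_TRAIN_FRACTION = 0.98
DEFAULT_TRAIN_FRACTION = 0.70
DEFAULT_MASK_FRACTION = 0.30


@dataclass
class MethodAdapter:
    """A named imputation method: ExpressionMatrix -> same-shape ExpressionMatrix.

    External tools can be wrapped with a files-in/files-out callable; the
    built-in Network and Baseline adapters additionally guarantee that
    nonzero input entries pass through bit-exactly.
    """

    name: str
    impute: Callable[[ExpressionMatrix], ExpressionMatrix]

    def __call__(self, matrix: ExpressionMatrix) -> ExpressionMatrix:
        out = self.impute(matrix)
        if out.values.shape != matrix.values.shape:
            raise ValueError(
                f"adapter {self.name!r} changed matrix shape: "
                f"{matrix.values.shape} -> {out.values.shape}"
            )
        return out


def baseline_adapter() -> MethodAdapter:
    return MethodAdapter(BASELINE, baseline_impute)


def network_adapter(
    network: RegulatoryNetwork, config: SolverConfig | None = None
) -> MethodAdapter:
    cfg = config or SolverConfig()
    return MethodAdapter(NETWORK, lambda m: impute_matrix(m, network, cfg))


@dataclass
class MethodAssignment:
    """Chosen method per gene plus provenance of the cross-validation run."""

    mapping: dict[str, str]
    default_method: str = BASELINE
    seed: int = 0
    mask_fraction: float = DEFAULT_MASK_FRACTION
    train_fraction: float = DEFAULT_TRAIN_FRACTION
    winning_correlation: dict[str, float] = field(default_factory=dict)

    def method_for(self, gene: str) -> str:
        return self.mapping.get(gene, self.default_method)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.mapping.values():
            out[m] = out.get(m, 0) + 1
        return out


def split_cells(
    matrix: ExpressionMatrix,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
    small_dataset_cells: int = SMALL_DATASET_CELLS,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Random train/test split of cells (train 70%, or 98% for small data).

    Datasets with fewer than ``small_dataset_cells`` cells automatically use
    a 98% training share so that enough cells remain to estimate per-gene
    correlations.  Cell order within each split follows the input order.
    """
    n = matrix.n_cells
    if n < 10:
        raise ValueError(f"need >= 10 cells to split, got {n}")
    if n < small_dataset_cells:
        train_fraction = max(train_fraction, SMALL_TRAIN_FRACTION)
    n_train = int(np.floor(train_fraction * n))
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(n, size=n_train, replace=False))
    mask = np.zeros(n, dtype=bool)
    mask[chosen] = True

    def take(sel: np.ndarray) -> ExpressionMatrix:
        return ExpressionMatrix(
            matrix.values[:, sel],
            matrix.gene_ids,
            [c for c, keep in zip(matrix.cell_ids, sel) if keep],
            matrix.scale,
        )

    return take(mask), take(~mask)


def _priority(methods: list[MethodAdapter]) -> dict[str, int]:
    """Tie-break priority: Network first, then registration order, Baseline last."""
    names = [m.name for m in methods]
    ordered = [n for n in names if n == NETWORK]
    ordered += [n for n in names if n not in (NETWORK, BASELINE)]
    ordered += [n for n in names if n == BASELINE]
    return {n: i for i, n in enumerate(ordered)}


def evaluate_methods(
    matrix: ExpressionMatrix,
    methods: list[MethodAdapter],
    mask_fraction: float = DEFAULT_MASK_FRACTION,
    min_entries: int = 10,
    seed: int = 0,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
) -> MethodAssignment:
    """Determine the best imputation method for each gene by cross-validation.

    A training split of the cells is masked (uniform per-gene scheme), every
    adapter imputes the masked split, and per-gene Pearson correlations are
    computed on the entries all methods imputed (>= ``min_entries`` per
    gene).  Each gene is assigned its argmax-correlation method; exact ties
    fall to the priority Network > other adapters > Baseline, and genes with
    no usable correlation default to Baseline.
    """
    names = [m.name for m in methods]
    if len(names) != len(set(names)):
        raise ValueError("duplicate method names")
    if BASELINE not in names:
        raise ValueError("Baseline must be among the evaluated methods")
    if len(methods) < 2:
        raise ValueError("need >= 2 methods to choose between")

    rng = np.random.default_rng(seed)
    split_seed, mask_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    train, _test = split_cells(matrix, train_fraction, seed=split_seed)
    masked = mask_uniform_per_gene(train, mask_fraction, seed=mask_seed)

    imputations: dict[str, ExpressionMatrix] = {}
    survivors: list[MethodAdapter] = []
    for adapter in methods:
        try:
            imputations[adapter.name] = adapter(masked.masked)
            survivors.append(adapter)
        except Exception as exc:  # noqa: BLE001 - adapters may wrap external tools
            logger.warning("method %s failed and was dropped: %s", adapter.name, exc)

    assignment = MethodAssignment(
        {}, BASELINE, seed, mask_fraction, train_fraction
    )
    if len(survivors) == 1:
        only = survivors[0].name
        assignment.mapping = {g: only for g in matrix.gene_ids}
        return assignment

    coords = common_imputed_entries(masked, imputations)
    corr = {
        m: per_gene_correlation(masked, imp, coords, min_entries)
        for m, imp in imputations.items()
    }
    prio = _priority(survivors)
    for gene in matrix.gene_ids:
        scores = {m: corr[m][gene] for m in corr if gene in corr[m]}
        if not scores:
            continue  # resolves to the default method
        best = max(scores.values())
        tied = sorted((m for m, r in scores.items() if r == best), key=prio.get)
        assignment.mapping[gene] = tied[0]
        assignment.winning_correlation[gene] = best
    return assignment


def ensemble_impute(
    matrix: ExpressionMatrix,
    methods: list[MethodAdapter],
    assignment: MethodAssignment,
) -> ExpressionMatrix:
    """Assemble the final imputation gene-wise from each gene's chosen method."""
    by_name = {m.name: m for m in methods}
    needed = {assignment.method_for(g) for g in matrix.gene_ids}
    missing = needed - set(by_name)
    if missing:
        raise KeyError(f"assigned methods missing from adapter list: {sorted(missing)}")
    results = {name: by_name[name](matrix) for name in sorted(needed)}
    out = matrix.values.copy()
    for i, gene in enumerate(matrix.gene_ids):
        out[i] = results[assignment.method_for(gene)].values[i]
    return ExpressionMatrix(out, matrix.gene_ids, matrix.cell_ids, "log2")
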