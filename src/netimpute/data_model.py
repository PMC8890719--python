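"""Core expression-matrix containers and scale transforms.

Matrices are oriented genes-in-rows, cells-in-columns everywhere in this
package.  Three scales are tracked explicitly so that downstream stages can
assert their preconditions instead of silently mixing units:

``counts``
    raw (possibly UMI-deduplicated) read counts,
``normalized``
    library-size normalized expression (RPM/TPM-like, column sums 1e6),
``log2``
    ``log2(normalized + 1)``.

The network imputation model operates on *deviations*: log2 expression minus
the gene's mean across all cells.  :class:`CenteredMatrix` stores those
deviations together with the original per-gene centers so imputed deviations
can be shifted back to the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_SCALES = ("counts", "normalized", "log2")
LIBRARY_SIZE = 1e6


def _check_ids(ids: list[str], kind: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {kind} id: {dup!r}")
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix of non-negative expression values.

    Parameters
    ----------
    values
        2-D float array, one row per gene, one column per cell.
    gene_ids, cell_ids
        Unique, ordered identifiers for rows and columns.
    scale
        One of ``counts``, ``normalized``, ``log2``.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    scale: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (genes x cells)")
        self.gene_ids = _check_ids(list(self.gene_ids), "gene")
        self.cell_ids = _check_ids(list(self.cell_ids), "cell")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.gene_ids), list(self.cell_ids), self.scale
        )

    def sparsity(self) -> float:
        """Fraction of exactly-zero entries."""
        return float(np.mean(self.values == 0))


@dataclass
class CenteredMatrix:
    """Per-gene centered log2 expression: ``deviations = log2 - centers``."""

    deviations: np.ndarray
    centers: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.deviations = np.asarray(self.deviations, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float).ravel()
        self.gene_ids = _check_ids(list(self.gene_ids), "gene")
        self.cell_ids = _check_ids(list(self.cell_ids), "cell")
        if self.deviations.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("deviations shape does not match id lists")
        if self.centers.shape != (len(self.gene_ids),):
            raise ValueError("one center per gene required")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class CopyNumberMatrix:
    """Genes x samples copy-number states, used during network training only."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _check_ids(list(self.gene_ids), "gene")
        self.sample_ids = _check_ids(list(self.sample_ids), "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("copy-number shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("copy-number values must be finite")

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


def normalize_library_size(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell so its total signal is one million (RPM-style).

    Raises
    ------
    ValueError
        If ``matrix.scale`` is not ``counts`` or any cell has zero total.
    """
    if matrix.scale != "counts":
        raise ValueError(f"expected counts input, got scale {matrix.scale!r}")
    totals = matrix.values.sum(axis=0)
    if np.any(totals <= 0):
        bad = matrix.cell_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"cell {bad!r} has zero total counts and cannot be normalized")
    values = matrix.values * (LIBRARY_SIZE / totals)
    return ExpressionMatrix(values, matrix.gene_ids, matrix.cell_ids, "normalized")


def log_transform(matrix: ExpressionMatrix, allow_counts: bool = False) -> ExpressionMatrix:
    """``log2(v + 1)`` entrywise; zeros stay zero.

    The pseudocount of 1 means structural/dropout zeros remain exactly zero on
    the log2 scale, which downstream modules rely on to identify unmeasured
    entries.
    """
    if matrix.scale == "log2":
        raise ValueError("matrix is already log2 scaled")
    if matrix.scale == "counts" and not allow_counts:
        raise ValueError(
            "log_transform expects normalized input; pass allow_counts=True "
            "to log-transform raw counts"
        )
    return ExpressionMatrix(
        np.log2(matrix.values + 1.0), matrix.gene_ids, matrix.cell_ids, "log2"
    )


def center_genes(matrix: ExpressionMatrix) -> CenteredMatrix:
    """Subtract each gene's mean (over all cells, zeros included) and keep it.

    Zero entries participate in the mean: the center is the plain arithmetic
    row mean of the log2 matrix.  The detected-only mean used by baseline
    imputation is a different quantity and lives in
    :mod:`netimpute.baseline_imputation`.
    """
    if matrix.scale != "log2":
        raise ValueError(f"centering requires log2 scale, got {matrix.scale!r}")
    centers = matrix.values.mean(axis=1)
    deviations = matrix.values - centers[:, None]
    return CenteredMatrix(deviations, centers, matrix.gene_ids, matrix.cell_ids)


def uncenter(centered: CenteredMatrix, clamp: bool = True) -> ExpressionMatrix:
    """Add the stored centers back; negative log2 results are clamped to 0.

    log2(x+1) of non-negative expression is non-negative, so any negative
    value produced by re-centering an imputed deviation is an artefact and is
    clipped.  Entries that need no clamping round-trip bit-exactly.
    """
    values = centered.deviations + centered.centers[:, None]
    if clamp:
        np.clip(values, 0.0, None, out=values)
    return ExpressionMatrix(values, centered.gene_ids, centered.cell_ids, "log2")
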