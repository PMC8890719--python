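"""Per-gene imputation quality on masked entries.

All comparisons are restricted to masked coordinates — entries that were
quantified, deliberately zeroed, and then imputed — and, when several
methods are compared, to the *common* subset every method filled with a
nonzero value.  Quality is quantified per gene as the Pearson correlation
between original and imputed values across cells (requires at least
``min_entries`` usable pairs) and as the mean squared imputation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix
from .masking import MaskedDataset

QUARTILES = ("Q1", "Q2", "Q3", "Q4")
CORRELATION_BAND = 0.1     # within this of the best correlation = top performer
MSE_RANGE_FRACTION = 0.05  # within this fraction of the per-gene MSE range

Coords = list[tuple[str, str, float]]


def common_imputed_entries(
    masked: MaskedDataset, imputations: dict[str, ExpressionMatrix]
) -> Coords:
    """Masked coordinates at which every method imputed a nonzero value."""
    shape = masked.masked.values.shape
    out: Coords = []
    index_pairs = []
    for name, imp in imputations.items():
        if imp.values.shape != shape:
            raise ValueError(
                f"imputation {name!r} shape {imp.values.shape} != masked shape {shape}"
            )
        index_pairs.append((imp.gene_index(), {c: j for j, c in enumerate(imp.cell_ids)}, imp))
    for g, c, v in masked.coords:
        if all(imp.values[gi[g], ci[c]] != 0 for gi, ci, imp in index_pairs):
            out.append((g, c, v))
    return out


def _pairs_by_gene(coords: Coords, imputed: ExpressionMatrix):
    gi = imputed.gene_index()
    ci = {c: j for j, c in enumerate(imputed.cell_ids)}
    by_gene: dict[str, list[tuple[float, float]]] = {}
    for g, c, v in coords:
        by_gene.setdefault(g, []).append((v, float(imputed.values[gi[g], ci[c]])))
    return by_gene


def per_gene_correlation(
    masked: MaskedDataset,
    imputed: ExpressionMatrix,
    coords: Coords,
    min_entries: int = 10,
) -> dict[str, float]:
    """Pearson r between original and imputed values, per gene.

    Genes with fewer than ``min_entries`` coordinates, or with zero variance
    on either side, are absent from the result rather than zero-filled.
    """
    out: dict[str, float] = {}
    for gene, pairs in _pairs_by_gene(coords, imputed).items():
        if len(pairs) < min_entries:
            continue
        orig = np.array([p[0] for p in pairs])
        imp = np.array([p[1] for p in pairs])
        # relative guard: a numerically-constant side has no defined correlation
        if orig.std() <= 1e-12 * max(1.0, np.abs(orig).max()) or \
                imp.std() <= 1e-12 * max(1.0, np.abs(imp).max()):
            continue
        out[gene] = float(np.corrcoef(orig, imp)[0, 1])
    return out


def per_gene_mse(
    masked: MaskedDataset, imputed: ExpressionMatrix, coords: Coords
) -> dict[str, float]:
    """Mean squared imputation error per gene (any gene with >= 1 coordinate)."""
    out: dict[str, float] = {}
    for gene, pairs in _pairs_by_gene(coords, imputed).items():
        diffs = np.array([p[0] - p[1] for p in pairs])
        out[gene] = float(np.mean(diffs**2))
    return out


def assign_quartiles(masked_matrix: ExpressionMatrix) -> dict[str, str]:
    """Quartile of per-gene mean expression, computed on the masked data.

    Q1 is the lowest-expression quartile.  Ties at a boundary are broken by
    gene order (stable sort), so the assignment is deterministic.
    """
    means = masked_matrix.values.mean(axis=1)
    order = np.argsort(means, kind="stable")
    n = len(order)
    out: dict[str, str] = {}
    for rank, i in enumerate(order):
        q = min(3, (4 * rank) // n) if n else 0
        out[masked_matrix.gene_ids[i]] = QUARTILES[q]
    return out


def top_performers(
    metric_by_method: dict[str, dict[str, float]], criterion: str
) -> dict[str, tuple[set[str], bool]]:
    """Per gene: the set of top-performing methods and a foreground flag.

    correlation criterion — every method within 0.1 of the per-gene maximum;
    mse criterion — every method within 5% of the per-gene MSE range of the
    minimum.  Genes where *all* evaluated methods qualify are flagged as
    background-only (foreground flag False).
    """
    if criterion not in ("correlation", "mse"):
        raise ValueError("criterion must be 'correlation' or 'mse'")
    if len(metric_by_method) < 2:
        raise ValueError("need >= 2 methods for top-performer analysis")
    genes: set[str] = set()
    for per_gene in metric_by_method.values():
        genes |= set(per_gene)
    out: dict[str, tuple[set[str], bool]] = {}
    for gene in genes:
        vals = {m: per_gene[gene] for m, per_gene in metric_by_method.items() if gene in per_gene}
        if len(vals) < 2:
            continue
        if criterion == "correlation":
            best = max(vals.values())
            top = {m for m, v in vals.items() if v >= best - CORRELATION_BAND}
        else:
            lo, hi = min(vals.values()), max(vals.values())
            band = lo + MSE_RANGE_FRACTION * (hi - lo)
            top = {m for m, v in vals.items() if v <= band}
        out[gene] = (top, len(top) < len(vals))
    return out


@dataclass
class EvaluationReport:
    """Tidy per-(gene, method) quality table with quartiles and top flags."""

    table: pd.DataFrame
    min_entries: int = 10
    method_names: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")

    def best_method_share(self, criterion: str = "correlation") -> pd.Series:
        """Fraction of foreground genes on which each method is a top performer."""
        col = "top_corr" if criterion == "correlation" else "top_mse"
        fg = self.table[self.table[col + "_foreground"]]
        if fg.empty:
            return pd.Series(dtype=float)
        return fg.groupby("method")[col].mean().sort_values(ascending=False)


def evaluate(
    masked: MaskedDataset,
    imputations: dict[str, ExpressionMatrix],
    min_entries: int = 10,
) -> EvaluationReport:
    """Full benchmark: common entries, per-gene r and MSE, quartiles, top flags."""
    coords = common_imputed_entries(masked, imputations)
    corr = {m: per_gene_correlation(masked, imp, coords, min_entries) for m, imp in imputations.items()}
    mse = {m: per_gene_mse(masked, imp, coords) for m, imp in imputations.items()}
    quart = assign_quartiles(masked.masked)
    n_by_gene: dict[str, int] = {}
    for g, _, _ in coords:
        n_by_gene[g] = n_by_gene.get(g, 0) + 1
    top_c = top_performers(corr, "correlation") if len(imputations) >= 2 and corr else {}
    top_m = top_performers(mse, "mse") if len(imputations) >= 2 and mse else {}

    rows = []
    for method, imp in imputations.items():
        for gene in sorted(n_by_gene):
            tc = top_c.get(gene)
            tm = top_m.get(gene)
            rows.append(
                {
                    "gene": gene,
                    "method": method,
                    "n": n_by_gene[gene],
                    "pearson_r": corr[method].get(gene, np.nan),
                    "mse": mse[method].get(gene, np.nan),
                    "quartile": quart[gene],
                    "top_corr": bool(tc and method in tc[0]),
                    "top_corr_foreground": bool(tc and tc[1]),
                    "top_mse": bool(tm and method in tm[0]),
                    "top_mse_foreground": bool(tm and tm[1]),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene", "method", "n", "pearson_r", "mse", "quartile",
            "top_corr", "top_corr_foreground", "top_mse", "top_mse_foreground",
        ],
    )
    return EvaluationReport(table, min_entries, list(imputations))
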