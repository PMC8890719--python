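"""Readers and writers for expression matrices, networks and benchmark files.

Dense matrices are tab- (or comma-) separated with gene ids in the first
column and cell ids in the header row.  Sparse matrices use MatrixMarket
coordinate format with sidecar id files (``<stem>.genes.txt`` and
``<stem>.cells.txt``, one id per line).  Networks are TSV edge lists with
the header ``target<TAB>predictor<TAB>coefficient``; the predictor token
``__CNV__`` stores a target's copy-number coefficient.  Floats are written
with 17 significant digits so round trips are bit-exact.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .data_model import ExpressionMatrix
from .masking import MaskCoords, MaskedDataset
from .network_inference import CNV_TOKEN, GeneModel, RegulatoryNetwork

FLOAT_FMT = "%.17g"


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".genes.txt"), stem.with_suffix(".cells.txt")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "csv", "mtx", "txt"):
        return "tsv" if suffix == "txt" else suffix
    raise ValueError(f"cannot infer matrix format from {path.name!r}; pass format=")


def read_matrix(path, fmt: str | None = None, scale: str = "normalized") -> ExpressionMatrix:
    """Read a genes x cells matrix from dense TSV/CSV or MatrixMarket triplets."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        genes_path, cells_path = _sidecar_paths(path)
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FileNotFoundError(f"missing sidecar id file {p}")
        genes = genes_path.read_text().splitlines()
        cells = cells_path.read_text().splitlines()
        raw = spio.mmread(path)
        values = np.asarray(raw.todense()) if sparse.issparse(raw) else np.asarray(raw)
        if values.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {values.shape} does not match sidecar ids "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        return ExpressionMatrix(values, genes, cells, scale)
    sep = "\t" if fmt == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate cell id {dup!r} in {path}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]][0]
        raise ValueError(f"non-numeric entries in column {bad!r} of {path}")
    return ExpressionMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)), scale)


def write_matrix(matrix: ExpressionMatrix, path, fmt: str | None = None) -> None:
    """Write a matrix; inverse of :func:`read_matrix` (bit-exact round trip)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        genes_path, cells_path = _sidecar_paths(path)
        coo = sparse.coo_matrix(matrix.values)
        # sort triplets row-major for deterministic byte output
        order = np.lexsort((coo.col, coo.row))
        coo = sparse.coo_matrix(
            (coo.data[order], (coo.row[order], coo.col[order])), shape=coo.shape
        )
        spio.mmwrite(path, coo, precision=17)
        genes_path.write_text("\n".join(matrix.gene_ids) + "\n")
        cells_path.write_text("\n".join(matrix.cell_ids) + "\n")
        return
    sep = "\t" if fmt == "tsv" else ","
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.cell_ids)
    df.to_csv(path, sep=sep, float_format=FLOAT_FMT)


NETWORK_HEADER = "target\tpredictor\tcoefficient"


def write_network(network: RegulatoryNetwork, path) -> None:
    """TSV edge list; an accompanying ``<path>.meta.json`` is NOT written here."""
    path = Path(path)
    lines = [NETWORK_HEADER]
    for target in network.gene_universe:
        model = network.models.get(target)
        if model is None:
            continue
        for pred in model.coefficients:
            lines.append(f"{target}\t{pred}\t{FLOAT_FMT % model.coefficients[pred]}")
        if model.cnv_coefficient is not None:
            lines.append(f"{target}\t{CNV_TOKEN}\t{FLOAT_FMT % model.cnv_coefficient}")
    path.write_text("\n".join(lines) + "\n")


def read_network(path) -> RegulatoryNetwork:
    """Read a TSV edge list; rejects self-edges, NaNs and a wrong header."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0] != NETWORK_HEADER:
        raise ValueError(
            f"{path}: expected header {NETWORK_HEADER!r}, got {lines[0] if lines else '<empty>'!r}"
        )
    coeffs: dict[str, dict[str, float]] = {}
    cnv: dict[str, float] = {}
    genes: list[str] = []
    seen: set[str] = set()

    def note(g: str) -> None:
        if g != CNV_TOKEN and g not in seen:
            seen.add(g)
            genes.append(g)

    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
        target, pred, coef_s = parts
        try:
            coef = float(coef_s)
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: bad coefficient {coef_s!r}") from exc
        if math.isnan(coef) or math.isinf(coef):
            raise ValueError(f"{path}:{ln}: non-finite coefficient for {target!r}")
        if pred == target:
            raise ValueError(f"{path}:{ln}: self-edge on gene {target!r}")
        note(target)
        note(pred)
        if pred == CNV_TOKEN:
            cnv[target] = coef
        else:
            coeffs.setdefault(target, {})[pred] = coef
    models = {
        t: GeneModel(t, coeffs.get(t, {}), cnv.get(t))
        for t in sorted(set(coeffs) | set(cnv))
    }
    return RegulatoryNetwork(models, genes)


def write_network_metadata(path, metadata: dict) -> None:
    Path(path).write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")


def write_mask_coords(coords: MaskCoords, path) -> None:
    path = Path(path)
    lines = ["gene\tcell\toriginal_value"]
    lines += [f"{g}\t{c}\t{FLOAT_FMT % v}" for g, c, v in coords]
    path.write_text("\n".join(lines) + "\n")


def read_mask_coords(path) -> MaskCoords:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0] != "gene\tcell\toriginal_value":
        raise ValueError(f"{path}: expected header 'gene<TAB>cell<TAB>original_value'")
    out: MaskCoords = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        g, c, v = line.split("\t")
        out.append((g, c, float(v)))
    return out


def write_masked_dataset(masked: MaskedDataset, matrix_path, coords_path, fmt: str | None = None) -> None:
    write_matrix(masked.masked, matrix_path, fmt)
    write_mask_coords(masked.coords, coords_path)


def write_assignment(assignment, path) -> None:
    """Ensemble method assignment as TSV: gene, method, winning correlation."""
    path = Path(path)
    lines = ["gene\tmethod\tpearson_r"]
    for gene in sorted(assignment.mapping):
        r = assignment.winning_correlation.get(gene)
        r_s = FLOAT_FMT % r if r is not None else "NA"
        lines.append(f"{gene}\t{assignment.mapping[gene]}\t{r_s}")
    path.write_text("\n".join(lines) + "\n")
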