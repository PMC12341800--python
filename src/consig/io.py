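"""Readers and writers for the external text formats the pipeline touches.

Formats: tab-separated marker tables, Broad-dialect GMT gene sets,
MatrixMarket coordinate triplets (genes = rows, cells = columns, 1-based)
with plain-text gene/cell id files, dense TSV expression, and tab-separated
cell-metadata tables.  Everything is UTF-8; the delimiter is overridable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datatypes import (
    CellAnnotation,
    CellClass,
    ExpressionMatrix,
    FCScale,
    FormatError,
    GeneSet,
    LayerTag,
    MarkerTable,
    ValidationError,
)

logger = logging.getLogger("consig")

DEFAULT_MARKER_COLUMNS: Mapping[str, str] = {
    "study_id": "study",
    "population_label": "population",
    "cell_class": "cell_class",
    "gene": "gene",
    "fc_value": "fc",
    "p_adj": "p_adj",
}

_MISSING_TOKENS = {"", "na", "nan", "n/a", "null", "none"}


def _parse_cell_class(value: str) -> CellClass:
    try:
        return CellClass[value.strip().upper()]
    except KeyError:
        logger.warning("unknown cell class %r mapped to OTHER", value)
        return CellClass.OTHER


def read_marker_table(path: str | Path,
                      fc_scale: FCScale | Mapping[str, FCScale],
                      *,
                      delimiter: str = "\t",
                      columns: Mapping[str, str] | None = None) -> MarkerTable:
    """Read a delimited marker table into a validated :class:`MarkerTable`.

    ``fc_scale`` is either one scale for every study or a mapping
    study_id -> scale.  Rows with unparseable fold changes are rejected and
    reported with their line numbers; ``p_adj`` missing-value tokens (NA,
    empty, ...) are kept as missing with a warning.
    """
    colmap = dict(DEFAULT_MARKER_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for field, col in colmap.items():
        if col not in df.columns:
            raise FormatError(f"marker table {path} lacks mandatory column {col!r}")
    out = pd.DataFrame({f: df[c].astype(str).str.strip() for f, c in colmap.items()})

    fc = pd.to_numeric(out["fc_value"], errors="coerce")
    bad = fc.isna()
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()  # +2: header + 1-based
        logger.warning("rejecting %d rows with unparseable fold change "
                       "(file lines %s)", int(bad.sum()), lines[:20])
    out["fc_value"] = fc

    padj_raw = out["p_adj"]
    missing = padj_raw.str.casefold().isin(_MISSING_TOKENS)
    padj = pd.to_numeric(padj_raw.where(~missing, other=""), errors="coerce")
    unparseable = padj.isna() & ~missing
    if unparseable.any():
        logger.warning("treating %d unparseable p_adj values as missing",
                       int(unparseable.sum()))
    if missing.any():
        logger.warning("%d rows carry a missing p_adj (kept; they fail any "
                       "p-value threshold)", int(missing.sum()))
    out["p_adj"] = padj

    out["cell_class"] = out["cell_class"].map(_parse_cell_class)
    if isinstance(fc_scale, FCScale):
        out["fc_scale"] = fc_scale
    else:
        unknown = set(out["study_id"]) - set(fc_scale)
        if unknown:
            raise ValidationError(f"no fc_scale given for studies: {sorted(unknown)}")
        out["fc_scale"] = out["study_id"].map(fc_scale)
    out = out[~bad].reset_index(drop=True)
    return MarkerTable(out)


def write_marker_table(table: MarkerTable, path: str | Path,
                       *, delimiter: str = "\t") -> None:
    df = table.records.copy()
    df["cell_class"] = df["cell_class"].map(lambda c: c.value)
    df = df.rename(columns={"study_id": "study", "population_label": "population",
                            "fc_value": "fc"})
    df.drop(columns=["fc_scale"]).to_csv(path, sep=delimiter, index=False)


def marker_fc_scales(table: MarkerTable) -> dict[str, FCScale]:
    """Study -> fold-change scale, for round-tripping a written table."""
    return dict(table.records.groupby("study_id")["fc_scale"].first())


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a Broad-dialect GMT file (name, description, genes...)."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} fields found)")
            name, desc, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            deduped: list[str] = []
            seen: set[str] = set()
            for g in genes:
                key = g.casefold()
                if key in seen:
                    logger.warning("%s:%d: duplicate gene %r in set %r dropped",
                                   path, lineno, g, name)
                    continue
                seen.add(key)
                deduped.append(g)
            if not deduped:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, genes=tuple(deduped), description=desc))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def _read_ids(path: str | Path) -> tuple[str, ...]:
    with open(path, encoding="utf-8") as fh:
        # id files may carry extra 10x-style columns; the first is the id
        return tuple(line.rstrip("\n").split("\t")[0]
                     for line in fh if line.strip())


def read_expression_mtx(matrix_path: str | Path,
                        genes_path: str | Path,
                        cells_path: str | Path,
                        layer_tag: LayerTag = LayerTag.COUNTS) -> ExpressionMatrix:
    """Read an MTX coordinate triplet (genes = rows, cells = columns)."""
    mat = spio.mmread(str(matrix_path))
    genes = _read_ids(genes_path)
    cells = _read_ids(cells_path)
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"gene id file lists {len(genes)} ids but matrix declares "
            f"{mat.shape[0]} rows")
    if mat.shape[1] != len(cells):
        raise FormatError(
            f"cell id file lists {len(cells)} ids but matrix declares "
            f"{mat.shape[1]} columns")
    return ExpressionMatrix(genes, cells, sparse.csr_matrix(mat), layer_tag)


def write_expression_mtx(expr: ExpressionMatrix,
                         matrix_path: str | Path,
                         genes_path: str | Path,
                         cells_path: str | Path) -> None:
    spio.mmwrite(str(matrix_path), sparse.coo_matrix(expr.values))
    Path(genes_path).write_text("\n".join(expr.gene_ids) + "\n", encoding="utf-8")
    Path(cells_path).write_text("\n".join(expr.cell_ids) + "\n", encoding="utf-8")


def read_expression_dense(path: str | Path,
                          layer_tag: LayerTag = LayerTag.COUNTS,
                          *, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a dense TSV with gene rows, cell columns and a leading id column."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    values = sparse.csr_matrix(df.to_numpy(dtype=float))
    return ExpressionMatrix(tuple(map(str, df.index)),
                            tuple(map(str, df.columns)), values, layer_tag)


def write_expression_dense(expr: ExpressionMatrix, path: str | Path,
                           *, delimiter: str = "\t") -> None:
    df = pd.DataFrame(expr.values.toarray(), index=list(expr.gene_ids),
                      columns=list(expr.cell_ids))
    df.to_csv(path, sep=delimiter, index_label="gene")


def read_cell_annotation(path: str | Path, *,
                         delimiter: str = "\t") -> CellAnnotation:
    """Read per-cell metadata; first column is the cell id."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.map(str)
    if "pseudotime" in df.columns:
        df["pseudotime"] = pd.to_numeric(df["pseudotime"], errors="coerce")
    return CellAnnotation(df)


def write_cell_annotation(ann: CellAnnotation, path: str | Path, *,
                          delimiter: str = "\t") -> None:
    ann.frame.to_csv(path, sep=delimiter, index_label="cell_id")
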