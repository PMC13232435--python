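"""Readers and writers for the pipeline's delimited-text interchange formats.

TSV with '.' decimals and UTF-8 is the canonical format; sparse expression
may be exchanged as a MatrixMarket coordinate file with row/column name
sidecars (``<stem>.rows.txt`` / ``<stem>.cols.txt``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ValidationError

__all__ = ["read_cell_table", "read_matrix", "write_matrix"]

REQUIRED_CELL_COLUMNS = ("cell_id", "sample_id", "group", "subcluster")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a cell annotation TSV.

    Requires columns cell_id, sample_id, group, subcluster; lineage and
    is_denominator are optional. Duplicate cell ids or missing values in
    required columns are errors.
    """
    path = Path(path)
    try:
        cells = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty cell table: {path}") from None
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValidationError(f"cell table missing required column(s): {missing}")
    if cells.empty:
        raise ValidationError(f"cell table has no rows: {path}")
    dup = cells["cell_id"][cells["cell_id"].duplicated()]
    if len(dup):
        raise ValidationError(
            "duplicate cell_id(s): " + ", ".join(map(str, dup.unique()[:10]))
        )
    for col in REQUIRED_CELL_COLUMNS:
        if cells[col].isna().any():
            raise ValidationError(f"missing values in required column {col!r}")
    if "is_denominator" in cells.columns:
        cells["is_denominator"] = cells["is_denominator"].astype(bool)
    return cells


def _sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".rows.txt"), stem.with_suffix(".cols.txt")


def read_matrix(path: str | Path, kind: str = "dense_tsv") -> pd.DataFrame:
    """Read a named matrix: dense TSV or MatrixMarket triplet + sidecars.

    In MatrixMarket form, entries absent from the triplet file materialize
    as explicit zeros for the named rows/columns.
    """
    path = Path(path)
    if kind == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return df
    if kind == "matrixmarket":
        rows_f, cols_f = _sidecars(path)
        for f in (rows_f, cols_f):
            if not f.exists():
                raise ValidationError(f"missing sidecar name file: {f}")
        rows = rows_f.read_text().splitlines()
        cols = cols_f.read_text().splitlines()
        M = scipy.io.mmread(path)
        M = scipy.sparse.coo_matrix(M).toarray()
        if M.shape != (len(rows), len(cols)):
            raise ValidationError(
                f"matrix shape {M.shape} does not match sidecar names "
                f"({len(rows)} rows, {len(cols)} cols)"
            )
        return pd.DataFrame(M, index=rows, columns=cols)
    raise ValidationError(f"unknown matrix kind {kind!r}")


def write_matrix(df: pd.DataFrame, path: str | Path, kind: str = "dense_tsv") -> None:
    """Write a named matrix in the format :func:`read_matrix` reads back."""
    path = Path(path)
    if kind == "dense_tsv":
        df.to_csv(path, sep="\t")
        return
    if kind == "matrixmarket":
        rows_f, cols_f = _sidecars(path)
        rows_f.write_text("\n".join(map(str, df.index)) + "\n")
        cols_f.write_text("\n".join(map(str, df.columns)) + "\n")
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(df.to_numpy()))
        return
    raise ValidationError(f"unknown matrix kind {kind!r}")
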