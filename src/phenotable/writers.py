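"""Writers: serialize harmonized tables with exact type preservation.

Parquet is the primary format (columnar, compressed, schema-embedding);
CSV, SQLite, and an AnnData H5AD annotated-matrix layout cover downstream
tools that expect them.  Every writer returns a :class:`WriteReport` whose
row/column counts must match the table written.

The SQLite writer deliberately enforces the engine's default 2,000-column
limit rather than raising it: wide morphology tables genuinely do not fit
this format under default settings, and hiding that would misrepresent the
output's portability.
"""

from __future__ import annotations

import csv
import sqlite3
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.parquet as pq

from .model import (
    ColumnLimitError,
    PhenotableError,
    TableChunk,
    ensure_path,
)

__all__ = [
    "WriteReport",
    "write_parquet",
    "read_parquet_table",
    "write_csv",
    "write_sqlite",
    "write_annotated_matrix",
    "write_table",
    "SQLITE_DEFAULT_MAX_COLUMNS",
    "FORMAT_EXTENSIONS",
]

#: SQLite's compiled-in default column limit.
SQLITE_DEFAULT_MAX_COLUMNS = 2000

_PARQUET_COMPRESSIONS = {
    "none": None,
    "snappy-class": "snappy",
    "zstd-class": "zstd",
    "gzip-class": "gzip",
}

FORMAT_EXTENSIONS = {
    "parquet": ".parquet",
    "csv": ".csv",
    "sqlite": ".sqlite",
    "h5ad": ".h5ad",
}


@dataclass(frozen=True)
class WriteReport:
    path: str
    format: str
    rows_written: int
    columns_written: int
    compression: str = "none"
    byte_size: int = 0


def _report(path: Path, fmt: str, table: TableChunk, compression="none") -> WriteReport:
    return WriteReport(
        path=str(path),
        format=fmt,
        rows_written=table.row_count,
        columns_written=len(table.schema),
        compression=compression,
        byte_size=path.stat().st_size,
    )


def write_parquet(
    table: TableChunk, path, compression: str = "snappy-class"
) -> WriteReport:
    """Write a table to Parquet with the declared schema embedded.

    Read-back via :func:`read_parquet_table` yields identical values,
    declared types, column order, and row order.
    """
    path = ensure_path(path)
    if compression not in _PARQUET_COMPRESSIONS:
        raise PhenotableError(
            f"unknown compression {compression!r}; "
            f"choose from {sorted(_PARQUET_COMPRESSIONS)}"
        )
    pq.write_table(
        table.attach_metadata(), path, compression=_PARQUET_COMPRESSIONS[compression]
    )
    return _report(path, "parquet", table, compression)


def read_parquet_table(path) -> TableChunk:
    """Load a Parquet file written by :func:`write_parquet`."""
    return TableChunk.from_arrow(pq.read_table(ensure_path(path)))


def write_csv(table: TableChunk, path) -> WriteReport:
    """Write RFC 4180 CSV with a header row; nulls become empty fields.

    Floats are written with ``repr`` so the decimal text round-trips to
    the identical binary value when read back against the same schema.
    """
    path = ensure_path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n")
        writer.writerow(table.column_names)
        for row in table.table.to_pylist():
            out = []
            for col in table.schema:
                v = row[col.name]
                if v is None:
                    out.append("")
                elif col.declared_type == "float-feature":
                    out.append(repr(float(v)))
                elif col.declared_type == "boolean":
                    out.append("True" if v else "False")
                else:
                    out.append(v)
            writer.writerow(out)
    return _report(path, "csv", table)


_SQLITE_TYPES = {
    "integer-key": "INTEGER",
    "float-feature": "REAL",
    "boolean": "INTEGER",
    "text": "TEXT",
}


def write_sqlite(table: TableChunk, path, table_name: str = "harmonized") -> WriteReport:
    """Write a single-table SQLite database with affine declared types.

    Raises :class:`ColumnLimitError` beyond the engine's default maximum
    of 2,000 columns; exactly 2,000 columns succeeds.
    """
    n_cols = len(table.schema)
    if n_cols > SQLITE_DEFAULT_MAX_COLUMNS:
        raise ColumnLimitError(
            f"table has {n_cols} columns; SQLite's default maximum column "
            f"length is {SQLITE_DEFAULT_MAX_COLUMNS}"
        )
    path = ensure_path(path)
    if path.exists():
        path.unlink()
    conn = sqlite3.connect(path)
    try:
        cols_sql = ", ".join(
            f'"{c.name}" {_SQLITE_TYPES[c.declared_type]}' for c in table.schema
        )
        conn.execute(f'CREATE TABLE "{table_name}" ({cols_sql})')
        placeholders = ", ".join("?" for _ in table.schema)
        rows = (
            tuple(row[c.name] for c in table.schema)
            for row in table.table.to_pylist()
        )
        conn.executemany(f'INSERT INTO "{table_name}" VALUES ({placeholders})', rows)
        conn.commit()
    finally:
        conn.close()
    return _report(path, "sqlite", table)


def write_annotated_matrix(table: TableChunk, path) -> WriteReport:
    """Write an AnnData H5AD container: features as X, keys/metadata as obs.

    Float-feature columns form the numeric matrix (rows = cells; nulls
    stored as NaN, since dense numeric matrices have no distinct null);
    every other column becomes a per-row annotation.  The split is a
    partition — each column lands on exactly one side.
    """
    import anndata as ad

    path = ensure_path(path)
    feature_cols = [c for c in table.schema if c.declared_type == "float-feature"]
    if not feature_cols:
        raise PhenotableError(
            "nothing to matrix: table has no float-feature columns"
        )
    obs_cols = [c for c in table.schema if c.declared_type != "float-feature"]

    n = table.row_count
    X = np.empty((n, len(feature_cols)), dtype=np.float64)
    for j, col in enumerate(feature_cols):
        arr = table.table.column(col.name).to_numpy(zero_copy_only=False)
        X[:, j] = np.asarray(arr, dtype=np.float64)

    obs = pd.DataFrame(index=pd.RangeIndex(n).astype(str))
    for col in obs_cols:
        values = table.table.column(col.name).to_pylist()
        if col.declared_type == "integer-key":
            obs[col.name] = pd.array(values, dtype="Int64")
        elif col.declared_type == "boolean":
            obs[col.name] = pd.array(values, dtype="boolean")
        else:
            obs[col.name] = pd.array(
                ["" if v is None else v for v in values], dtype=object
            )
    var = pd.DataFrame(index=pd.Index([c.name for c in feature_cols], name="feature"))
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.write_h5ad(path)
    return WriteReport(
        path=str(path),
        format="annotated-matrix",
        rows_written=n,
        columns_written=len(table.schema),
        byte_size=path.stat().st_size,
    )


def write_table(
    table: TableChunk,
    path,
    fmt: str,
    *,
    compression: str = "snappy-class",
    table_name: str = "harmonized",
) -> WriteReport:
    """Format-dispatching writer used by the orchestrator and CLI."""
    if fmt == "parquet":
        return write_parquet(table, path, compression)
    if fmt == "csv":
        return write_csv(table, path)
    if fmt == "sqlite":
        return write_sqlite(table, path, table_name)
    if fmt in ("h5ad", "annotated-matrix"):
        return write_annotated_matrix(table, path)
    raise PhenotableError(
        f"unknown output format {fmt!r}; choose from parquet, csv, sqlite, h5ad"
    )
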