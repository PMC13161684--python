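"""Readers: typed, paged ingestion of delimited text, SQLite, and NPZ sources.

Reading is two-pass.  A first pass (:func:`scan_column_types`) resolves every
column to an unambiguous declared type, because both delimited text and
SQLite's affinity typing permit stray strings inside otherwise numeric
columns.  The second pass reads fixed-size pages and casts values against the
resolved schema, either failing fast (``strict-fail``) or nulling stray
values and counting the coercions (``coerce-null``).

Pages are half-open row ranges in file order (delimited) or rowid order
(SQLite), so concatenating all pages of a source at any page size reproduces
the full table exactly.
"""

from __future__ import annotations

import csv
import logging
import sqlite3
import time
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pyarrow as pa

from .model import (
    ArchiveError,
    CastError,
    ColumnSchema,
    MalformedRecordError,
    METADATA_PREFIX,
    MixedTypeError,
    NA_TOKENS,
    PhenotableError,
    Preset,
    SourceSpec,
    TableChunk,
    arrow_type,
)

logger = logging.getLogger(__name__)

__all__ = [
    "scan_column_types",
    "read_delimited_chunk",
    "read_sqlite_chunk",
    "read_array_archive",
    "read_chunk",
    "count_rows",
]

_BOOL_TOKENS = {"true": True, "false": False}


def _is_identifying(name: str, preset: Preset) -> bool:
    return name in preset.identifying_columns or name.startswith(METADATA_PREFIX)


def _try_int(token: str) -> Optional[int]:
    try:
        return int(token)
    except ValueError:
        try:
            f = float(token)
        except ValueError:
            return None
        return int(f) if f.is_integer() else None


def _try_float(token: str) -> Optional[float]:
    try:
        return float(token)
    except ValueError:
        return None


def _dialect_for(path: Path) -> str:
    return "\t" if path.suffix.lower() == ".tsv" else ","


# ---------------------------------------------------------------------------
# Pass 1: type resolution
# ---------------------------------------------------------------------------


class _ColumnStats:
    """Accumulates value-class counts for one physical column."""

    __slots__ = (
        "name", "n_nonnull", "n_null", "n_int", "n_float",
        "n_bool", "n_text", "first_text_row",
    )

    def __init__(self, name: str):
        self.name = name
        self.n_nonnull = 0
        self.n_null = 0
        self.n_int = 0
        self.n_float = 0  # numeric incl. integers
        self.n_bool = 0
        self.n_text = 0
        self.first_text_row: Optional[int] = None

    def add_token(self, token: str, row_1based: int) -> None:
        if token in NA_TOKENS:
            self.n_null += 1
            return
        self.n_nonnull += 1
        if token.lower() in _BOOL_TOKENS:
            self.n_bool += 1
            return
        if _try_float(token) is not None:
            self.n_float += 1
            if _try_int(token) is not None:
                self.n_int += 1
            return
        self.n_text += 1
        if self.first_text_row is None:
            self.first_text_row = row_1based

    def add_value(self, value, row_1based: int) -> None:
        """Classify an already-typed (SQLite) value."""
        if value is None:
            self.n_null += 1
        elif isinstance(value, bool):
            self.n_nonnull += 1
            self.n_bool += 1
        elif isinstance(value, int):
            self.n_nonnull += 1
            self.n_float += 1
            self.n_int += 1
        elif isinstance(value, float):
            self.n_nonnull += 1
            self.n_float += 1
            if value.is_integer():
                self.n_int += 1
        else:
            self.add_token(str(value), row_1based)

    def resolve(self, preset: Preset, origin: str) -> ColumnSchema:
        nullable = self.n_null > 0
        identifying = _is_identifying(self.name, preset)
        if self.n_nonnull == 0:
            dt = "integer-key" if identifying else "text"
            return ColumnSchema(self.name, dt, nullable=True, origin_table=origin)
        if self.n_bool == self.n_nonnull:
            return ColumnSchema(self.name, "boolean", nullable, origin)
        if identifying and self.n_int == self.n_nonnull:
            return ColumnSchema(self.name, "integer-key", nullable, origin)
        if self.n_float == self.n_nonnull:
            return ColumnSchema(self.name, "float-feature", nullable, origin)
        # mixed content
        numeric_fraction = self.n_float / self.n_nonnull
        if numeric_fraction > 0.5:
            if preset.type_policy == "strict-fail":
                raise MixedTypeError(
                    f"mixed-type column {self.name!r}: first non-numeric value "
                    f"at row {self.first_text_row}"
                )
            return ColumnSchema(self.name, "float-feature", nullable=True, origin_table=origin)
        return ColumnSchema(self.name, "text", nullable, origin)


def scan_column_types(source: SourceSpec, preset: Preset) -> List[ColumnSchema]:
    """Resolve one unambiguous :class:`ColumnSchema` per physical column.

    A column is ``integer-key`` when every non-null value parses as an
    integer *and* its name is one of the preset's identifying columns;
    ``float-feature`` when every non-null value is numeric; ``text``
    otherwise — except that under ``coerce-null`` a numeric-majority column
    (>50% of non-null values numeric) containing stray text resolves to a
    nullable ``float-feature``.  Under ``strict-fail`` such mixed columns
    raise :class:`MixedTypeError` naming the first offending row.
    """
    if source.kind == "delimited-text":
        return _scan_delimited(source, preset)
    if source.kind == "sqlite-db":
        return _scan_sqlite(source, preset)
    if source.kind == "array-archive":
        schema, _, _ = _load_archive(source, preset.feature_name_prefix)
        return schema
    raise PhenotableError(f"unknown source kind {source.kind!r}")


def _scan_delimited(source: SourceSpec, preset: Preset) -> List[ColumnSchema]:
    path = Path(source.path)
    origin = source.role or source.table_name
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=_dialect_for(path))
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise MalformedRecordError(f"{path} has no header row") from None
        stats = [_ColumnStats(name) for name in header]
        for i, row in enumerate(reader, start=1):
            if len(row) != len(header):
                raise MalformedRecordError(
                    f"{path} line {i + 1}: expected {len(header)} fields, got {len(row)}"
                )
            for st, token in zip(stats, row):
                st.add_token(token, i)
    return [st.resolve(preset, origin) for st in stats]


def _sqlite_connect(path: str) -> sqlite3.Connection:
    last: Exception | None = None
    for _ in range(3):
        try:
            return sqlite3.connect(f"file:{path}?mode=ro", uri=True, timeout=5.0)
        except sqlite3.OperationalError as exc:  # pragma: no cover - retry path
            last = exc
            time.sleep(0.1)
    raise PhenotableError(f"cannot open database {path}: {last}")


def _sqlite_columns(conn: sqlite3.Connection, table: str) -> list[str]:
    rows = conn.execute(f'PRAGMA table_info("{table}")').fetchall()
    if not rows:
        catalog = [
            r[0]
            for r in conn.execute(
                "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name"
            )
        ]
        raise PhenotableError(
            f"table {table!r} not found; database contains: {', '.join(catalog)}"
        )
    return [r[1] for r in rows]


def _scan_sqlite(source: SourceSpec, preset: Preset) -> List[ColumnSchema]:
    origin = source.role or source.table_name
    conn = _sqlite_connect(source.path)
    try:
        cols = _sqlite_columns(conn, source.table_name)
        stats = [_ColumnStats(name) for name in cols]
        sel = ", ".join(f'"{c}"' for c in cols)
        cursor = conn.execute(
            f'SELECT {sel} FROM "{source.table_name}" ORDER BY rowid'
        )
        for i, row in enumerate(cursor, start=1):
            for st, value in zip(stats, row):
                st.add_value(value, i)
    finally:
        conn.close()
    return [st.resolve(preset, origin) for st in stats]


# ---------------------------------------------------------------------------
# Pass 2: paged reads
# ---------------------------------------------------------------------------


def _cast_cell(token, col: ColumnSchema, policy: str, row_1based: int,
               na_coerces: bool = False):
    """Cast one raw value; returns (value, n_coercions).

    ``na_coerces`` distinguishes delimited text (where NA tokens are the
    format's native way of spelling null — not coercions) from SQLite
    (where a text value stored in a numeric-declared column is a
    storage-class conflict and counts as a coercion).
    """
    if token is None:
        return None, 0
    if isinstance(token, str):
        if col.declared_type == "text":
            if not na_coerces and token in NA_TOKENS:
                return None, 0
            return token, 0
        if token in NA_TOKENS:
            return None, (1 if na_coerces else 0)
        if col.declared_type == "boolean":
            low = token.lower()
            if low in _BOOL_TOKENS:
                return _BOOL_TOKENS[low], 0
        elif col.declared_type == "integer-key":
            v = _try_int(token)
            if v is not None:
                return v, 0
        elif col.declared_type == "float-feature":
            v = _try_float(token)
            if v is not None:
                return v, 0
        if policy == "strict-fail":
            raise CastError(
                f"cannot cast {token!r} to {col.declared_type} in column "
                f"{col.name!r} at row {row_1based}"
            )
        return None, 1
    # already-typed (SQLite / archive) values
    if col.declared_type == "integer-key":
        if isinstance(token, bool):
            token = int(token)
        if isinstance(token, int):
            return token, 0
        if isinstance(token, float):
            if token.is_integer():
                return int(token), 0
            raise CastError(
                f"non-integral value {token!r} in integer-key column {col.name!r} "
                f"at row {row_1based}"
            )
    elif col.declared_type == "float-feature":
        if isinstance(token, (int, float)) and not isinstance(token, bool):
            return float(token), 0
    elif col.declared_type == "boolean":
        if isinstance(token, bool):
            return token, 0
        if isinstance(token, int):
            return bool(token), 0
    elif col.declared_type == "text":
        return str(token), 0
    if policy == "strict-fail":
        raise CastError(
            f"cannot cast {token!r} to {col.declared_type} in column "
            f"{col.name!r} at row {row_1based}"
        )
    return None, 1


def _rows_to_chunk(
    rows: list[Sequence],
    schema: Sequence[ColumnSchema],
    source: SourceSpec,
    offset: int,
    policy: str,
    na_coerces: bool = False,
) -> TableChunk:
    coercions = 0
    columns: list[list] = [[] for _ in schema]
    for r, row in enumerate(rows):
        for j, col in enumerate(schema):
            value, n = _cast_cell(row[j], col, policy, offset + r + 1, na_coerces)
            coercions += n
            columns[j].append(value)
    arrays = [
        pa.array(values, type=arrow_type(col)) for values, col in zip(columns, schema)
    ]
    fields = [pa.field(c.name, a.type, nullable=True) for c, a in zip(schema, arrays)]
    table = pa.Table.from_arrays(arrays, schema=pa.schema(fields))
    return TableChunk(
        schema=list(schema), table=table, source=source, offset=offset,
        coercions=coercions,
    )


def read_delimited_chunk(
    source: SourceSpec,
    schema: Sequence[ColumnSchema],
    offset: int,
    limit: int,
    *,
    type_policy: str = "coerce-null",
) -> TableChunk:
    """Read data rows ``[offset, offset + limit)`` of a delimited file.

    The header row is mandatory and not counted.  A short (or empty) final
    page is allowed; the schema is preserved even for zero-row pages.
    """
    path = Path(source.path)
    names = [c.name for c in schema]
    rows: list[list] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=_dialect_for(path))
        header = [h.strip() for h in next(reader)]
        if header != names:
            raise MalformedRecordError(
                f"{path}: header does not match resolved schema"
            )
        for i, row in enumerate(reader):
            if len(row) != len(names):
                raise MalformedRecordError(
                    f"{path} line {i + 2}: expected {len(names)} fields, got {len(row)}"
                )
            if i >= offset + limit:
                break
            if i >= offset:
                rows.append(row)
    return _rows_to_chunk(rows, schema, source, offset, type_policy)


def read_sqlite_chunk(
    source: SourceSpec,
    schema: Sequence[ColumnSchema],
    offset: int,
    limit: int,
    *,
    type_policy: str = "coerce-null",
) -> TableChunk:
    """Read rows ``[offset, offset + limit)`` of a SQLite table, rowid order.

    SQLite's affinity typing allows text in numeric-declared columns; such
    values are treated as mixed values and resolved per the type policy.
    """
    conn = _sqlite_connect(source.path)
    try:
        _sqlite_columns(conn, source.table_name)  # raises if table missing
        sel = ", ".join(f'"{c.name}"' for c in schema)
        rows = conn.execute(
            f'SELECT {sel} FROM "{source.table_name}" ORDER BY rowid '
            f"LIMIT ? OFFSET ?",
            (limit, offset),
        ).fetchall()
    finally:
        conn.close()
    return _rows_to_chunk(rows, schema, source, offset, type_policy, na_coerces=True)


# ---------------------------------------------------------------------------
# Array archives (DeepProfiler-style NPZ)
# ---------------------------------------------------------------------------


def _load_archive(source: SourceSpec, feature_prefix: str):
    """Return (schema, metadata arrays, feature matrix) for an NPZ archive."""
    with np.load(source.path, allow_pickle=False) as npz:
        members = list(npz.files)
        feature_member = None
        if "features" in members:
            feature_member = "features"
        else:
            for m in members:
                if npz[m].ndim == 2 and np.issubdtype(npz[m].dtype, np.number):
                    feature_member = m
                    break
        if feature_member is None:
            raise ArchiveError(
                f"{source.path}: no feature matrix (no 2-D numeric array member)"
            )
        features = np.asarray(npz[feature_member])
        n_rows, n_features = features.shape
        origin = source.role or source.table_name

        schema: list[ColumnSchema] = []
        meta_arrays: list[np.ndarray] = []
        for m in members:
            if m == feature_member:
                continue
            arr = np.asarray(npz[m])
            if arr.ndim != 1:
                continue
            if arr.shape[0] != n_rows:
                raise ArchiveError(
                    f"{source.path}: ragged archive — feature rows {n_rows} vs "
                    f"metadata member {m!r} length {arr.shape[0]}"
                )
            if np.issubdtype(arr.dtype, np.integer):
                dt = "integer-key"
            elif np.issubdtype(arr.dtype, np.floating):
                dt = "float-feature"
            else:
                dt = "text"
            schema.append(ColumnSchema(m, dt, nullable=False, origin_table=origin))
            meta_arrays.append(arr)

        width = len(str(max(n_features - 1, 0)))
        for i in range(n_features):
            schema.append(
                ColumnSchema(
                    f"{feature_prefix}_{str(i).zfill(width)}",
                    "float-feature",
                    nullable=False,
                    origin_table=origin,
                )
            )
        return schema, meta_arrays, features


def read_array_archive(
    source: SourceSpec,
    feature_prefix: str,
    *,
    offset: int = 0,
    limit: Optional[int] = None,
) -> TableChunk:
    """Read an NPZ archive of per-cell feature vectors into one chunk.

    Feature column ``i`` is named ``<feature_prefix>_<i>`` with the index
    zero-padded to the width of the largest index, so lexicographic and
    numeric orderings agree.  1-D metadata members of matching length
    become text/integer columns under their member names.
    """
    schema, meta_arrays, features = _load_archive(source, feature_prefix)
    n_rows = features.shape[0]
    stop = n_rows if limit is None else min(n_rows, offset + limit)
    sel = slice(offset, max(stop, offset))

    arrays: list[pa.Array] = []
    n_meta = len(meta_arrays)
    for col, arr in zip(schema[:n_meta], meta_arrays):
        part = arr[sel]
        if col.declared_type == "text":
            part = [str(v) for v in part]
        arrays.append(pa.array(part, type=arrow_type(col)))
    feat = features[sel].astype(np.float64, copy=False)
    for i, col in enumerate(schema[n_meta:]):
        arrays.append(pa.array(feat[:, i], type=arrow_type(col)))
    fields = [pa.field(c.name, a.type, nullable=True) for c, a in zip(schema, arrays)]
    table = pa.Table.from_arrays(arrays, schema=pa.schema(fields))
    return TableChunk(schema=list(schema), table=table, source=source, offset=offset)


# ---------------------------------------------------------------------------
# Dispatch helpers used by the orchestrator
# ---------------------------------------------------------------------------


def read_chunk(
    source: SourceSpec,
    schema: Sequence[ColumnSchema],
    offset: int,
    limit: int,
    preset: Preset,
) -> TableChunk:
    """Kind-dispatching paged read."""
    if source.kind == "delimited-text":
        return read_delimited_chunk(
            source, schema, offset, limit, type_policy=preset.type_policy
        )
    if source.kind == "sqlite-db":
        return read_sqlite_chunk(
            source, schema, offset, limit, type_policy=preset.type_policy
        )
    if source.kind == "array-archive":
        return read_array_archive(
            source, preset.feature_name_prefix, offset=offset, limit=limit
        )
    raise PhenotableError(f"unknown source kind {source.kind!r}")


def count_rows(source: SourceSpec) -> int:
    """Data row count of a source (excludes delimited headers)."""
    if source.declared_row_count is not None:
        return source.declared_row_count
    if source.kind == "delimited-text":
        path = Path(source.path)
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter=_dialect_for(path))
            n = sum(1 for _ in reader)
        return max(n - 1, 0)
    if source.kind == "sqlite-db":
        conn = _sqlite_connect(source.path)
        try:
            _sqlite_columns(conn, source.table_name)
            (n,) = conn.execute(
                f'SELECT COUNT(*) FROM "{source.table_name}"'
            ).fetchone()
        finally:
            conn.close()
        return int(n)
    if source.kind == "array-archive":
        with np.load(source.path, allow_pickle=False) as npz:
            for m in npz.files:
                arr = npz[m]
                if arr.ndim == 2 and np.issubdtype(arr.dtype, np.number):
                    return int(arr.shape[0])
        raise ArchiveError(f"{source.path}: no feature matrix")
    raise PhenotableError(f"unknown source kind {source.kind!r}")
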