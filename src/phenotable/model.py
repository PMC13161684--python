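"""Shared data model for the harmonization pipeline.

The pipeline moves single-cell morphology measurements from heterogeneous
image-analysis exports (delimited text, SQLite databases, NumPy array
archives) into one analysis-ready table per source group.  Everything in
flight is a :class:`TableChunk`: a typed, column-major page of rows backed
by a :class:`pyarrow.Table`, so types survive every hop between disk and
memory.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import pyarrow as pa

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class PhenotableError(Exception):
    """Base class for all package errors."""


class UnknownPresetError(PhenotableError, KeyError):
    pass


class PresetValidationError(PhenotableError, ValueError):
    pass


class UnsupportedFormatError(PhenotableError, ValueError):
    pass


class EmptySourceSetError(PhenotableError, FileNotFoundError):
    pass


class MixedTypeError(PhenotableError, ValueError):
    """A column mixes text and numeric values under the strict-fail policy."""


class MalformedRecordError(PhenotableError, ValueError):
    """A delimited row has the wrong number of fields."""


class CastError(PhenotableError, ValueError):
    pass


class ColumnCollisionError(PhenotableError, ValueError):
    pass


class SchemaConflictError(PhenotableError, ValueError):
    """Irreconcilable declared types for the same column name."""


class AlignmentError(PhenotableError, ValueError):
    pass


class JoinCompileError(PhenotableError, ValueError):
    pass


class ColumnLimitError(PhenotableError, ValueError):
    """Output engine cannot hold this many columns."""


class ArchiveError(PhenotableError, ValueError):
    """Malformed array archive (missing feature matrix or ragged metadata)."""


class TaskExecutionError(PhenotableError, RuntimeError):
    """A task in the work plan failed; carries the task id and root cause."""

    def __init__(self, task_id: str, cause: BaseException):
        super().__init__(f"task {task_id!r} failed: {cause}")
        self.task_id = task_id
        self.cause = cause


# ---------------------------------------------------------------------------
# Enumerations (plain string literals, sklearn/scanpy style)
# ---------------------------------------------------------------------------

SourceKind = Literal["delimited-text", "sqlite-db", "array-archive"]
SOURCE_KINDS: tuple[str, ...] = ("delimited-text", "sqlite-db", "array-archive")

DeclaredType = Literal["integer-key", "float-feature", "text", "boolean"]
JoinKind = Literal["inner", "left"]
TypePolicy = Literal["strict-fail", "coerce-null"]
FloatWidth = Literal[4, 8]

#: Extension → source kind mapping (case-insensitive).
EXTENSION_KINDS: dict[str, str] = {
    ".csv": "delimited-text",
    ".tsv": "delimited-text",
    ".sqlite": "sqlite-db",
    ".db": "sqlite-db",
    ".npz": "array-archive",
}

#: Values read from delimited text that denote a missing value.
NA_TOKENS = frozenset({"", "NA", "NaN", "nan"})

#: Prefix applied to identifying (key/metadata) columns.
METADATA_PREFIX = "Metadata_"


# ---------------------------------------------------------------------------
# Source description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SourceSpec:
    """One discovered input: a file, or one table inside a database file.

    Parameters
    ----------
    path
        Filesystem location of the file holding the data.
    kind
        One of ``delimited-text``, ``sqlite-db``, ``array-archive``.
    table_name
        SQLite table name, compartment name inferred from the filename, or
        archive identifier.
    group_key
        Plate/directory identifier; sources sharing a group are joined
        together.
    declared_row_count
        Row count if known ahead of reading (used for page planning).
    role
        Compartment role assigned from the preset's table selectors
        (e.g. ``image``, ``cells``); empty until discovery assigns one.
    """

    path: str
    kind: str
    table_name: str
    group_key: str
    declared_row_count: Optional[int] = None
    role: str = ""

    def __post_init__(self) -> None:
        if not self.table_name:
            raise ValueError("SourceSpec.table_name must be non-empty")
        if not self.group_key:
            raise ValueError("SourceSpec.group_key must be non-empty")
        if self.kind not in SOURCE_KINDS:
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.declared_row_count is not None and self.declared_row_count < 0:
            raise ValueError("declared_row_count must be nonnegative")


@dataclass(frozen=True)
class JoinClause:
    """One equality condition linking two compartment tables.

    Composite keys are expressed as consecutive clauses sharing the same
    (left_table, right_table, join_kind); the join compiler groups them
    into a single join step.
    """

    left_table: str
    left_column: str
    right_table: str
    right_column: str
    join_kind: str = "left"

    def __post_init__(self) -> None:
        for f in ("left_table", "left_column", "right_table", "right_column"):
            if not getattr(self, f):
                raise ValueError(f"JoinClause.{f} must be non-empty")
        if self.left_table == self.right_table:
            raise ValueError("JoinClause cannot join a table to itself")
        if self.join_kind not in ("inner", "left"):
            raise ValueError(f"unknown join kind {self.join_kind!r}")


@dataclass
class Preset:
    """Named configuration bundle mapping a known export layout to a plan.

    Attributes
    ----------
    name : str
        Registry name.
    source_kind : str
        Kind of file(s) the preset reads.
    table_selectors : dict[str, str]
        compartment-role → filename/table glob pattern (case-insensitive on
        stems).
    base_table : str
        Role whose rows define the output grain (one row per base object).
    identifying_columns : list[str]
        Column names treated as metadata keys rather than features.
    joins : list[JoinClause]
        Ordered join conditions; empty for single-table layouts.
    chunk_size : int
        Page size, in rows, for chunked reads and key-paged joins.
    type_policy : str
        ``strict-fail`` (mixed columns raise) or ``coerce-null`` (stray text
        in numeric-majority columns becomes null, counted).
    float_width : int
        4 or 8 bytes for feature storage.
    feature_name_prefix : str
        Name stem for unnamed feature columns read from array archives.
    """

    name: str
    source_kind: str
    table_selectors: dict[str, str]
    base_table: str
    identifying_columns: list[str]
    joins: list[JoinClause] = field(default_factory=list)
    chunk_size: int = 100_000
    type_policy: str = "coerce-null"
    float_width: int = 8
    feature_name_prefix: str = "Feature"

    def copy(self) -> "Preset":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class ColumnSchema:
    """Declared type and provenance of one column."""

    name: str
    declared_type: str
    nullable: bool = False
    origin_table: str = ""

    def with_name(self, name: str) -> "ColumnSchema":
        return dataclasses.replace(self, name=name)

    def as_nullable(self) -> "ColumnSchema":
        return dataclasses.replace(self, nullable=True)


#: Promotion lattice for schema unification.
TYPE_ORDER = {"boolean": 0, "integer-key": 1, "float-feature": 2, "text": 3}


def arrow_type(schema: ColumnSchema, float_width: int = 8) -> pa.DataType:
    """Arrow storage type for a declared column type."""
    if schema.declared_type == "integer-key":
        return pa.int64()
    if schema.declared_type == "float-feature":
        return pa.float32() if float_width == 4 else pa.float64()
    if schema.declared_type == "boolean":
        return pa.bool_()
    if schema.declared_type == "text":
        return pa.string()
    raise ValueError(f"unknown declared type {schema.declared_type!r}")


# ---------------------------------------------------------------------------
# TableChunk — the universal in-flight unit
# ---------------------------------------------------------------------------

_SCHEMA_META_KEY = b"phenotable_schema"


@dataclass
class TableChunk:
    """A typed, column-major page of rows with provenance.

    Wraps a :class:`pyarrow.Table` (the columnar payload) plus the declared
    per-column schema, the originating source and row offset, and the count
    of values coerced to null while reading.
    """

    schema: list[ColumnSchema]
    table: pa.Table
    source: Optional[SourceSpec] = None
    offset: int = 0
    coercions: int = 0

    def __post_init__(self) -> None:
        names = [c.name for c in self.schema]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ColumnCollisionError(f"duplicate column names: {dupes}")
        if list(self.table.column_names) != names:
            raise ValueError("arrow table columns do not match declared schema")

    @property
    def row_count(self) -> int:
        return self.table.num_rows

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.schema]

    def schema_by_name(self) -> dict[str, ColumnSchema]:
        return {c.name: c for c in self.schema}

    def to_pylist(self) -> list[dict]:
        return self.table.to_pylist()

    # -- spill helpers ------------------------------------------------------

    def attach_metadata(self) -> pa.Table:
        """Arrow table with the declared schema embedded as JSON metadata."""
        payload = json.dumps(
            {
                "columns": [dataclasses.asdict(c) for c in self.schema],
                "coercions": self.coercions,
                "offset": self.offset,
            }
        ).encode()
        meta = dict(self.table.schema.metadata or {})
        meta[_SCHEMA_META_KEY] = payload
        return self.table.replace_schema_metadata(meta)

    @classmethod
    def from_arrow(
        cls,
        table: pa.Table,
        schema: Optional[Sequence[ColumnSchema]] = None,
        **kw,
    ) -> "TableChunk":
        """Build a chunk from an arrow table, recovering embedded metadata."""
        if schema is None:
            meta = table.schema.metadata or {}
            if _SCHEMA_META_KEY not in meta:
                raise ValueError("arrow table carries no embedded column schema")
            payload = json.loads(meta[_SCHEMA_META_KEY])
            schema = [ColumnSchema(**c) for c in payload["columns"]]
            kw.setdefault("coercions", payload.get("coercions", 0))
            kw.setdefault("offset", payload.get("offset", 0))
        return cls(schema=list(schema), table=table.replace_schema_metadata(None), **kw)


@dataclass
class HarmonizedTable(TableChunk):
    """Joined output at one-row-per-base-object grain with unified schema."""

    grain: str = ""
    key_columns: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def empty_arrow_table(
    schema: Sequence[ColumnSchema], float_width: int = 8
) -> pa.Table:
    """Zero-row arrow table matching a declared schema."""
    fields = [
        pa.field(c.name, arrow_type(c, float_width), nullable=True) for c in schema
    ]
    return pa.Table.from_arrays(
        [pa.array([], type=f.type) for f in fields], schema=pa.schema(fields)
    )


def ensure_path(p) -> Path:
    return p if isinstance(p, Path) else Path(p)
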