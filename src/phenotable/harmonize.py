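"""Structural harmonization: consistent names, strict types, unified schemas.

Naming follows the downstream image-based-profiling convention: identifying
(key) columns carry the ``Metadata_`` prefix, every other column carries a
capitalized compartment prefix (``Cells_``, ``Nuclei_``, ``Cytoplasm_``,
``Image_``, or any preset-declared role).  Prefixing is idempotent — a
column is never double-prefixed — so re-running harmonization is a no-op.

Harmonization here is structural, not semantic: feature names are never
translated between tools.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Sequence

import pyarrow as pa
import pyarrow.compute as pc

from .model import (
    AlignmentError,
    CastError,
    ColumnCollisionError,
    ColumnSchema,
    METADATA_PREFIX,
    Preset,
    SchemaConflictError,
    TableChunk,
    TYPE_ORDER,
    arrow_type,
)

__all__ = ["apply_naming", "cast_columns", "unify_schemas", "align_to_schema"]


def harmonized_name(name: str, preset: Preset, role: str) -> str:
    """Target name for one column of a table with compartment ``role``."""
    name = name.strip()
    if name.startswith(METADATA_PREFIX):
        return name
    if name in preset.identifying_columns:
        return METADATA_PREFIX + name
    role_prefix = role.capitalize() + "_"
    if name.startswith(role_prefix):
        return name
    return role_prefix + name


def apply_naming(chunk: TableChunk, preset: Preset, role: str) -> TableChunk:
    """Rename a chunk's columns to the harmonized convention (idempotent)."""
    new_schema: List[ColumnSchema] = []
    seen: Dict[str, str] = {}
    for col in chunk.schema:
        target = harmonized_name(col.name, preset, role)
        if target in seen:
            raise ColumnCollisionError(
                f"column collision on {target!r}: from {seen[target]!r} and "
                f"{col.name!r} in role {role!r}"
            )
        seen[target] = col.name
        new_schema.append(col.with_name(target))
    table = chunk.table.rename_columns([c.name for c in new_schema])
    return dataclasses.replace(chunk, schema=new_schema, table=table)


def cast_columns(chunk: TableChunk, preset: Preset) -> TableChunk:
    """Cast a chunk to the preset's storage widths.

    Float features move to the preset's ``float_width``; integer keys are
    stored as signed 64-bit integers and must be value-preserving (a
    non-integral key value raises :class:`CastError`).
    """
    arrays = []
    for col in chunk.schema:
        arr = chunk.table.column(col.name)
        target = arrow_type(col, preset.float_width)
        if arr.type == target:
            arrays.append(arr)
            continue
        if col.declared_type == "integer-key" and pa.types.is_floating(arr.type):
            floored = pc.floor(arr)
            bad = pc.any(pc.not_equal(floored, arr)).as_py()
            if bad:
                mism = pc.not_equal(floored, arr)
                idx = mism.combine_chunks().index(True).as_py()
                raise CastError(
                    f"non-integral value in integer-key column {col.name!r} "
                    f"at row {idx + 1}"
                )
        try:
            arrays.append(arr.cast(target))
        except pa.ArrowInvalid as exc:
            raise CastError(f"cannot cast column {col.name!r}: {exc}") from exc
    fields = [
        pa.field(c.name, a.type, nullable=True) for c, a in zip(chunk.schema, arrays)
    ]
    table = pa.Table.from_arrays(arrays, schema=pa.schema(fields))
    return dataclasses.replace(chunk, table=table)


def _promote(a: ColumnSchema, b: ColumnSchema, type_policy: str) -> ColumnSchema:
    if a.declared_type == b.declared_type:
        return a
    identifying = a.name.startswith(METADATA_PREFIX)
    kinds = {a.declared_type, b.declared_type}
    if identifying and "integer-key" in kinds:
        raise SchemaConflictError(
            f"key schema conflict on {a.name!r}: {a.declared_type} vs "
            f"{b.declared_type}"
        )
    if kinds == {"float-feature", "text"} and type_policy == "strict-fail":
        raise SchemaConflictError(
            f"type conflict on {a.name!r} under strict-fail: float-feature vs text"
        )
    winner = a if TYPE_ORDER[a.declared_type] >= TYPE_ORDER[b.declared_type] else b
    return dataclasses.replace(
        a, declared_type=winner.declared_type, nullable=a.nullable or b.nullable
    )


def unify_schemas(
    schemas: Sequence[Sequence[ColumnSchema]],
    *,
    type_policy: str = "coerce-null",
) -> List[ColumnSchema]:
    """Union schemas by column name, first-seen column order.

    A column missing from any input schema becomes nullable.  Type
    conflicts resolve by promotion (boolean < integer-key < float-feature
    < text), except identifying (``Metadata_``) columns, which are pinned:
    conflicting key types raise :class:`SchemaConflictError`.  Under
    ``strict-fail`` a float/text conflict is an error instead of promoting
    to text.
    """
    if not schemas:
        raise ValueError("unify_schemas requires at least one schema")
    order: List[str] = []
    merged: Dict[str, ColumnSchema] = {}
    presence: Dict[str, int] = {}
    for schema in schemas:
        for col in schema:
            if col.name not in merged:
                merged[col.name] = col
                order.append(col.name)
                presence[col.name] = 0
            else:
                merged[col.name] = _promote(merged[col.name], col, type_policy)
            presence[col.name] += 1
    n = len(schemas)
    out = []
    for name in order:
        col = merged[name]
        if presence[name] < n and not col.nullable:
            col = col.as_nullable()
        out.append(col)
    return out


def align_to_schema(chunk: TableChunk, target: Sequence[ColumnSchema]) -> TableChunk:
    """Conform a chunk to a unified schema: fill, reorder, cast.

    Columns absent from the chunk are filled with nulls; columns are
    reordered to the target order and cast to the target types.  A chunk
    column not present in the target is an :class:`AlignmentError` (the
    chunk must be a subset of the target).
    """
    have = chunk.schema_by_name()
    extra = [n for n in have if n not in {c.name for c in target}]
    if extra:
        raise AlignmentError(
            f"chunk column(s) {extra} absent from target schema"
        )
    n = chunk.row_count
    arrays = []
    for col in target:
        t = arrow_type(col)
        if col.name in have:
            arr = chunk.table.column(col.name)
            if arr.type != t:
                try:
                    arr = arr.cast(t)
                except pa.ArrowInvalid as exc:
                    raise CastError(
                        f"cannot align column {col.name!r} to "
                        f"{col.declared_type}: {exc}"
                    ) from exc
            arrays.append(arr)
        else:
            arrays.append(pa.nulls(n, type=t))
    fields = [pa.field(c.name, a.type, nullable=True) for c, a in zip(target, arrays)]
    table = pa.Table.from_arrays(arrays, schema=pa.schema(fields))
    return dataclasses.replace(chunk, schema=list(target), table=table)
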