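"""Join engine: compile preset join clauses into a plan and execute it.

The plan is declarative.  Consecutive clauses sharing the same table pair
and join kind form one composite-key join step (e.g. the cytoplasm→cells
link matches on both the image key and the parent-object id).  Every plan
renders as ANSI SQL text — logged on execution and exportable for audit —
documenting the relational structure even though execution happens through
pyarrow's in-memory join engine.

Output grain is one row per base-table object.  Inner joins keep matched
rows only; left joins keep all base-side rows with nulls on the unmatched
side; duplicate matches multiply rows (standard join multiplicity) and are
warned about, never silently deduplicated — duplicate parents usually mean
upstream segmentation errors worth seeing.  Output is canonically sorted
ascending by the key columns so chunked and parallel runs are
byte-comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pyarrow as pa
import pyarrow.compute as pc

from .harmonize import harmonized_name
from .model import (
    ColumnSchema,
    HarmonizedTable,
    JoinClause,
    JoinCompileError,
    METADATA_PREFIX,
    Preset,
    TableChunk,
    empty_arrow_table,
)

logger = logging.getLogger(__name__)

__all__ = ["JoinPlan", "JoinStep", "compile_join_plan", "execute_join",
           "page_join_keys", "render_sql"]


@dataclass(frozen=True)
class JoinStep:
    """One executable join: composite keys resolved to harmonized names."""

    right_table: str
    join_kind: str
    left_keys: Tuple[str, ...]
    right_keys: Tuple[str, ...]


@dataclass
class JoinPlan:
    base_table: str
    steps: List[JoinStep]
    output_columns: List[ColumnSchema]
    key_columns: List[str]
    warnings: List[str] = field(default_factory=list)

    def sql(self) -> str:
        return render_sql(self)


def _resolve(
    raw: str, role: str, preset: Preset, schema_names: set, table: str
) -> str:
    """Map a raw clause column to its post-prefixing name in ``table``."""
    for candidate in (harmonized_name(raw, preset, role), raw):
        if candidate in schema_names:
            return candidate
    raise JoinCompileError(
        f"join clause references column {raw!r} not present in table "
        f"{table!r} (post-harmonization)"
    )


def _group_clauses(
    clauses: Sequence[JoinClause],
) -> List[Tuple[str, str, str, List[JoinClause]]]:
    """Group consecutive clauses with identical (left, right, kind)."""
    groups: List[Tuple[str, str, str, List[JoinClause]]] = []
    for clause in clauses:
        key = (clause.left_table, clause.right_table, clause.join_kind)
        if groups and (groups[-1][0], groups[-1][1], groups[-1][2]) == key:
            groups[-1][3].append(clause)
        else:
            groups.append((*key, [clause]))
    return groups


def compile_join_plan(
    preset: Preset, available: Dict[str, Sequence[ColumnSchema]]
) -> JoinPlan:
    """Compile the preset's join clauses against available table schemas.

    ``available`` maps compartment role → harmonized (post-prefixing)
    schema.  Missing optional compartments drop their left-join steps with
    a warning; a missing inner-join table is a compile error, as is a
    clause referencing a column that does not exist.
    """
    if preset.base_table not in available:
        raise JoinCompileError(
            f"base table {preset.base_table!r} not among available tables "
            f"{sorted(available)}"
        )
    names_by_role = {r: {c.name for c in s} for r, s in available.items()}

    steps: List[JoinStep] = []
    warnings: List[str] = []
    output_names = set(names_by_role[preset.base_table])
    output_cols: List[ColumnSchema] = list(available[preset.base_table])

    for left_t, right_t, kind, clauses in _group_clauses(preset.joins):
        missing = [t for t in (left_t, right_t) if t not in available]
        if missing:
            if kind == "left":
                msg = (
                    f"dropping left join to {right_t!r}: table(s) "
                    f"{missing} not present in this source group"
                )
                warnings.append(msg)
                logger.warning(msg)
                continue
            raise JoinCompileError(
                f"inner join requires table(s) {missing}, absent from source group"
            )
        left_keys = tuple(
            _resolve(c.left_column, left_t, preset, names_by_role[left_t], left_t)
            for c in clauses
        )
        right_keys = tuple(
            _resolve(c.right_column, right_t, preset, names_by_role[right_t], right_t)
            for c in clauses
        )
        steps.append(JoinStep(right_t, kind, left_keys, right_keys))
        nullable_right = [
            (c.as_nullable() if kind == "left" else c)
            for c in available[right_t]
            if c.name not in right_keys  # right key copies coalesce away
        ]
        collide = [c.name for c in nullable_right if c.name in output_names]
        if collide:
            raise JoinCompileError(
                f"join with {right_t!r} would duplicate column(s) {collide}"
            )
        output_names.update(c.name for c in nullable_right)
        output_cols.extend(nullable_right)

    key_columns = [
        name
        for name in (
            METADATA_PREFIX + "TableNumber",
            METADATA_PREFIX + "ImageNumber",
            METADATA_PREFIX + "ObjectNumber",
        )
        if name in names_by_role[preset.base_table]
    ]
    if not key_columns:
        key_columns = [
            c.name
            for c in available[preset.base_table]
            if c.declared_type == "integer-key" and c.name.startswith(METADATA_PREFIX)
        ][:2]
    plan = JoinPlan(
        base_table=preset.base_table,
        steps=steps,
        output_columns=output_cols,
        key_columns=key_columns,
        warnings=warnings,
    )
    logger.info("compiled join plan:\n%s", plan.sql())
    return plan


def render_sql(plan: JoinPlan) -> str:
    """ANSI-style query text documenting the table relationships."""
    lines = [
        "SELECT",
        "  " + ",\n  ".join(c.name for c in plan.output_columns),
        f"FROM {plan.base_table}",
    ]
    for step in plan.steps:
        kw = "INNER JOIN" if step.join_kind == "inner" else "LEFT JOIN"
        conds = " AND ".join(
            f"{plan.base_table}.{l} = {step.right_table}.{r}"
            for l, r in zip(step.left_keys, step.right_keys)
        )
        lines.append(f"{kw} {step.right_table} ON {conds}")
    if plan.key_columns:
        lines.append("ORDER BY " + ", ".join(f"{k} ASC" for k in plan.key_columns))
    return "\n".join(lines)


def _warn_duplicate_keys(table: pa.Table, keys: Sequence[str], label: str) -> List[str]:
    if table.num_rows == 0:
        return []
    counts = table.select(list(keys)).group_by(list(keys)).aggregate([([], "count_all")])
    dupes = counts.filter(pc.greater(counts.column("count_all"), 1))
    warnings = []
    for row in dupes.to_pylist()[:5]:
        key_repr = {k: row[k] for k in keys}
        msg = f"duplicate match keys in {label}: {key_repr} ({row['count_all']} rows)"
        warnings.append(msg)
        logger.warning(msg)
    return warnings


def execute_join(plan: JoinPlan, tables: Dict[str, TableChunk]) -> HarmonizedTable:
    """Execute a compiled plan over harmonized chunks.

    Relational semantics: inner keeps only matched rows; left keeps every
    base-side row with nulls on the unmatched side; duplicate matches
    multiply rows.  The result is sorted ascending by the plan's key
    columns and carries the one-row-per-base-object grain.
    """
    base = tables[plan.base_table]
    acc = base.table
    warnings: List[str] = list(plan.warnings)
    for step in plan.steps:
        right = tables[step.right_table].table
        warnings.extend(
            _warn_duplicate_keys(right, step.right_keys, step.right_table)
        )
        join_type = "inner" if step.join_kind == "inner" else "left outer"
        acc = acc.join(
            right,
            keys=list(step.left_keys),
            right_keys=list(step.right_keys),
            join_type=join_type,
        )
    # conform to the declared output schema (order and types)
    out_names = [c.name for c in plan.output_columns]
    if acc.num_rows == 0:
        acc = empty_arrow_table(plan.output_columns)
    else:
        acc = acc.select(out_names)
    if plan.key_columns and acc.num_rows:
        acc = acc.sort_by([(k, "ascending") for k in plan.key_columns])
    fields = [
        pa.field(c.name, acc.column(c.name).type, nullable=True)
        for c in plan.output_columns
    ]
    acc = acc.cast(pa.schema(fields))
    return HarmonizedTable(
        schema=list(plan.output_columns),
        table=acc,
        grain=f"one row per {plan.base_table} object",
        key_columns=list(plan.key_columns),
        warnings=warnings,
    )


def page_join_keys(
    base: TableChunk, key: str, chunk_size: int
) -> List[Tuple[int, int]]:
    """Greedy contiguous key ranges covering all distinct values of ``key``.

    Each inclusive range holds at most ``chunk_size`` base rows, unless a
    single key value alone exceeds the budget — that key is then isolated
    in its own range.  Ranges are ascending and non-overlapping.
    """
    col = base.schema_by_name().get(key)
    if col is None or col.declared_type != "integer-key":
        raise JoinCompileError(f"{key!r} is not an integer-key column")
    if base.row_count == 0:
        return []
    counts = (
        base.table.select([key]).group_by([key]).aggregate([([], "count_all")])
    ).sort_by([(key, "ascending")])
    ranges: List[Tuple[int, int]] = []
    lo: Optional[int] = None
    hi: Optional[int] = None
    total = 0
    for row in counts.to_pylist():
        value, n = row[key], row["count_all"]
        if lo is None:
            lo, hi, total = value, value, n
        elif total + n <= chunk_size:
            hi, total = value, total + n
        else:
            ranges.append((lo, hi))
            lo, hi, total = value, value, n
    ranges.append((lo, hi))
    return ranges
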