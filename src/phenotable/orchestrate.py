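"""Task-graph orchestration: extract → harmonize → join → concat → write.

Each source group becomes an independent acyclic subgraph: one extract task
per source per page (map stage), a harmonize task downstream of each
extract, one join task per key page, one concat (reduce stage), and one
write task.  Execution follows the dataflow contract — a task runs only
once all of its inputs are available — under a serial, multithread, or
multiprocess executor, all behind one contract.  Intermediate products are
spilled to temporary Parquet files keyed by task id rather than held in
memory, and final outputs are canonically sorted, so results are
byte-identical across executors, worker counts, and chunk sizes.
"""

from __future__ import annotations

import concurrent.futures as cf
import dataclasses
import json
import logging
import math
import multiprocessing
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import pyarrow as pa
import pyarrow.compute as pc
import pyarrow.parquet as pq

from .discovery import SourceGroupMap, discover_sources
from .harmonize import align_to_schema, apply_naming, cast_columns, unify_schemas
from .joins import JoinPlan, compile_join_plan, execute_join, page_join_keys
from .model import (
    ColumnSchema,
    PhenotableError,
    Preset,
    SourceSpec,
    TableChunk,
    TaskExecutionError,
    ensure_path,
)
from .presets import get_preset, merge_overrides
from .readers import count_rows, read_chunk, scan_column_types
from .writers import FORMAT_EXTENSIONS, WriteReport, write_table

logger = logging.getLogger(__name__)

__all__ = [
    "Task",
    "WorkPlan",
    "ManifestEntry",
    "OutputManifest",
    "build_workplan",
    "execute_workplan",
    "convert",
]

TASK_KINDS = ("extract", "harmonize", "join", "concat", "write")


@dataclass(frozen=True)
class Task:
    task_id: str
    kind: str
    inputs: Tuple[str, ...]
    params: dict


@dataclass
class WorkPlan:
    tasks: Dict[str, Task]
    edges: List[Tuple[str, str]]
    preset: Preset
    group_meta: Dict[str, dict] = field(default_factory=dict)

    def validate(self) -> None:
        for task in self.tasks.values():
            if task.kind not in TASK_KINDS:
                raise PhenotableError(f"unknown task kind {task.kind!r}")
            if task.kind != "extract":
                missing = [i for i in task.inputs if i not in self.tasks]
                if missing:
                    raise PhenotableError(
                        f"task {task.task_id!r} depends on missing task(s) {missing}"
                    )
        self.topological_order()  # raises on cycles

    def topological_order(self) -> List[str]:
        """Deterministic topological order (ready tasks by lexicographic id)."""
        pending = {t: set(task.inputs) for t, task in self.tasks.items()}
        dependents: Dict[str, List[str]] = {t: [] for t in self.tasks}
        for t, deps in pending.items():
            for d in deps:
                dependents[d].append(t)
        ready = sorted(t for t, deps in pending.items() if not deps)
        order: List[str] = []
        while ready:
            t = ready.pop(0)
            order.append(t)
            newly = []
            for d in dependents[t]:
                pending[d].discard(t)
                if not pending[d]:
                    newly.append(d)
            ready = sorted(ready + newly)
        if len(order) != len(self.tasks):
            raise PhenotableError("work plan contains a dependency cycle")
        return order


@dataclass
class ManifestEntry:
    group_key: str
    path: str
    rows: int
    columns: int
    coercion_warnings: int
    plan_text: str
    warnings: List[str] = field(default_factory=list)


@dataclass
class OutputManifest:
    groups: Dict[str, ManifestEntry]

    def to_json(self) -> str:
        return json.dumps(
            {k: dataclasses.asdict(v) for k, v in self.groups.items()}, indent=2
        )

    @property
    def total_rows(self) -> int:
        return sum(e.rows for e in self.groups.values())

    @property
    def total_coercions(self) -> int:
        return sum(e.coercion_warnings for e in self.groups.values())


def _sanitize(key: str) -> str:
    out = "".join(c if c.isalnum() or c in "-_." else "_" for c in key)
    out = out.strip("./") or "group"
    return out.replace("/", "_")


# ---------------------------------------------------------------------------
# Plan construction
# ---------------------------------------------------------------------------


def build_workplan(
    groups: SourceGroupMap,
    preset: Preset,
    dest,
    fmt: str = "parquet",
    *,
    compression: str = "snappy-class",
) -> WorkPlan:
    """Build the acyclic task graph for all source groups.

    Schemas are resolved (two-pass typing) and page boundaries computed at
    plan time, so the graph is fully static: per group, one extract task
    per source per page, one harmonize per extract, one join per key page
    (when the preset declares joins), one concat, one write.
    """
    if not groups.groups:
        raise PhenotableError("cannot build a work plan for zero source groups")
    if fmt not in FORMAT_EXTENSIONS:
        raise PhenotableError(f"unknown output format {fmt!r}")
    dest = ensure_path(dest)
    single = len(groups.groups) == 1
    ext = FORMAT_EXTENSIONS[fmt]

    tasks: Dict[str, Task] = {}
    edges: List[Tuple[str, str]] = []
    group_meta: Dict[str, dict] = {}

    for gi, (group_key, sources) in enumerate(groups.groups.items()):
        gp = f"g{gi:03d}"
        role_harmonized: Dict[str, List[str]] = {}
        role_schemas: Dict[str, List[List[ColumnSchema]]] = {}

        for si, source in enumerate(sources):
            schema = scan_column_types(source, preset)
            n = count_rows(source)
            n_pages = max(1, math.ceil(n / preset.chunk_size))
            for page in range(n_pages):
                ex_id = f"{gp}-extract-{source.role}-{si}-p{page:05d}"
                tasks[ex_id] = Task(
                    ex_id,
                    "extract",
                    (),
                    {
                        "source": source,
                        "schema": schema,
                        "offset": page * preset.chunk_size,
                        "limit": preset.chunk_size,
                    },
                )
                hz_id = f"{gp}-harmonize-{source.role}-{si}-p{page:05d}"
                tasks[hz_id] = Task(
                    hz_id, "harmonize", (ex_id,), {"role": source.role}
                )
                edges.append((ex_id, hz_id))
                role_harmonized.setdefault(source.role, []).append(hz_id)
            # harmonized schema is computable statically
            named = [
                c.with_name(_harmonized_name(c.name, preset, source.role))
                for c in schema
            ]
            role_schemas.setdefault(source.role, []).append(named)

        available = {
            role: unify_schemas(schemas, type_policy=preset.type_policy)
            for role, schemas in role_schemas.items()
        }

        join_ids: List[str] = []
        plan_text = ""
        key_columns: List[str] = []
        if preset.joins and len(available) > 1:
            jplan = compile_join_plan(preset, available)
            plan_text = jplan.sql()
            key_columns = list(jplan.key_columns)
            paging_key = (
                "Metadata_ImageNumber"
                if "Metadata_ImageNumber" in key_columns
                else (key_columns[0] if key_columns else None)
            )
            ranges = _plan_key_ranges(
                sources, preset, available, paging_key
            )
            all_hz = tuple(
                hid for role in sorted(role_harmonized) for hid in role_harmonized[role]
            )
            for ri, key_range in enumerate(ranges):
                j_id = f"{gp}-join-r{ri:05d}"
                tasks[j_id] = Task(
                    j_id,
                    "join",
                    all_hz,
                    {
                        "plan": jplan,
                        "role_inputs": {
                            r: list(ids) for r, ids in role_harmonized.items()
                        },
                        "role_schemas": available,
                        "paging_key": paging_key,
                        "key_range": key_range,
                    },
                )
                edges.extend((h, j_id) for h in all_hz)
                join_ids.append(j_id)
        else:
            base_role = (
                preset.base_table
                if preset.base_table in available
                else sorted(available)[0]
            )
            key_columns = [
                c.name
                for c in available[base_role]
                if c.declared_type == "integer-key"
                and c.name.startswith("Metadata_")
            ][:2]

        concat_inputs = (
            tuple(join_ids)
            if join_ids
            else tuple(
                hid
                for role in sorted(role_harmonized)
                for hid in role_harmonized[role]
            )
        )
        c_id = f"{gp}-concat"
        tasks[c_id] = Task(
            c_id, "concat", concat_inputs, {"key_columns": key_columns}
        )
        edges.extend((i, c_id) for i in concat_inputs)

        if single and dest.suffix == ext:
            out_path = dest
        else:
            out_path = dest / f"{_sanitize(group_key)}{ext}"
        w_id = f"{gp}-write"
        tasks[w_id] = Task(
            w_id,
            "write",
            (c_id,),
            {"path": str(out_path), "fmt": fmt, "compression": compression},
        )
        edges.append((c_id, w_id))
        group_meta[group_key] = {
            "write_task": w_id,
            "plan_text": plan_text,
            "prefix": gp,
        }

    plan = WorkPlan(tasks=tasks, edges=edges, preset=preset, group_meta=group_meta)
    plan.validate()
    return plan


def _harmonized_name(name: str, preset: Preset, role: str) -> str:
    from .harmonize import harmonized_name

    return harmonized_name(name, preset, role)


def _plan_key_ranges(
    sources: List[SourceSpec],
    preset: Preset,
    available: Mapping[str, List[ColumnSchema]],
    paging_key: Optional[str],
) -> List[Optional[Tuple[int, int]]]:
    """Key pages for the base table, computed from a plan-time key scan."""
    if paging_key is None:
        return [None]
    base_sources = [s for s in sources if s.role == preset.base_table]
    if not base_sources:
        return [None]
    chunks = []
    for source in base_sources:
        schema = scan_column_types(source, preset)
        chunk = read_chunk(source, schema, 0, 1 << 62, preset)
        chunk = cast_columns(apply_naming(chunk, preset, source.role), preset)
        chunks.append(chunk)
    base_schema = available[preset.base_table]
    aligned = [align_to_schema(c, base_schema) for c in chunks]
    table = pa.concat_tables([c.table for c in aligned])
    base = TableChunk(schema=list(base_schema), table=table)
    if base.row_count == 0:
        return [None]
    return list(page_join_keys(base, paging_key, preset.chunk_size))


# ---------------------------------------------------------------------------
# Task execution
# ---------------------------------------------------------------------------


@dataclass
class TaskResult:
    task_id: str
    rows: int
    columns: int
    coercions: int = 0
    warnings: List[str] = field(default_factory=list)
    report: Optional[WriteReport] = None
    duration: float = 0.0


def _spill_path(workdir: str, task_id: str) -> Path:
    return Path(workdir) / f"{task_id}.parquet"


def _load_spill(workdir: str, task_id: str) -> TableChunk:
    return TableChunk.from_arrow(pq.read_table(_spill_path(workdir, task_id)))


def _spill(chunk: TableChunk, workdir: str, task_id: str) -> None:
    pq.write_table(chunk.attach_metadata(), _spill_path(workdir, task_id))


def _concat_role(
    workdir: str,
    task_ids: List[str],
    schema: List[ColumnSchema],
) -> TableChunk:
    chunks = [_load_spill(workdir, t) for t in task_ids]
    aligned = [align_to_schema(c, schema) for c in chunks]
    table = pa.concat_tables([c.table for c in aligned])
    coercions = sum(c.coercions for c in chunks)
    return TableChunk(schema=list(schema), table=table, coercions=coercions)


def _run_task(workdir: str, task: Task, preset: Preset) -> TaskResult:
    """Execute one task against the spill directory (executor-agnostic)."""
    t0 = time.perf_counter()
    p = task.params
    if task.kind == "extract":
        chunk = read_chunk(p["source"], p["schema"], p["offset"], p["limit"], preset)
        _spill(chunk, workdir, task.task_id)
        result = TaskResult(
            task.task_id, chunk.row_count, len(chunk.schema), chunk.coercions
        )
    elif task.kind == "harmonize":
        chunk = _load_spill(workdir, task.inputs[0])
        chunk = cast_columns(apply_naming(chunk, preset, p["role"]), preset)
        _spill(chunk, workdir, task.task_id)
        result = TaskResult(
            task.task_id, chunk.row_count, len(chunk.schema), chunk.coercions
        )
    elif task.kind == "join":
        jplan: JoinPlan = p["plan"]
        tables = {
            role: _concat_role(workdir, ids, p["role_schemas"][role])
            for role, ids in p["role_inputs"].items()
        }
        key_range = p.get("key_range")
        if key_range is not None:
            lo, hi = key_range
            base = tables[jplan.base_table]
            mask = pc.and_(
                pc.greater_equal(base.table.column(p["paging_key"]), pa.scalar(lo)),
                pc.less_equal(base.table.column(p["paging_key"]), pa.scalar(hi)),
            )
            tables[jplan.base_table] = dataclasses.replace(
                base, table=base.table.filter(mask)
            )
        joined = execute_join(jplan, tables)
        _spill(joined, workdir, task.task_id)
        result = TaskResult(
            task.task_id,
            joined.row_count,
            len(joined.schema),
            warnings=list(joined.warnings),
        )
    elif task.kind == "concat":
        chunks = [_load_spill(workdir, t) for t in task.inputs]
        schema = unify_schemas([c.schema for c in chunks], type_policy=preset.type_policy)
        aligned = [align_to_schema(c, schema) for c in chunks]
        table = pa.concat_tables([c.table for c in aligned])
        key_columns = [k for k in p["key_columns"] if k in table.column_names]
        if key_columns and table.num_rows:
            table = table.sort_by([(k, "ascending") for k in key_columns])
        out = TableChunk(schema=schema, table=table, coercions=0)
        _spill(out, workdir, task.task_id)
        result = TaskResult(task.task_id, out.row_count, len(out.schema))
    elif task.kind == "write":
        chunk = _load_spill(workdir, task.inputs[0])
        out_path = Path(p["path"])
        out_path.parent.mkdir(parents=True, exist_ok=True)
        report = write_table(
            chunk, out_path, p["fmt"], compression=p["compression"]
        )
        result = TaskResult(
            task.task_id, report.rows_written, report.columns_written, report=report
        )
    else:  # pragma: no cover
        raise PhenotableError(f"unknown task kind {task.kind!r}")
    result.duration = time.perf_counter() - t0
    logger.info(
        "task %s kind=%s rows=%d duration=%.3fs",
        result.task_id, task.kind, result.rows, result.duration,
    )
    return result


# ---------------------------------------------------------------------------
# Executors
# ---------------------------------------------------------------------------


def _make_executor(mode: str, workers: int):
    if mode == "multithread":
        return cf.ThreadPoolExecutor(max_workers=workers)
    if mode == "multiprocess":
        ctx = multiprocessing.get_context("fork")
        return cf.ProcessPoolExecutor(max_workers=workers, mp_context=ctx)
    raise PhenotableError(f"unknown execution mode {mode!r}")


def execute_workplan(
    plan: WorkPlan,
    mode: str = "multiprocess",
    workers: int = 2,
    seed: int = 0,
    *,
    temp_dir: Optional[str] = None,
) -> OutputManifest:
    """Run a work plan to completion and assemble the output manifest.

    A task runs only after all its dependencies have completed; failures
    cancel all dependents and surface the first root-cause error as a
    :class:`TaskExecutionError` naming the failing task.  Outputs are
    byte-identical across modes and worker counts (``seed`` exists for
    interface symmetry with the fixture generators; the pipeline itself is
    deterministic and ignores it).
    """
    del seed  # deterministic pipeline
    plan.validate()
    results: Dict[str, TaskResult] = {}

    with tempfile.TemporaryDirectory(dir=temp_dir, prefix="phenotable-") as workdir:
        if mode == "serial" or workers == 1:
            for task_id in plan.topological_order():
                task = plan.tasks[task_id]
                try:
                    results[task_id] = _run_task(workdir, task, plan.preset)
                except Exception as exc:
                    raise TaskExecutionError(task_id, exc) from exc
        else:
            _execute_parallel(plan, mode, workers, workdir, results)
        return _build_manifest(plan, results)


def _execute_parallel(
    plan: WorkPlan,
    mode: str,
    workers: int,
    workdir: str,
    results: Dict[str, TaskResult],
) -> None:
    pending = {t: set(task.inputs) for t, task in plan.tasks.items()}
    dependents: Dict[str, List[str]] = {t: [] for t in plan.tasks}
    for t, deps in pending.items():
        for d in deps:
            dependents[d].append(t)
    ready = sorted(t for t, deps in pending.items() if not deps)
    running: Dict[cf.Future, str] = {}
    failure: Optional[TaskExecutionError] = None

    with _make_executor(mode, workers) as pool:
        while (ready or running) and failure is None:
            while ready:
                task_id = ready.pop(0)
                fut = pool.submit(_run_task, workdir, plan.tasks[task_id], plan.preset)
                running[fut] = task_id
            done, _ = cf.wait(list(running), return_when=cf.FIRST_COMPLETED)
            newly: List[str] = []
            for fut in done:
                task_id = running.pop(fut)
                try:
                    results[task_id] = fut.result()
                except Exception as exc:
                    failure = TaskExecutionError(task_id, exc)
                    break
                for d in dependents[task_id]:
                    pending[d].discard(task_id)
                    if not pending[d] and d not in results:
                        newly.append(d)
            ready = sorted(set(ready + newly))
    if failure is not None:
        raise failure


def _build_manifest(
    plan: WorkPlan, results: Dict[str, TaskResult]
) -> OutputManifest:
    groups: Dict[str, ManifestEntry] = {}
    for group_key, meta in plan.group_meta.items():
        gp = meta["prefix"]
        write_result = results[meta["write_task"]]
        coercions = sum(
            r.coercions
            for tid, r in results.items()
            if tid.startswith(f"{gp}-extract")
        )
        warnings = [
            w
            for tid, r in results.items()
            if tid.startswith(gp)
            for w in r.warnings
        ]
        groups[group_key] = ManifestEntry(
            group_key=group_key,
            path=write_result.report.path if write_result.report else "",
            rows=write_result.rows,
            columns=write_result.columns,
            coercion_warnings=coercions,
            plan_text=meta["plan_text"],
            warnings=warnings,
        )
    manifest = OutputManifest(groups=groups)
    logger.info("manifest: %s", manifest.to_json())
    return manifest


# ---------------------------------------------------------------------------
# Top-level entry point
# ---------------------------------------------------------------------------


def convert(
    source_path,
    dest_path,
    preset_name: str = "cellprofiler_csv",
    overrides: Optional[Mapping[str, object]] = None,
    fmt: str = "parquet",
    mode: str = "multiprocess",
    workers: int = 2,
    *,
    compression: str = "snappy-class",
    temp_dir: Optional[str] = None,
) -> OutputManifest:
    """One-call pipeline: preset → discovery → plan → execution → manifest.

    Composes :func:`~phenotable.presets.get_preset`,
    :func:`~phenotable.presets.merge_overrides`,
    :func:`~phenotable.discovery.discover_sources`,
    :func:`build_workplan` and :func:`execute_workplan`.
    """
    preset = get_preset(preset_name)
    if overrides:
        preset = merge_overrides(preset, overrides)
    groups = discover_sources(source_path, preset)
    plan = build_workplan(groups, preset, dest_path, fmt, compression=compression)
    return execute_workplan(plan, mode=mode, workers=workers, temp_dir=temp_dir)
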