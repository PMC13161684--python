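"""Run instrumentation and toy-scale format benchmarking.

`compare_formats` measures on-disk size and read/write durations for each
(format, compression) pair over repeated runs, reporting the min/max range
and median.  Durations are hardware-dependent observations, never
cross-machine targets; combinations a format cannot hold (e.g. SQLite
beyond its 2,000-column default) are recorded as ``incompatible`` rather
than failing the report.
"""

from __future__ import annotations

import dataclasses
import sqlite3
import statistics
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd

from .model import ColumnLimitError, SourceSpec, TableChunk
from .orchestrate import OutputManifest, WorkPlan
from .readers import read_delimited_chunk
from .writers import read_parquet_table, write_table

__all__ = ["RunSummary", "compare_formats", "summarize_run"]


@dataclass
class RunSummary:
    """Per-run accounting: stage row counts, coercions, warnings, plan."""

    stage_rows: dict
    coercion_count: int
    warnings: List[str]
    plan_text: str
    write_reports: List[dict] = field(default_factory=list)


def summarize_run(plan: WorkPlan, manifest: OutputManifest) -> RunSummary:
    """Condense a finished run into a single summary record."""
    stage_rows = {"output": manifest.total_rows}
    warnings: List[str] = []
    reports = []
    plan_texts = []
    for entry in manifest.groups.values():
        warnings.extend(entry.warnings)
        if entry.plan_text:
            plan_texts.append(entry.plan_text)
        reports.append(
            {"path": entry.path, "rows": entry.rows, "columns": entry.columns}
        )
    return RunSummary(
        stage_rows=stage_rows,
        coercion_count=manifest.total_coercions,
        warnings=warnings,
        plan_text="\n\n".join(plan_texts),
        write_reports=reports,
    )


def _read_back(path: Path, fmt: str, table: TableChunk) -> None:
    if fmt == "parquet":
        read_parquet_table(path)
    elif fmt == "csv":
        stub = SourceSpec(
            path=str(path), kind="delimited-text", table_name=path.stem,
            group_key=".",
        )
        read_delimited_chunk(stub, table.schema, 0, table.row_count + 1)
    elif fmt == "sqlite":
        conn = sqlite3.connect(f"file:{path}?mode=ro", uri=True)
        try:
            conn.execute('SELECT * FROM "harmonized"').fetchall()
        finally:
            conn.close()
    elif fmt in ("h5ad", "annotated-matrix"):
        import anndata as ad

        ad.read_h5ad(path)


def compare_formats(
    table: TableChunk,
    formats: Sequence[str] = ("parquet", "csv", "sqlite", "h5ad"),
    compressions: Sequence[str] = ("snappy-class",),
    repeats: int = 6,
    *,
    out_csv: Optional[str] = None,
) -> pd.DataFrame:
    """Benchmark write/read round trips per (format, compression) pair.

    Returns one row per combination with byte size and the median and
    [min, max] range of write/read durations over ``repeats`` runs.  Pass
    ``out_csv`` to also emit the report as CSV.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    records = []
    with tempfile.TemporaryDirectory(prefix="phenotable-bench-") as tmp:
        for fmt in formats:
            fmt_compressions = compressions if fmt == "parquet" else ("none",)
            for compression in fmt_compressions:
                path = Path(tmp) / f"bench-{fmt}-{compression}"
                writes, reads = [], []
                status = "ok"
                byte_size = 0
                try:
                    for _ in range(repeats):
                        t0 = time.perf_counter()
                        report = write_table(
                            table, path, fmt, compression=compression
                        )
                        writes.append(time.perf_counter() - t0)
                        byte_size = report.byte_size
                        t0 = time.perf_counter()
                        _read_back(path, fmt, table)
                        reads.append(time.perf_counter() - t0)
                except ColumnLimitError:
                    status = "incompatible"
                rec = {
                    "format": fmt,
                    "compression": compression,
                    "status": status,
                    "bytes": byte_size,
                    "rows": table.row_count,
                    "columns": len(table.schema),
                    "repeats": repeats,
                }
                for label, series in (("write", writes), ("read", reads)):
                    if series:
                        rec[f"{label}_median_s"] = statistics.median(series)
                        rec[f"{label}_min_s"] = min(series)
                        rec[f"{label}_max_s"] = max(series)
                    else:
                        rec[f"{label}_median_s"] = float("nan")
                        rec[f"{label}_min_s"] = float("nan")
                        rec[f"{label}_max_s"] = float("nan")
                rec["note"] = "durations are hardware-dependent"
                records.append(rec)
    report_df = pd.DataFrame.from_records(records)
    if out_csv:
        report_df.to_csv(out_csv, index=False)
    return report_df
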