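"""Synthetic export generators with known ground-truth join structure.

Each generator emulates one supported tool's on-disk layout — the
CellProfiler spreadsheet/database exports (Image/Cells/Nuclei/Cytoplasm at
one nucleus and one cytoplasm per cell), DeepProfiler's per-site NPZ
feature matrices, and IN Carta's per-object CSV — so every pipeline stage
is testable without downloads.  Generation is a pure function of the
parameters: identical params and seed reproduce byte-identical files.

The module also houses the independent verification oracles: a naive
nested-loop join (:func:`nested_loop_join`) and a direct enumeration of the
generated object graph (:func:`expected_join_rowcount`).  Both are written
against the object graph, never against the join engine, so they can
arbitrate its output.

Ground-truth conventions: ids are dense 1-based integers (``ImageNumber``
1..n, ``ObjectNumber`` 1..k per image) matching CellProfiler; orphaned
cytoplasm rows point both parent ids at max-existing-id + 1 within their
image, guaranteeing a non-match without colliding with real objects;
feature values are standard normal draws.
"""

from __future__ import annotations

import csv
import io
import sqlite3
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model import SourceSpec, ensure_path

__all__ = [
    "FixtureParams",
    "generate_cellprofiler_fixture",
    "generate_deepprofiler_fixture",
    "generate_incarta_fixture",
    "expected_join_rowcount",
    "nested_loop_join",
    "MIXED_TYPE_TOKEN",
]

#: Stray text planted in numeric columns to exercise mixed-type handling.
MIXED_TYPE_TOKEN = "smudge"


@dataclass(frozen=True)
class FixtureParams:
    """Ground-truth parameters for a CellProfiler-style fixture."""

    n_images: int = 2
    cells_per_image: int = 3
    features_per_compartment: int = 5
    orphan_fraction: float = 0.0
    mixed_type_injections: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1 or self.cells_per_image < 1:
            raise ValueError("n_images and cells_per_image must be >= 1")
        if self.features_per_compartment < 1:
            raise ValueError("features_per_compartment must be >= 1")
        if not 0.0 <= self.orphan_fraction <= 1.0:
            raise ValueError("orphan_fraction must be in [0, 1]")
        if self.mixed_type_injections < 0:
            raise ValueError("mixed_type_injections must be >= 0")


# ---------------------------------------------------------------------------
# Object graph (shared ground truth for generator and oracle)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _CytoplasmRow:
    image: int
    obj: int
    parent_cells: int
    parent_nuclei: int
    orphan: bool


def _build_graph(params: FixtureParams) -> List[_CytoplasmRow]:
    """Deterministic linked-object graph; pure function of params."""
    rng = np.random.default_rng([params.seed, 0])
    total = params.n_images * params.cells_per_image
    n_orphans = int(round(params.orphan_fraction * total))
    orphan_positions = set(
        rng.choice(total, size=n_orphans, replace=False).tolist()
    ) if n_orphans else set()

    rows: List[_CytoplasmRow] = []
    pos = 0
    orphan_counter: Dict[int, int] = {}
    for image in range(1, params.n_images + 1):
        for obj in range(1, params.cells_per_image + 1):
            if pos in orphan_positions:
                orphan_counter[image] = orphan_counter.get(image, 0) + 1
                dangling = params.cells_per_image + orphan_counter[image]
                rows.append(_CytoplasmRow(image, obj, dangling, dangling, True))
            else:
                rows.append(_CytoplasmRow(image, obj, obj, obj, False))
            pos += 1
    return rows


def _well_name(i: int) -> str:
    return f"{chr(ord('A') + (i // 12) % 8)}{(i % 12) + 1:02d}"


def _feature_names(n: int) -> List[str]:
    width = len(str(max(n - 1, 0)))
    return [f"AreaShape_Feature_{str(j).zfill(width)}" for j in range(n)]


def _format_value(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _build_tables(params: FixtureParams) -> Dict[str, Tuple[List[str], List[list]]]:
    """All four tables as (header, rows); values already finalized."""
    graph = _build_graph(params)
    rng_values = np.random.default_rng([params.seed, 1])
    rng_inject = np.random.default_rng([params.seed, 2])
    feats = _feature_names(params.features_per_compartment)

    image_header = ["ImageNumber", "Metadata_Plate", "Metadata_Well",
                    "Count_Cells", "Width_DNA"]
    image_rows = [
        [i, "Plate1", _well_name(i - 1), params.cells_per_image,
         float(rng_values.normal())]
        for i in range(1, params.n_images + 1)
    ]

    def object_table(with_parents: bool) -> Tuple[List[str], List[list]]:
        header = ["ImageNumber", "ObjectNumber"]
        if with_parents:
            header += ["Parent_Cells", "Parent_Nuclei"]
        header += feats
        rows = []
        for row in graph:
            values = [row.image, row.obj]
            if with_parents:
                values += [row.parent_cells, row.parent_nuclei]
            values += [float(v) for v in rng_values.normal(size=len(feats))]
            rows.append(values)
        return header, rows

    cells = object_table(False)
    nuclei = object_table(False)
    cytoplasm = object_table(True)

    # plant stray text in the Cells feature columns, round-robin over
    # columns so each keeps a numeric majority (>50% of non-null values)
    n_rows = len(cells[1])
    n_feats = len(feats)
    capacity = max((n_rows - 1) // 2, 0) * n_feats
    if params.mixed_type_injections > capacity:
        raise ValueError(
            f"cannot place {params.mixed_type_injections} injections while "
            f"keeping numeric majorities (capacity {capacity})"
        )
    feat_offset = 2  # Cells table: ImageNumber, ObjectNumber, then features
    used: Dict[int, set] = {}
    for i in range(params.mixed_type_injections):
        col = i % n_feats
        taken = used.setdefault(col, set())
        free = [r for r in range(n_rows) if r not in taken]
        r = int(rng_inject.choice(len(free)))
        taken.add(free[r])
        cells[1][free[r]][feat_offset + col] = MIXED_TYPE_TOKEN

    return {
        "image": (image_header, image_rows),
        "cells": cells,
        "nuclei": nuclei,
        "cytoplasm": cytoplasm,
    }


# ---------------------------------------------------------------------------
# CellProfiler-layout writers
# ---------------------------------------------------------------------------

_CSV_FILENAMES = {
    "image": "Image.csv",
    "cells": "Cells.csv",
    "nuclei": "Nuclei.csv",
    "cytoplasm": "Cytoplasm.csv",
}
_SQLITE_TABLES = {
    "image": "Per_Image",
    "cells": "Per_Cells",
    "nuclei": "Per_Nuclei",
    "cytoplasm": "Per_Cytoplasm",
}
_CYTOMINER_TABLES = {
    "image": "image",
    "cells": "cells",
    "nuclei": "nuclei",
    "cytoplasm": "cytoplasm",
}


def generate_cellprofiler_fixture(params: FixtureParams, layout: str, dest):
    """Write a CellProfiler-style export under ``dest``; return its sources.

    ``layout`` is ``csv-dir`` (spreadsheet export: four CSVs per directory),
    ``sqlite-db`` (database export: four ``Per_*`` tables in one file), or
    ``cytominer-sqlite`` (legacy lowercase tables with a ``TableNumber``
    batching key).  Returns the discovered :class:`SourceGroupMap` for the
    matching registry preset.
    """
    from .discovery import discover_sources
    from .presets import get_preset

    dest = ensure_path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    tables = _build_tables(params)

    if layout == "csv-dir":
        for role, (header, rows) in tables.items():
            with open(dest / _CSV_FILENAMES[role], "w", newline="") as fh:
                writer = csv.writer(fh, lineterminator="\r\n")
                writer.writerow(header)
                for row in rows:
                    writer.writerow([_format_value(v) for v in row])
        return discover_sources(dest, get_preset("cellprofiler_csv"))

    if layout in ("sqlite-db", "cytominer-sqlite"):
        names = _SQLITE_TABLES if layout == "sqlite-db" else _CYTOMINER_TABLES
        preset_name = (
            "cellprofiler_sqlite"
            if layout == "sqlite-db"
            else "cell-health-cellprofiler-to-cytominer-database"
        )
        db = dest / "plate.sqlite"
        if db.exists():
            db.unlink()
        conn = sqlite3.connect(db)
        try:
            for role, (header, rows) in tables.items():
                if layout == "cytominer-sqlite":
                    header = ["TableNumber"] + header
                    rows = [[1] + row for row in rows]
                cols = ", ".join(f'"{c}"' for c in header)
                conn.execute(f'CREATE TABLE "{names[role]}" ({cols})')
                ph = ", ".join("?" for _ in header)
                conn.executemany(
                    f'INSERT INTO "{names[role]}" VALUES ({ph})', rows
                )
            conn.commit()
        finally:
            conn.close()
        return discover_sources(db, get_preset(preset_name))

    raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# DeepProfiler / IN Carta layouts
# ---------------------------------------------------------------------------


def _write_npz_deterministic(path: Path, members: Mapping[str, np.ndarray]) -> None:
    """NPZ writer with fixed zip timestamps so bytes depend only on data."""
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for name, arr in members.items():
            buf = io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arr), allow_pickle=False)
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def generate_deepprofiler_fixture(
    n_cells: int, n_features: int, seed: int, dest
) -> SourceSpec:
    """Write one DeepProfiler-style NPZ feature archive.

    Members: ``features`` (n_cells × n_features float matrix),
    ``Metadata_Well`` and ``Metadata_Site`` per-row metadata arrays.
    """
    dest = ensure_path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([seed, 3])
    path = dest / "profile_site1.npz"
    wells = np.array([_well_name(i % 96) for i in range(n_cells)])
    sites = np.arange(1, n_cells + 1, dtype=np.int64)
    features = rng.normal(size=(n_cells, n_features)).astype(np.float64)
    _write_npz_deterministic(
        path,
        {"features": features, "Metadata_Well": wells, "Metadata_Site": sites},
    )
    return SourceSpec(
        path=str(path),
        kind="array-archive",
        table_name=path.stem,
        group_key=".",
        declared_row_count=n_cells,
        role="profile",
    )


def generate_incarta_fixture(
    n_objects: int, n_features: int, seed: int, dest
) -> SourceSpec:
    """Write one IN Carta-style per-object CSV (id + well + features)."""
    dest = ensure_path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([seed, 4])
    path = dest / "objects.csv"
    header = ["ObjectID", "Well"] + [
        f"Feature_{j + 1}" for j in range(n_features)
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\r\n")
        writer.writerow(header)
        for i in range(n_objects):
            row = [i + 1, _well_name(i % 96)] + [
                repr(float(v)) for v in rng.normal(size=n_features)
            ]
            writer.writerow(row)
    return SourceSpec(
        path=str(path),
        kind="delimited-text",
        table_name=path.stem,
        group_key=".",
        declared_row_count=n_objects,
        role="objects",
    )


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

_DEFAULT_POLICY = {"image": "inner", "cells": "left", "nuclei": "left"}


def expected_join_rowcount(
    params: FixtureParams, join_policy: Optional[Mapping[str, str]] = None
) -> int:
    """Output row count by direct enumeration of the generated object graph.

    Computed without the join engine: walks the cytoplasm rows and checks,
    per joined table and its policy, whether a matching object exists.
    Under a left policy a dangling parent keeps its row (nulls fill in);
    under inner it is dropped.
    """
    policy = dict(_DEFAULT_POLICY)
    if join_policy:
        policy.update(join_policy)
    count = 0
    for row in _build_graph(params):
        # image always exists for a generated object
        cells_match = not row.orphan
        nuclei_match = not row.orphan
        if policy.get("cells", "left") == "inner" and not cells_match:
            continue
        if policy.get("nuclei", "left") == "inner" and not nuclei_match:
            continue
        count += 1
    return count


def nested_loop_join(
    tables: Mapping[str, Sequence[Mapping]],
    base: str,
    steps: Sequence[Tuple[str, str, Sequence[str], Sequence[str]]],
) -> List[dict]:
    """Naive nested-loop join oracle over row dictionaries.

    ``steps`` are ``(right_table, join_kind, left_keys, right_keys)`` in
    execution order.  Implemented with plain loops and per-row scans,
    independently of the join engine, so the two can be compared as row
    multisets.
    """
    acc: List[dict] = [dict(r) for r in tables[base]]
    for right_name, kind, left_keys, right_keys in steps:
        right = tables[right_name]
        right_extra = [
            k for k in (right[0].keys() if right else []) if k not in right_keys
        ]
        out: List[dict] = []
        for row in acc:
            matches = []
            for cand in right:
                ok = True
                for lk, rk in zip(left_keys, right_keys):
                    if row.get(lk) is None or row.get(lk) != cand.get(rk):
                        ok = False
                        break
                if ok:
                    matches.append(cand)
            if matches:
                for cand in matches:
                    merged = dict(row)
                    for k in right_extra:
                        merged[k] = cand[k]
                    out.append(merged)
            elif kind == "left":
                merged = dict(row)
                for k in right_extra:
                    merged[k] = None
                out.append(merged)
            # inner + no match: drop row
        acc = out
    return acc
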