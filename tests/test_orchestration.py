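"""Work-plan construction, executor contracts, and end-to-end convert."""

import dataclasses
import hashlib

import pytest

from phenotable.discovery import discover_sources
from phenotable.fixtures import (
    FixtureParams,
    expected_join_rowcount,
    generate_cellprofiler_fixture,
    generate_deepprofiler_fixture,
)
from phenotable.model import PhenotableError, SourceSpec, TaskExecutionError
from phenotable.orchestrate import Task, WorkPlan, build_workplan, convert, execute_workplan
from phenotable.presets import get_preset


def digest(path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@pytest.fixture
def small_groups(tmp_path):
    params = FixtureParams(n_images=2, cells_per_image=3, seed=20)
    groups = generate_cellprofiler_fixture(params, "csv-dir", tmp_path / "src")
    return params, tmp_path, groups


# ---------------------------------------------------------------------------
# build_workplan
# ---------------------------------------------------------------------------


def test_workplan_structure_single_group(small_groups):
    _, tmp, groups = small_groups
    plan = build_workplan(groups, get_preset("cellprofiler_csv"), tmp / "out")
    kinds = [t.kind for t in plan.tasks.values()]
    assert kinds.count("extract") == 4  # one page per source at default chunk
    assert kinds.count("harmonize") == 4
    assert kinds.count("join") >= 1
    assert kinds.count("concat") == 1
    assert kinds.count("write") == 1
    plan.validate()  # acyclic with satisfied inputs


def test_workplan_two_groups_are_disjoint_subgraphs(tmp_path):
    for plate in ("p1", "p2"):
        generate_cellprofiler_fixture(FixtureParams(seed=21), "csv-dir", tmp_path / plate)
    groups = discover_sources(tmp_path, get_preset("cellprofiler_csv"))
    plan = build_workplan(groups, get_preset("cellprofiler_csv"), tmp_path / "out")
    assert [t for t in plan.tasks.values() if t.kind == "write"].__len__() == 2
    prefixes = {t.task_id.split("-")[0] for t in plan.tasks.values()}
    assert prefixes == {"g000", "g001"}
    for a, b in plan.edges:
        assert a.split("-")[0] == b.split("-")[0]  # no cross-group edges


def test_workplan_zero_groups_is_error(tmp_path):
    from phenotable.discovery import SourceGroupMap

    with pytest.raises(PhenotableError):
        build_workplan(SourceGroupMap(groups={}), get_preset("cellprofiler_csv"), tmp_path)


def test_workplan_page_counts_follow_chunk_size(small_groups):
    _, tmp, groups = small_groups
    preset = get_preset("cellprofiler_csv")
    preset.chunk_size = 2
    plan = build_workplan(groups, preset, tmp / "out")
    extracts = [t for t in plan.tasks.values() if t.kind == "extract"]
    # image: 2 rows -> 1 page; each compartment: 6 rows -> 3 pages
    assert len(extracts) == 1 + 3 * 3
    joins = [t for t in plan.tasks.values() if t.kind == "join"]
    assert len(joins) == 2  # 2 images, <=2 base rows per key page


def test_cycle_detection():
    t1 = Task("a", "concat", ("b",), {"key_columns": []})
    t2 = Task("b", "concat", ("a",), {"key_columns": []})
    plan = WorkPlan(tasks={"a": t1, "b": t2}, edges=[("a", "b"), ("b", "a")],
                    preset=get_preset("cellprofiler_csv"))
    with pytest.raises(PhenotableError, match="cycle"):
        plan.validate()


# ---------------------------------------------------------------------------
# execute_workplan / convert
# ---------------------------------------------------------------------------


def test_convert_csv_fixture_row_count_matches_oracle(small_groups):
    params, tmp, _ = small_groups
    manifest = convert(tmp / "src", tmp / "out", mode="serial")
    assert manifest.total_rows == expected_join_rowcount(params) == 6
    entry = next(iter(manifest.groups.values()))
    assert "LEFT JOIN nuclei" in entry.plan_text


@pytest.mark.parametrize("mode,workers", [("serial", 1), ("multiprocess", 4), ("multithread", 4), ("multithread", 1)])
def test_outputs_identical_across_executors(small_groups, mode, workers):
    params, tmp, _ = small_groups
    baseline = convert(tmp / "src", tmp / "base", mode="serial")
    manifest = convert(tmp / "src", tmp / f"out-{mode}-{workers}", mode=mode, workers=workers)
    assert manifest.total_rows == baseline.total_rows
    base_entry = next(iter(baseline.groups.values()))
    entry = next(iter(manifest.groups.values()))
    assert digest(tmp / "base" / "group.parquet") == digest(
        tmp / f"out-{mode}-{workers}" / "group.parquet"
    )
    assert (entry.rows, entry.columns) == (base_entry.rows, base_entry.columns)


@pytest.mark.parametrize("chunk_size", [1, 2, 100_000])
def test_outputs_identical_across_chunk_sizes(small_groups, chunk_size):
    _, tmp, _ = small_groups
    convert(tmp / "src", tmp / "base", mode="serial")
    convert(
        tmp / "src", tmp / f"out-{chunk_size}",
        overrides={"chunk_size": chunk_size}, mode="serial",
    )
    assert digest(tmp / "base" / "group.parquet") == digest(
        tmp / f"out-{chunk_size}" / "group.parquet"
    )


def test_failing_extract_cancels_dependents_and_names_task(small_groups):
    _, tmp, groups = small_groups
    preset = get_preset("cellprofiler_csv")
    plan = build_workplan(groups, preset, tmp / "out")
    ex_id = next(t for t in plan.tasks.values() if t.kind == "extract").task_id
    broken = dataclasses.replace(
        plan.tasks[ex_id],
        params={
            **plan.tasks[ex_id].params,
            "source": SourceSpec(
                path=str(tmp / "missing.csv"), kind="delimited-text",
                table_name="gone", group_key=".", role="image",
            ),
        },
    )
    plan.tasks[ex_id] = broken
    with pytest.raises(TaskExecutionError) as exc:
        execute_workplan(plan, mode="serial")
    assert exc.value.task_id == ex_id
    assert not (tmp / "out").exists()  # write task never ran


def test_deepprofiler_single_table_convert(tmp_path):
    generate_deepprofiler_fixture(5, 10, seed=22, dest=tmp_path / "dp")
    manifest = convert(
        tmp_path / "dp", tmp_path / "out", preset_name="deepprofiler", mode="serial"
    )
    assert manifest.total_rows == 5
    entry = next(iter(manifest.groups.values()))
    assert entry.plan_text == ""  # no join for single-table sources


def test_convert_coercion_warnings_equal_injections(tmp_path):
    params = FixtureParams(
        n_images=2, cells_per_image=5, mixed_type_injections=4, seed=23
    )
    generate_cellprofiler_fixture(params, "csv-dir", tmp_path / "src")
    manifest = convert(tmp_path / "src", tmp_path / "out", mode="serial")
    assert manifest.total_coercions == 4
    assert manifest.total_rows == 10


def test_convert_sqlite_and_cytominer_layouts(tmp_path):
    params = FixtureParams(n_images=2, cells_per_image=3, seed=24)
    generate_cellprofiler_fixture(params, "sqlite-db", tmp_path / "sq")
    m1 = convert(
        tmp_path / "sq" / "plate.sqlite", tmp_path / "o1",
        preset_name="cellprofiler_sqlite", mode="serial",
    )
    generate_cellprofiler_fixture(params, "cytominer-sqlite", tmp_path / "cm")
    m2 = convert(
        tmp_path / "cm" / "plate.sqlite", tmp_path / "o2",
        preset_name="cell-health-cellprofiler-to-cytominer-database", mode="serial",
    )
    assert m1.total_rows == m2.total_rows == 6
    entry = next(iter(m2.groups.values()))
    assert "Metadata_TableNumber" in entry.plan_text


def test_convert_to_explicit_file_path(tmp_path, small_groups):
    _, tmp, _ = small_groups
    manifest = convert(tmp / "src", tmp_path / "cells.parquet", mode="serial")
    entry = next(iter(manifest.groups.values()))
    assert entry.path == str(tmp_path / "cells.parquet")
    assert (tmp_path / "cells.parquet").exists()


@pytest.mark.parametrize("fmt", ["csv", "sqlite", "h5ad"])
def test_convert_alternate_output_formats(small_groups, fmt):
    _, tmp, _ = small_groups
    manifest = convert(tmp / "src", tmp / f"out-{fmt}", fmt=fmt, mode="serial")
    entry = next(iter(manifest.groups.values()))
    assert entry.rows == 6
    from pathlib import Path

    assert Path(entry.path).exists()
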