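"""Join plan compilation and execution against the nested-loop oracle."""

import dataclasses
from collections import Counter

import pyarrow as pa
import pytest
from hypothesis import given, settings, strategies as st

from phenotable.fixtures import (
    FixtureParams,
    generate_cellprofiler_fixture,
    nested_loop_join,
)
from phenotable.harmonize import apply_naming, cast_columns
from phenotable.joins import compile_join_plan, execute_join, page_join_keys
from phenotable.model import JoinClause, JoinCompileError
from phenotable.presets import get_preset
from phenotable.readers import read_chunk, scan_column_types

from conftest import make_chunk


def harmonized_tables(root, preset):
    """Read and harmonize every discovered table of a CSV fixture."""
    from phenotable.discovery import discover_sources

    tables = {}
    for spec in discover_sources(root, preset).all_sources():
        schema = scan_column_types(spec, preset)
        chunk = read_chunk(spec, schema, 0, 1 << 32, preset)
        tables[spec.role] = cast_columns(apply_naming(chunk, preset, spec.role), preset)
    return tables


def multiset(rows, names):
    return Counter(tuple(r.get(n) for n in names) for r in rows)


def run_engine_and_oracle(params, tmp, preset=None):
    preset = preset or get_preset("cellprofiler_csv")
    generate_cellprofiler_fixture(params, "csv-dir", tmp)
    tables = harmonized_tables(tmp, preset)
    plan = compile_join_plan(preset, {r: t.schema for r, t in tables.items()})
    joined = execute_join(plan, tables)
    steps = [
        (s.right_table, s.join_kind, s.left_keys, s.right_keys) for s in plan.steps
    ]
    oracle = nested_loop_join(
        {r: t.to_pylist() for r, t in tables.items()}, "cytoplasm", steps
    )
    return joined, oracle


# ---------------------------------------------------------------------------
# compile_join_plan
# ---------------------------------------------------------------------------


def test_cellprofiler_preset_compiles_three_steps(tmp_path):
    preset = get_preset("cellprofiler_csv")
    generate_cellprofiler_fixture(FixtureParams(seed=1), "csv-dir", tmp_path)
    tables = harmonized_tables(tmp_path, preset)
    plan = compile_join_plan(preset, {r: t.schema for r, t in tables.items()})
    assert [(s.right_table, s.join_kind) for s in plan.steps] == [
        ("image", "inner"), ("cells", "left"), ("nuclei", "left"),
    ]
    sql = plan.sql()
    assert "INNER JOIN image" in sql and "LEFT JOIN nuclei" in sql


def test_missing_optional_compartment_drops_clause_with_warning(tmp_path):
    preset = get_preset("cellprofiler_csv")
    generate_cellprofiler_fixture(FixtureParams(seed=1), "csv-dir", tmp_path)
    tables = harmonized_tables(tmp_path, preset)
    tables.pop("nuclei")
    plan = compile_join_plan(preset, {r: t.schema for r, t in tables.items()})
    assert len(plan.steps) == 2
    assert any("nuclei" in w for w in plan.warnings)


def test_missing_inner_table_is_compile_error(tmp_path):
    preset = get_preset("cellprofiler_csv")
    generate_cellprofiler_fixture(FixtureParams(seed=1), "csv-dir", tmp_path)
    tables = harmonized_tables(tmp_path, preset)
    tables.pop("image")
    with pytest.raises(JoinCompileError, match="image"):
        compile_join_plan(preset, {r: t.schema for r, t in tables.items()})


def test_clause_on_nonexistent_column_is_compile_error(tmp_path):
    preset = get_preset("cellprofiler_csv")
    preset.identifying_columns.append("Parent_Golgi")
    preset.joins.append(
        JoinClause("cytoplasm", "Parent_Golgi", "cells", "ObjectNumber", "left")
    )
    generate_cellprofiler_fixture(FixtureParams(seed=1), "csv-dir", tmp_path)
    tables = harmonized_tables(tmp_path, preset)
    with pytest.raises(JoinCompileError, match="Parent_Golgi"):
        compile_join_plan(preset, {r: t.schema for r, t in tables.items()})


# ---------------------------------------------------------------------------
# execute_join
# ---------------------------------------------------------------------------


def test_clean_fixture_yields_images_times_cells_rows(tmp_path):
    joined, oracle = run_engine_and_oracle(
        FixtureParams(n_images=2, cells_per_image=3, seed=2), tmp_path
    )
    assert joined.row_count == 6
    assert len(oracle) == 6
    assert joined.grain == "one row per cytoplasm object"


def test_orphan_row_retained_with_null_cells_columns(tmp_path):
    params = FixtureParams(n_images=1, cells_per_image=3, orphan_fraction=0.34, seed=3)
    joined, _ = run_engine_and_oracle(params, tmp_path)
    assert joined.row_count == 3  # left join keeps the orphan
    cells_cols = [n for n in joined.column_names if n.startswith("Cells_")]
    nulls = joined.table.column(cells_cols[0]).null_count
    assert nulls == 1


def test_empty_base_table_keeps_full_schema(tmp_path):
    preset = get_preset("cellprofiler_csv")
    generate_cellprofiler_fixture(FixtureParams(seed=4), "csv-dir", tmp_path)
    tables = harmonized_tables(tmp_path, preset)
    empty = tables["cytoplasm"].table.slice(0, 0)
    tables["cytoplasm"] = dataclasses.replace(tables["cytoplasm"], table=empty)
    plan = compile_join_plan(preset, {r: t.schema for r, t in tables.items()})
    joined = execute_join(plan, tables)
    assert joined.row_count == 0
    assert joined.column_names == [c.name for c in plan.output_columns]


def test_duplicate_parent_multiplies_rows_and_warns(tmp_path):
    preset = get_preset("cellprofiler_csv")
    generate_cellprofiler_fixture(
        FixtureParams(n_images=1, cells_per_image=2, seed=5), "csv-dir", tmp_path
    )
    tables = harmonized_tables(tmp_path, preset)
    cells = tables["cells"].table
    dup = pa.concat_tables([cells, cells.slice(0, 1)])  # duplicate ObjectNumber 1
    tables["cells"] = dataclasses.replace(tables["cells"], table=dup)
    plan = compile_join_plan(preset, {r: t.schema for r, t in tables.items()})
    joined = execute_join(plan, tables)
    assert joined.row_count == 3  # 2 cells + 1 duplicated match
    assert any("duplicate" in w for w in joined.warnings)


def test_canonical_sort_ascending_by_keys(tmp_path):
    joined, _ = run_engine_and_oracle(
        FixtureParams(n_images=3, cells_per_image=4, seed=6), tmp_path
    )
    keys = list(
        zip(
            joined.table.column("Metadata_ImageNumber").to_pylist(),
            joined.table.column("Metadata_ObjectNumber").to_pylist(),
        )
    )
    assert keys == sorted(keys)


@settings(max_examples=10)
@given(
    n_images=st.integers(1, 3),
    cells=st.integers(1, 12),
    orphan=st.sampled_from([0.0, 0.2, 0.5]),
    seed=st.integers(0, 10_000),
)
def test_engine_matches_nested_loop_oracle(
    n_images, cells, orphan, seed, tmp_path_factory
):
    """Row multiset equals the independent oracle on random fixtures."""
    tmp = tmp_path_factory.mktemp("oracle")
    params = FixtureParams(
        n_images=n_images, cells_per_image=cells, orphan_fraction=orphan, seed=seed
    )
    joined, oracle = run_engine_and_oracle(params, tmp)
    names = joined.column_names
    assert multiset(joined.to_pylist(), names) == multiset(oracle, names)


def test_left_join_monotonicity_under_row_deletion(tmp_path):
    """Deleting a non-base row never shrinks a left-joined output."""
    preset = get_preset("cellprofiler_csv")
    generate_cellprofiler_fixture(
        FixtureParams(n_images=2, cells_per_image=4, seed=7), "csv-dir", tmp_path
    )
    tables = harmonized_tables(tmp_path, preset)
    plan = compile_join_plan(preset, {r: t.schema for r, t in tables.items()})
    full = execute_join(plan, tables).row_count
    pruned = dict(tables)
    cells = tables["cells"].table
    pruned["cells"] = dataclasses.replace(
        tables["cells"], table=cells.slice(1, cells.num_rows - 1)
    )
    assert execute_join(plan, pruned).row_count >= full - 0  # still 8: left join
    assert execute_join(plan, pruned).row_count == full


# ---------------------------------------------------------------------------
# page_join_keys
# ---------------------------------------------------------------------------


def test_page_join_keys_greedy_cover():
    base = make_chunk({"Metadata_K": ("integer-key", [1, 1, 2, 2, 3, 3])})
    assert page_join_keys(base, "Metadata_K", 4) == [(1, 2), (3, 3)]


def test_page_join_keys_isolates_oversized_key():
    base = make_chunk({"Metadata_K": ("integer-key", [1, 1])})
    assert page_join_keys(base, "Metadata_K", 1) == [(1, 1)]


def test_page_join_keys_empty_base():
    base = make_chunk({"Metadata_K": ("integer-key", [])})
    assert page_join_keys(base, "Metadata_K", 5) == []


def test_page_join_keys_rejects_non_key_column():
    base = make_chunk({"Cells_A": ("float-feature", [1.0])})
    with pytest.raises(JoinCompileError):
        page_join_keys(base, "Cells_A", 5)


@given(chunk_size=st.integers(1, 10))
def test_paged_join_union_equals_unpaged(chunk_size, tmp_path_factory):
    """Joining per key page and concatenating equals the unpaged join."""
    tmp = tmp_path_factory.mktemp("paged")
    preset = get_preset("cellprofiler_csv")
    params = FixtureParams(n_images=3, cells_per_image=3, seed=8)
    generate_cellprofiler_fixture(params, "csv-dir", tmp)
    tables = harmonized_tables(tmp, preset)
    plan = compile_join_plan(preset, {r: t.schema for r, t in tables.items()})
    whole = execute_join(plan, tables)

    base = tables["cytoplasm"]
    parts = []
    for lo, hi in page_join_keys(base, "Metadata_ImageNumber", chunk_size):
        import pyarrow.compute as pc

        mask = pc.and_(
            pc.greater_equal(base.table.column("Metadata_ImageNumber"), pa.scalar(lo)),
            pc.less_equal(base.table.column("Metadata_ImageNumber"), pa.scalar(hi)),
        )
        sub = dict(tables)
        sub["cytoplasm"] = dataclasses.replace(base, table=base.table.filter(mask))
        parts.append(execute_join(plan, sub).table)
    merged = pa.concat_tables(parts).sort_by(
        [(k, "ascending") for k in plan.key_columns]
    )
    assert merged.equals(whole.table)
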