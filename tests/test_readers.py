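"""Typed, paged reading of delimited text, SQLite, and NPZ archives."""

import csv
import sqlite3

import numpy as np
import pyarrow as pa
import pytest
from hypothesis import given, strategies as st

from phenotable.fixtures import generate_deepprofiler_fixture
from phenotable.model import (
    ArchiveError,
    CastError,
    MalformedRecordError,
    MixedTypeError,
    SourceSpec,
)
from phenotable.presets import get_preset
from phenotable.readers import (
    count_rows,
    read_array_archive,
    read_delimited_chunk,
    read_sqlite_chunk,
    scan_column_types,
)


def write_csv(path, header, rows):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)
    return SourceSpec(
        path=str(path), kind="delimited-text", table_name=path.stem,
        group_key=".", role="cells",
    )


@pytest.fixture
def preset():
    return get_preset("cellprofiler_csv")


# ---------------------------------------------------------------------------
# scan_column_types
# ---------------------------------------------------------------------------


def test_scan_identifying_integer_column(tmp_path, preset):
    src = write_csv(tmp_path / "t.csv", ["ImageNumber"], [[1], [2], [2]])
    (col,) = scan_column_types(src, preset)
    assert col.declared_type == "integer-key"
    assert not col.nullable


def test_scan_all_integer_feature_column_is_float(tmp_path, preset):
    src = write_csv(tmp_path / "t.csv", ["Count_Spots"], [[1], [2]])
    (col,) = scan_column_types(src, preset)
    assert col.declared_type == "float-feature"


def test_scan_mixed_numeric_majority_coerces_to_nullable_float(tmp_path, preset):
    src = write_csv(tmp_path / "t.csv", ["AreaShape_Area"], [[10.5], ["bad"], [11.0]])
    (col,) = scan_column_types(src, preset)
    assert (col.declared_type, col.nullable) == ("float-feature", True)


def test_scan_mixed_column_strict_fail_names_first_offender(tmp_path, preset):
    preset.type_policy = "strict-fail"
    src = write_csv(tmp_path / "t.csv", ["AreaShape_Area"], [[10.5], ["bad"], [11.0]])
    with pytest.raises(MixedTypeError, match="row 2"):
        scan_column_types(src, preset)


def test_scan_text_majority_stays_text(tmp_path, preset):
    src = write_csv(
        tmp_path / "t.csv", ["Metadata_Gene"], [["KRAS"], ["TP53"], [7]]
    )
    (col,) = scan_column_types(src, preset)
    assert col.declared_type == "text"


def test_scan_is_row_order_insensitive(tmp_path, preset):
    rows = [[1, 0.5, "A01"], [2, "bad", "B02"], [3, 1.5, "C03"]]
    header = ["ImageNumber", "AreaShape_Area", "Metadata_Well"]
    src = write_csv(tmp_path / "a.csv", header, rows)
    shuffled = write_csv(tmp_path / "b.csv", header, rows[::-1])
    a = [(c.name, c.declared_type, c.nullable) for c in scan_column_types(src, preset)]
    b = [(c.name, c.declared_type, c.nullable) for c in scan_column_types(shuffled, preset)]
    assert a == b


# ---------------------------------------------------------------------------
# read_delimited_chunk paging
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "offset,limit,expected_rows",
    [(4, 3, [5, 6, 7]), (9, 3, [10]), (10, 3, []), (0, 10, list(range(1, 11)))],
)
def test_delimited_page_slicing(tmp_path, preset, offset, limit, expected_rows):
    src = write_csv(
        tmp_path / "t.csv", ["ImageNumber"], [[i] for i in range(1, 11)]
    )
    schema = scan_column_types(src, preset)
    chunk = read_delimited_chunk(src, schema, offset, limit)
    assert chunk.table.column("ImageNumber").to_pylist() == expected_rows
    assert chunk.column_names == ["ImageNumber"]  # schema kept even when empty


@given(page_size=st.integers(min_value=1, max_value=12))
def test_concatenated_pages_reproduce_full_table(page_size, tmp_path_factory):
    tmp = tmp_path_factory.mktemp("pages")
    preset = get_preset("cellprofiler_csv")
    rows = [[i, float(i) / 3] for i in range(1, 11)]
    src = write_csv(tmp / "t.csv", ["ImageNumber", "AreaShape_Area"], rows)
    schema = scan_column_types(src, preset)
    whole = read_delimited_chunk(src, schema, 0, 100)
    pages = []
    offset = 0
    while True:
        page = read_delimited_chunk(src, schema, offset, page_size)
        if page.row_count == 0:
            break
        pages.append(page.table)
        offset += page_size
    assert pa.concat_tables(pages).equals(whole.table)


def test_malformed_record_reports_line_number(tmp_path, preset):
    path = tmp_path / "t.csv"
    path.write_text("A,B\n1,2\n3\n")
    src = SourceSpec(str(path), "delimited-text", "t", ".", role="cells")
    with pytest.raises(MalformedRecordError, match="line 3"):
        scan_column_types(src, preset)


def test_na_tokens_become_null_without_coercion(tmp_path, preset):
    src = write_csv(
        tmp_path / "t.csv",
        ["AreaShape_Area"],
        [[""], ["NA"], ["NaN"], ["nan"], [1.0], [2.0], [3.0], ["bad"]],
    )
    schema = scan_column_types(src, preset)
    chunk = read_delimited_chunk(src, schema, 0, 100)
    col = chunk.table.column("AreaShape_Area")
    # null count = NA tokens (4) + coercions (1)
    assert col.null_count == 5
    assert chunk.coercions == 1


def test_strict_fail_cast_error_on_stray_text(tmp_path, preset):
    src = write_csv(tmp_path / "t.csv", ["AreaShape_Area"], [[1.0], [2.0]])
    schema = scan_column_types(src, preset)
    bad = write_csv(tmp_path / "u.csv", ["AreaShape_Area"], [[1.0], ["oops"]])
    with pytest.raises(CastError, match="oops"):
        read_delimited_chunk(bad, schema, 0, 10, type_policy="strict-fail")


# ---------------------------------------------------------------------------
# read_sqlite_chunk
# ---------------------------------------------------------------------------


@pytest.fixture
def sqlite_source(tmp_path):
    db = tmp_path / "plate.sqlite"
    conn = sqlite3.connect(db)
    conn.execute(
        "CREATE TABLE per_cytoplasm (ImageNumber INTEGER, ObjectNumber INTEGER,"
        " AreaShape_Area REAL)"
    )
    rows = [(1, i, float(i)) for i in range(1, 6)] + [(2, 1, "nan")]
    conn.executemany("INSERT INTO per_cytoplasm VALUES (?,?,?)", rows)
    conn.commit()
    conn.close()
    return SourceSpec(str(db), "sqlite-db", "per_cytoplasm", ".", role="cytoplasm")


def test_sqlite_whole_table_page(sqlite_source, preset):
    schema = scan_column_types(sqlite_source, preset)
    chunk = read_sqlite_chunk(sqlite_source, schema, 0, 10)
    assert chunk.row_count == 6


def test_sqlite_text_in_numeric_column_coerces_and_counts(sqlite_source, preset):
    schema = scan_column_types(sqlite_source, preset)
    chunk = read_sqlite_chunk(sqlite_source, schema, 0, 10)
    area = chunk.table.column("AreaShape_Area")
    assert area.to_pylist()[5] is None
    assert chunk.coercions == 1


def test_sqlite_empty_page_past_end(sqlite_source, preset):
    schema = scan_column_types(sqlite_source, preset)
    chunk = read_sqlite_chunk(sqlite_source, schema, 6, 10)
    assert chunk.row_count == 0
    assert chunk.column_names == ["ImageNumber", "ObjectNumber", "AreaShape_Area"]


def test_sqlite_missing_table_lists_catalog(sqlite_source, preset):
    import dataclasses

    bad = dataclasses.replace(sqlite_source, table_name="per_mito")
    with pytest.raises(Exception, match="per_cytoplasm"):
        scan_column_types(bad, preset)


# ---------------------------------------------------------------------------
# read_array_archive
# ---------------------------------------------------------------------------


def test_archive_feature_naming_and_metadata(tmp_path):
    spec = generate_deepprofiler_fixture(5, 10, seed=0, dest=tmp_path)
    chunk = read_array_archive(spec, "DP")
    assert chunk.row_count == 5
    assert len(chunk.schema) == 12  # 2 metadata + 10 features
    feats = [n for n in chunk.column_names if n.startswith("DP_")]
    assert feats == [f"DP_{i}" for i in range(10)]


def test_archive_zero_padding_aligns_orders(tmp_path):
    spec = generate_deepprofiler_fixture(2, 12, seed=0, dest=tmp_path)
    chunk = read_array_archive(spec, "DP")
    feats = [n for n in chunk.column_names if n.startswith("DP_")]
    assert feats[0] == "DP_00" and feats[-1] == "DP_11"
    assert feats == sorted(feats)


def test_archive_empty_matrix(tmp_path):
    spec = generate_deepprofiler_fixture(0, 10, seed=0, dest=tmp_path)
    chunk = read_array_archive(spec, "DP")
    assert chunk.row_count == 0
    assert sum(n.startswith("DP_") for n in chunk.column_names) == 10


def test_archive_ragged_metadata_errors(tmp_path):
    np.savez(
        tmp_path / "bad.npz",
        features=np.zeros((5, 3)),
        Metadata_Well=np.array(["A01"] * 4),
    )
    spec = SourceSpec(str(tmp_path / "bad.npz"), "array-archive", "bad", ".")
    with pytest.raises(ArchiveError, match="5.*4"):
        read_array_archive(spec, "DP")


def test_archive_without_matrix_errors(tmp_path):
    np.savez(tmp_path / "bad.npz", Metadata_Well=np.array(["A01"]))
    spec = SourceSpec(str(tmp_path / "bad.npz"), "array-archive", "bad", ".")
    with pytest.raises(ArchiveError, match="no feature matrix"):
        read_array_archive(spec, "DP")


def test_count_rows_matches_reads(tmp_path, preset, sqlite_source):
    src = write_csv(tmp_path / "t.csv", ["ImageNumber"], [[i] for i in range(7)])
    assert count_rows(src) == 7
    assert count_rows(sqlite_source) == 6
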