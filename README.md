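# phenotable

Harmonize single-cell image-analysis feature exports into analysis-ready,
strictly typed columnar tables.

## The problem

High-content imaging (HCI) experiments segment cells from microscopy images
and measure thousands of morphology features per cell. The tools that do
this write their results in incompatible shapes:

- **CellProfiler** spreadsheet exports: one CSV per compartment
  (`Image.csv`, `Cells.csv`, `Nuclei.csv`, `Cytoplasm.csv`) per plate
  directory, linked by 1-based `ImageNumber`/`ObjectNumber` keys and
  `Parent_*` columns;
- **CellProfiler** database exports: the same tables inside a SQLite file
  (`Per_Image`, `Per_Cytoplasm`, …), with SQLite's affinity typing allowing
  stray strings inside numeric columns;
- **DeepProfiler**: per-site NPZ archives holding a dense cell × feature
  matrix plus metadata arrays;
- **IN Carta**: flat per-object CSVs;
- legacy **cytominer-database** SQLite files with lowercase tables and a
  `TableNumber` batching key.

Before any profiling statistics can be computed, these must be reconciled
into one table at a well-defined grain — one row per linked cell — with
consistent column names and unambiguous types. phenotable does exactly that
step, and only that step.

## What it does

A named **preset** (`cellprofiler_csv`, `cellprofiler_sqlite`,
`deepprofiler`, `in-carta`,
`cell-health-cellprofiler-to-cytominer-database`) bundles table selectors,
identifying (key) columns, and an ordered list of declarative join clauses.
Presets can be partially overridden at call time or via a YAML/JSON config.
The pipeline then runs as an acyclic task graph per source group (plate
directory or database file):

1. **discover** — classify files by extension, assign compartment roles,
   group per plate/database;
2. **extract** — two-pass typed reads: a scan resolves every column to
   `integer-key` / `float-feature` / `boolean` / `text` (stray text in a
   numeric-majority column is nulled and counted under `coerce-null`, or a
   hard error under `strict-fail`), then pages of rows are read against the
   resolved schema;
3. **harmonize** — identifying columns gain the `Metadata_` prefix, all
   other columns gain their compartment prefix (`Cells_`, `Nuclei_`,
   `Cytoplasm_`, `Image_`), idempotently; floats are stored at the
   configured width, keys as 64-bit integers;
4. **join** — the clauses compile to a plan rendered as ANSI SQL for audit
   and executed in memory: cytoplasm is the base compartment, the image
   table inner-joins on the image key, cells and nuclei left-join on
   (image key, parent id), so orphaned segmentation records surface as
   nulls instead of disappearing;
5. **write** — Parquet (default, snappy), CSV, SQLite (enforcing the
   engine's default 2,000-column limit), or AnnData H5AD with features as
   the matrix and `Metadata_` columns as per-cell annotations.

Execution is serial, multithreaded, or multiprocess behind one executor
contract; intermediate products spill to temporary Parquet files, and
outputs are canonically sorted by `(Metadata_ImageNumber,
Metadata_ObjectNumber)` so results are **byte-identical** across chunk
sizes, executors, and worker counts.

## Worked example

```python
from phenotable import convert
from phenotable.fixtures import FixtureParams, generate_cellprofiler_fixture

# a synthetic CellProfiler spreadsheet export: 2 images x 3 cells,
# one stray text value planted in a numeric feature column
params = FixtureParams(n_images=2, cells_per_image=3,
                       mixed_type_injections=1, seed=2)
generate_cellprofiler_fixture(params, "csv-dir", "scratch/plate1")

manifest = convert("scratch/plate1", "scratch/out",
                   preset_name="cellprofiler_csv", fmt="parquet")
print(manifest.to_json())
```

prints (paths abbreviated):

```json
{
  ".": {
    "group_key": ".",
    "path": "scratch/out/group.parquet",
    "rows": 6,
    "columns": 23,
    "coercion_warnings": 1,
    "plan_text": "SELECT ... FROM cytoplasm INNER JOIN image ON cytoplasm.Metadata_ImageNumber = image.Metadata_ImageNumber LEFT JOIN cells ON ... LEFT JOIN nuclei ON ... ORDER BY Metadata_ImageNumber ASC, Metadata_ObjectNumber ASC"
  }
}
```

`rows: 6` is the fixture's ground truth (2 images × 3 cells, one output row
per linked cell); `columns: 23` covers the four `Metadata_` keys, the image
metadata/features, and five features per compartment; `coercion_warnings:
1` is exactly the one planted stray value, nulled during ingestion.

The same is available from a shell:

```bash
phenotable make-fixture --dest plate1 --layout csv-dir --n-images 2 --cells-per-image 3
phenotable convert --source plate1 --dest out --preset cellprofiler_csv --format parquet --emit-plan
phenotable bench --table-path out/group.parquet --out report.csv
```

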