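# Methods

This note documents the data model, the procedures, and the design choices
behind phenotable, including the points where the design was genuinely
open and the package had to pick a convention.

## Data model and grain

Everything in flight is a `TableChunk`: a column-major page of rows backed
by an Arrow table, carrying a declared per-column schema
(`integer-key | float-feature | boolean | text`), its source and row
offset, and a count of values coerced to null while reading. The joined
output (`HarmonizedTable`) is at **cytoplasm grain**: one row per
cytoplasm object. The cytoplasm table is the base because, in
CellProfiler-style segmentations, it carries parent identifiers for both
the cell and nucleus segmented from the same object, so cytoplasm rows are
the natural spine linking all three compartments to one biological cell.
The image table is inner-joined (an object without an image row is
incoherent); cells and nuclei are left-joined so dangling parent ids —
usually segmentation errors — surface as null feature blocks rather than
silently dropping cells.

## Two-pass typing

Delimited text has no types, and SQLite's affinity typing permits text
inside numeric-declared columns. A first pass scans every column and
resolves it once:

- `integer-key` if every non-null value parses as an integer **and** the
  name is one of the preset's identifying columns (keys are pinned to
  integers; a non-integral key is always an error);
- `float-feature` if every non-null value is numeric;
- `boolean` for pure true/false columns;
- `text` otherwise — except that under the default `coerce-null` policy a
  column whose non-null values are **more than 50% numeric** resolves to a
  nullable `float-feature`, and its stray text values are nulled and
  counted during the read pass. Below that majority the column stays text;
  the threshold exists to avoid destroying genuine text metadata that
  happens to contain a few numerals. Under `strict-fail` any mixed column
  is an error naming the first offending row.

NA accounting distinguishes provenance: in delimited text the tokens
`"" / NA / NaN / nan` are the format's native spelling of null and are not
coercions; in SQLite, a text value stored in a numeric-declared column is
a storage-class conflict and counts as a coercion even when the text spells
an NA token. Under `coerce-null` the output null count therefore equals
the coercion count plus the input NA-token count.

## Naming

Identifying columns gain the `Metadata_` prefix; every other column gains
its capitalized compartment prefix (`Image_`, `Cells_`, `Nuclei_`,
`Cytoplasm_`, or any preset-declared role). Prefixing is idempotent — a
column already carrying its prefix is left alone — so harmonization can be
re-applied safely, and inputs that are already partially harmonized (e.g.
`Metadata_Plate` in CellProfiler image tables) pass through unchanged. The
target convention itself is a package decision aligned with what
downstream profiling software expects; post-rename collisions are errors
naming both origins, never silently resolved.

## Joins

Preset join clauses are single column pairs; consecutive clauses sharing
the same (left table, right table, kind) form one composite-key step, so
the cytoplasm→cells link matches on `(ImageNumber, Parent_Cells =
ObjectNumber)` as a single join. Plans always render as ANSI SQL text and
are logged and recorded in the output manifest, documenting the relational
structure regardless of the engine that executes them (pyarrow's in-memory
join engine here). Semantics are standard relational: duplicate matches
multiply rows — deduplicating would hide upstream segmentation errors — and
each duplicated key is warned about. Output is canonically sorted
ascending by `(Metadata_TableNumber,) Metadata_ImageNumber,
Metadata_ObjectNumber`, which is what makes chunked and parallel runs
byte-comparable. For large inputs the join is paged over contiguous ranges
of the image key, each range holding at most `chunk_size` base rows (a
single key larger than the budget is isolated in its own range); because
the image key is part of every join condition, the union of paged joins
equals the unpaged join exactly.

## Orchestration

Each source group (plate directory, or database file) becomes an
independent subgraph: one extract task per source per page, a harmonize
task per extract, one join task per key page, one concat, one write. Page
boundaries and schemas are resolved at plan time, so the graph is fully
static and acyclic. Execution follows the dataflow rule — a task runs when
its inputs exist — under serial, thread-pool, or process-pool executors
behind one contract; a failure cancels all dependents and surfaces the
first root cause with its task id. Intermediate products are spilled to
temporary Parquet files keyed by task id rather than held in memory,
keeping peak memory proportional to one page, not one table. Multiprocess
is the default mode (lowest peak memory per worker); multithreading is
offered where wall-clock matters more, since the readers and the Arrow
kernels release the interpreter lock for much of their work. The `seed`
parameter on execution exists only for interface symmetry with the fixture
generators: the pipeline itself is deterministic and ignores it.

## Serialization

Parquet is the default output (snappy compression), with the declared
schema embedded in file metadata so read-back restores values, declared
types, column order, and row order exactly — including empty strings,
nulls, and 8-byte floats. CSV output is RFC 4180 with floats written via
`repr` so the decimal text round-trips to the identical binary value; its
one structural loss is that null and empty string both serialize as an
empty field. Harmonized tables never contain raw empty strings (they are
nullified at ingestion by the NA-token rule), so the CSV round trip of
pipeline output is exact. The SQLite writer enforces the engine's default
2,000-column maximum instead of recompiling it away: wide morphology
tables genuinely do not fit this format under default settings, and
reproducing that incompatibility honestly is more useful than papering
over it. The H5AD writer partitions columns: float features form the dense
matrix (nulls stored as NaN, since dense numeric matrices have no distinct
null), everything else becomes per-cell annotations; every column lands on
exactly one side.

## Synthetic fixtures and oracles

The generators emulate each supported layout with a known object graph:
dense 1-based ids, exactly one nucleus and one cytoplasm per cell,
standard-normal feature values, optional orphaned cytoplasm rows (both
parent ids pointed at max-existing-id + 1 within the image, guaranteeing a
non-match without collisions), and an exact number of stray text values
planted round-robin across feature columns so each column keeps its
numeric majority. Generation is byte-deterministic; the NPZ writer fixes
zip timestamps so archives are reproducible too. What the fixtures do
**not** emulate: realistic morphology feature distributions, plate/batch
effects, correlated features, or the full CellProfiler feature-name
vocabulary. Passing tests therefore demonstrate structural correctness —
typing, naming, join semantics, conservation, determinism — not
statistical behavior on real screens.

Two independent oracles arbitrate the engine: a naive nested-loop join
over row dictionaries, and a direct enumeration of the generated object
graph that predicts output row counts under any inner/left policy. Both
are implemented without touching the join engine.

## Problem sizes and defaults

| parameter | default | why |
| --- | --- | --- |
| `chunk_size` | 100,000 rows | bounds page memory while keeping per-page overhead negligible |
| `type_policy` | `coerce-null` | real exports contain stray text; nulling-and-counting preserves data and visibility |
| `float_width` | 8 bytes | exact round trips; 4 bytes available where storage dominates |
| numeric-majority threshold | > 50% | below it, a column is more plausibly text metadata |
| bench repeats | 6 | median plus full range over repeated runs |

Test and acceptance runs use desk-scale fixtures (up to 2 images × 500
cells for oracle comparisons, 10,240 rows × 42 columns for format
timing), chosen so the full verification cycle completes in seconds on a
single CPU while still exercising paging, parallelism, and the join
multiplicity cases. Timing comparisons are emitted as observations with
their hardware-dependence labeled, never asserted as cross-machine
numbers.

## Known limitations

- Harmonization is structural, not semantic: feature names are never
  translated between tools.
- Cloud object-store inputs, gzipped CSVs, and Arrow IPC ingestion are out
  of scope.
- CSV output cannot distinguish null from empty string (documented above).
- The IN Carta and DeepProfiler selector patterns are permissive (`*`);
  directories mixing multiple single-table exports of the same kind should
  be converted per subdirectory.
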