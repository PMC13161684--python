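import pyarrow as pa
import pytest
from hypothesis import HealthCheck, settings

from phenotable.fixtures import FixtureParams, generate_cellprofiler_fixture
from phenotable.model import ColumnSchema, TableChunk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_chunk(spec: dict, **kw) -> TableChunk:
    """Build a TableChunk from {name: (declared_type, values)}."""
    from phenotable.model import arrow_type

    cols, arrays = [], []
    for name, (dt, values) in spec.items():
        col = ColumnSchema(name, dt, nullable=any(v is None for v in values))
        cols.append(col)
        arrays.append(pa.array(values, type=arrow_type(col)))
    fields = [pa.field(c.name, a.type, nullable=True) for c, a in zip(cols, arrays)]
    table = pa.Table.from_arrays(arrays, schema=pa.schema(fields))
    return TableChunk(schema=cols, table=table, **kw)


@pytest.fixture
def chunk_factory():
    return make_chunk


@pytest.fixture
def cp_csv_fixture(tmp_path):
    """Small clean CellProfiler-style CSV export: 2 images x 3 cells."""
    params = FixtureParams(n_images=2, cells_per_image=3, seed=11)
    groups = generate_cellprofiler_fixture(params, "csv-dir", tmp_path / "src")
    return params, tmp_path / "src", groups
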