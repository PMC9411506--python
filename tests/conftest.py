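import pandas as pd
import pytest

from fertghg.efdirect import estimate_all, filter_synthetic_only
from fertghg.registry import ManufacturingEFTable, Registry, TransportEFTable
from fertghg.synthetic import (
    WorldSpec,
    gen_activity_table,
    gen_ef_tables,
    gen_sourcing_mix,
    gen_world_plots,
)


@pytest.fixture(scope="session")
def world_spec() -> WorldSpec:
    return WorldSpec(seed=7)


@pytest.fixture(scope="session")
def activity(world_spec) -> pd.DataFrame:
    return gen_activity_table(world_spec)


@pytest.fixture(scope="session")
def sourcing(world_spec) -> pd.DataFrame:
    return gen_sourcing_mix(world_spec)


@pytest.fixture(scope="session")
def ef_store(world_spec):
    records, _ = filter_synthetic_only(gen_world_plots(world_spec))
    return estimate_all(records)


@pytest.fixture(scope="session")
def registry(world_spec, ef_store) -> Registry:
    manuf, transport = gen_ef_tables(world_spec)
    return Registry(
        manufacturing=ManufacturingEFTable.from_frame(manuf),
        transport=TransportEFTable.from_frame(transport),
        empirical=ef_store,
    )
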