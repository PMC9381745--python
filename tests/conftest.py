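import pytest

from atpskit.datasets import (
    load_peg600_koh_partition,
    load_peg600_koh_tielines,
    peg600_koh_partition_table,
    peg600_koh_tieline_table,
)
from atpskit.partitioning import match_records_to_tielines
from atpskit.synthetic import GeneratorConfig


@pytest.fixture(scope="session")
def ref_tielines():
    """The five reference PEG600+KOH tie-lines."""
    return load_peg600_koh_tielines()


@pytest.fixture(scope="session")
def ref_tieline_table():
    return peg600_koh_tieline_table()


@pytest.fixture(scope="session")
def ref_partition(ref_tielines):
    """The ten reference partition records, matched to their tie-lines."""
    return match_records_to_tielines(load_peg600_koh_partition(), ref_tielines)


@pytest.fixture(scope="session")
def ref_partition_table():
    return peg600_koh_partition_table()


@pytest.fixture
def noiseless_config():
    """Generator config with every noise channel off: exact-model data."""
    return GeneratorConfig(
        seed=7,
        binodal_noise_sd=0.0,
        endpoint_noise_sd=0.0,
        partition_noise_sd=0.0,
        refractometry_noise_sd=0.0,
    )
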