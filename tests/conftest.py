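import pytest

from nbckit import (
    ExCovInstance,
    SSPInstance,
    build_excov_network,
    build_ssp_network,
)


@pytest.fixture(scope="session")
def fig1_net():
    """The worked SSP circuit for the set {2, 5, 9}."""
    return build_ssp_network(SSPInstance([2, 5, 9]))


@pytest.fixture(scope="session")
def cover_instance():
    """The worked ExCov instance: U = {1,2,3,4}, SS = {{2},{3},{1,4},{2,3}}."""
    return ExCovInstance([1, 2, 3, 4], [[2], [3], [1, 4], [2, 3]])


@pytest.fixture(scope="session")
def cover_net(cover_instance):
    return build_excov_network(cover_instance)
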