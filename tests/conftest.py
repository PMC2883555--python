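import pytest

from poreflux.channel import ChannelSpec, SpeciesSpec, make_uniform_species
from poreflux.io import make_fixture


@pytest.fixture
def one_site_n_only() -> ChannelSpec:
    """Single-site channel fed by one species with symmetric exits 0.5/0.5."""
    sp = SpeciesSpec(label="n", flux_J=0.01, hop_rate={}, exit_left=0.5, exit_right=0.5)
    return ChannelSpec(n_sites=1, capacity=1, entrance_site=1, species=(sp,))


@pytest.fixture
def one_site_mixture() -> ChannelSpec:
    return make_fixture("one_site")


@pytest.fixture
def two_site() -> ChannelSpec:
    return make_fixture("two_site")


@pytest.fixture
def dilute_uniform() -> ChannelSpec:
    return make_fixture("dilute_uniform")


@pytest.fixture
def uniform_4site() -> ChannelSpec:
    sp = make_uniform_species("u", 0.01, 1.0, 4)
    return ChannelSpec(n_sites=4, capacity=1, entrance_site=1, species=(sp,))
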