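import pytest

from nearmerge import design, fixtures, morph


@pytest.fixture(scope="session")
def endpoint_pair_i():
    return fixtures.make_endpoint_pair("i", seed=0)


@pytest.fixture(scope="session")
def endpoint_pair_a():
    return fixtures.make_endpoint_pair("a", seed=0)


@pytest.fixture(scope="session")
def continuum_i(endpoint_pair_i):
    nasal, lateral = endpoint_pair_i
    return morph.build_continuum(nasal, lateral)


@pytest.fixture(scope="session")
def continuum_a(endpoint_pair_a):
    nasal, lateral = endpoint_pair_a
    return morph.build_continuum(nasal, lateral)


@pytest.fixture(scope="session")
def ax_trials():
    return design.build_ax_blocks(seed=11)


@pytest.fixture(scope="session")
def id_trials():
    return design.build_id_blocks(seed=11)
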