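import pytest

from metaforge.fixtures import FixtureSpec, generate_consortium
from metaforge.ontology import OntologyBundle


@pytest.fixture(scope="session")
def clean_store():
    """Default synthetic consortium (finalized, zero findings). Read-only:
    tests that mutate must work on ``clean_store.copy()``."""
    store, truth = generate_consortium(FixtureSpec())
    assert len(truth) == 0
    return store


@pytest.fixture(scope="session")
def bundle():
    return OntologyBundle.builtin()
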