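import pytest

from chadolite import memory_store
from chadolite.fixtures import FixtureSpec, generate, load_fixture
from chadolite.vocab import bootstrap_inventory


@pytest.fixture(scope="session")
def fixture_tree(tmp_path_factory):
    """Default synthetic dataset: (directory, manifest)."""
    d = tmp_path_factory.mktemp("fixture")
    manifest = generate(FixtureSpec(seed=1), d)
    return d, manifest


@pytest.fixture(scope="session")
def session_store(fixture_tree):
    """One fully loaded store shared by read-only tests."""
    d, manifest = fixture_tree
    store = memory_store()
    load_fixture(store, d)
    return store, manifest


@pytest.fixture()
def loaded_store(fixture_tree):
    """A private fully loaded store for tests that mutate it."""
    d, _ = fixture_tree
    store = memory_store()
    load_fixture(store, d)
    return store


@pytest.fixture()
def bare_store():
    """Empty schema with the term inventory bootstrapped."""
    store = memory_store()
    bootstrap_inventory(store)
    return store
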