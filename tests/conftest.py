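import pytest

from omigraph import TripleStore
from omigraph.fixtures import integrate_fixture_dir, write_fixture_dir


@pytest.fixture(scope="session")
def fixture_study(tmp_path_factory):
    """One generated synthetic study: (directory, truth model)."""
    path = tmp_path_factory.mktemp("study")
    truth = write_fixture_dir(str(path), seed=7)
    return str(path), truth


@pytest.fixture(scope="session")
def fixture_store(fixture_study):
    """The synthetic study integrated into a store.  Session-scoped and
    read-only: tests that mutate the store must build their own."""
    path, _ = fixture_study
    store = TripleStore()
    integrate_fixture_dir(store, path)
    return store
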