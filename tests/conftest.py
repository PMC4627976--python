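import pytest

from statselect import ToyKbSpec, load_packaged_kb, make_toy_kb


@pytest.fixture(scope="session")
def kb():
    """The packaged unified decision tree (read-only across tests)."""
    return load_packaged_kb()


@pytest.fixture()
def toy_kb():
    """Minimal 1-question KB: root -> r001 (yes) / r002 (no)."""
    return make_toy_kb(ToyKbSpec(depth=1, complete=True, n_recommendations=2,
                                 seed=0))


@pytest.fixture()
def toy_kb3():
    """Complete 3-level binary toy tree: 7 nodes, 8 leaves."""
    return make_toy_kb(ToyKbSpec(depth=3, complete=True, n_recommendations=4,
                                 seed=0))
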