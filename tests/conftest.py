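import pytest

from pathoverlap.synthetic import (
    FixtureParams,
    generate_gap_pair,
    generate_toy_pair,
    write_degenerate_documents,
)


@pytest.fixture(scope="session")
def degenerate_docs(tmp_path_factory):
    """The edge-case SBML documents, written once per session."""
    return write_degenerate_documents(tmp_path_factory.mktemp("degenerate"))


@pytest.fixture(scope="session")
def identical_pair(tmp_path_factory):
    """Two structurally identical maps (planted fraction 1, linear)."""
    return generate_toy_pair(
        FixtureParams(n_species=5, n_reactions=4, planted_fraction=1.0, topology="linear", seed=7),
        tmp_path_factory.mktemp("identical"),
    )


@pytest.fixture(scope="session")
def subgraph_pair(tmp_path_factory):
    """doc1's reactions are all planted in doc2, which has 2 extra reactions."""
    return generate_toy_pair(
        FixtureParams(
            n_species=5,
            n_reactions=4,
            planted_fraction=1.0,
            topology="linear",
            seed=11,
            extra_reactions2=2,
        ),
        tmp_path_factory.mktemp("subgraph"),
    )


@pytest.fixture(scope="session")
def gap_pair(tmp_path_factory):
    return generate_gap_pair(tmp_path_factory.mktemp("gap"), n_reactions=4, seed=3)
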