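import pytest

from intronscape import RunConfig, analyze, make_parallel_gain_fixture
from intronscape.families import IleFamily


@pytest.fixture(scope="session")
def fixture_collection():
    """The bundled synthetic parallel-gain benchmark (seed 1)."""
    return make_parallel_gain_fixture(seed=1)


@pytest.fixture(scope="session")
def fixture_families(fixture_collection):
    return [
        IleFamily.from_consensus(name, seq)
        for name, seq in sorted(fixture_collection.family_seeds.items())
    ]


@pytest.fixture(scope="session")
def fixture_analysis(fixture_collection, fixture_families):
    fx = fixture_collection
    return analyze(
        fx.result.gene_models,
        fx.result.alignments,
        fx.result.tree,
        fixture_families,
        RunConfig(seed=1),
    )
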