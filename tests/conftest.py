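import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def species_tree():
    from cteninx.trees import SpeciesTree

    return SpeciesTree.default()


@pytest.fixture(scope="session")
def paper():
    """(gene tree, family map, species tree) for the published membership."""
    from cteninx.fixtures import paper_fixture

    return paper_fixture()
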