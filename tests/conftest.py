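import pytest
from hypothesis import HealthCheck, settings

from riversed.design import PlantedEffects, StudyDesign
from riversed.reactions import Reaction, ReactionSet
from riversed.simulate import generate_metadata

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_design():
    """Six sites, one season, one year, two replicates: 12 samples."""
    return StudyDesign(n_seasons=1, n_years=1, n_replicates=2, seed=7)


@pytest.fixture(scope="session")
def small_meta(small_design):
    return generate_metadata(small_design, PlantedEffects())


@pytest.fixture(scope="session")
def toy_reactions():
    """Three enzymes over four metabolites, including one two-reaction enzyme."""
    return ReactionSet(
        (
            Reaction("R1", "1.1.1.1", (("A", 1.0),), (("B", 1.0),)),
            Reaction("R2", "2.2.2.2", (("A", 1.0),), (("C", 1.0),)),
            Reaction("R3", "2.2.2.2", (("B", 2.0),), (("D", 1.0),)),
        )
    )
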