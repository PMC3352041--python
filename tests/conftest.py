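import pytest
from hypothesis import HealthCheck, settings

from mirlink.io_formats import GENE, MIRNA, DeregulationSet, InteractionTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def mir_dereg() -> DeregulationSet:
    return DeregulationSet(
        entity_class=MIRNA,
        entries={"hsa-miR-1": +1, "hsa-miR-2": +1, "hsa-miR-3": -1},
    )


@pytest.fixture
def gene_dereg() -> DeregulationSet:
    return DeregulationSet(
        entity_class=GENE,
        entries={"G1": +1, "G2": -1, "G3": -1, "G4": +1},
    )


@pytest.fixture
def interactions() -> InteractionTable:
    pairs = (
        ("hsa-miR-1", "G1", 0.001),
        ("hsa-miR-1", "G2", 0.002),
        ("hsa-miR-1", "G9", 0.003),
        ("hsa-miR-2", "G1", 0.004),
        ("hsa-miR-3", "G3", 0.005),
        ("hsa-miR-4", "G4", 0.006),
        ("hsa-miR-4", "G9", 0.007),
    )
    return InteractionTable(pairs=pairs, organism_prefix="hsa")
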