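import numpy as np
import pytest

from redlistrf import AttributeSpec, SpeciesTable, SyntheticConfig, generate


@pytest.fixture
def toy_specs():
    return [
        AttributeSpec(name="wings", kind="binary", n_categories=2, tier="poorly_known"),
        AttributeSpec(name="size", kind="ordinal", n_categories=5, tier="well_known"),
        AttributeSpec(
            name="commonness_1950_1990", kind="ordinal", n_categories=5,
            tier="evaluated", derivation="commonness",
        ),
    ]


@pytest.fixture
def toy_table(toy_specs):
    return SpeciesTable(
        species_ids=["sp1", "sp2", "sp3", "sp4"],
        kingdom=np.array(["animalia"] * 4, dtype=object),
        group=np.array(["aves", "aves", "lepidoptera", "lepidoptera"], dtype=object),
        values=np.array(
            [[1, 0, 4], [0, -1, 3], [1, 2, 0], [0, 4, 1]], dtype=np.int16
        ),
        specs=toy_specs,
        rarity=np.array([1, 0, 1, 0]),
        decline=np.array([0, 1, 1, 0]),
        group_parents={"aves": "vertebrata", "lepidoptera": "insecta",
                       "vertebrata": "animalia", "insecta": "animalia"},
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across read-only tests."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def complete_dataset():
    """Default-shape dataset without missingness (forest tests)."""
    return generate(SyntheticConfig(seed=1, missing_rate=0.0))
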