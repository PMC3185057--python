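import pytest
from hypothesis import settings

from dietbarcode.simulate import Degradation, SimulationConfig, generate_reference

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_families=2, genera_per_family=2, species_per_genus=2,
        species_band=0.002, genus_band=0.015, family_band=0.035, seed=7,
    )


@pytest.fixture(scope="session")
def small_db(small_config):
    """8-species reference with band-calibrated divergences."""
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def db20_config():
    """20-species study system: 5 families x 2 genera x 2 species."""
    return SimulationConfig(
        n_families=5, genera_per_family=2, species_per_genus=2,
        seed=11,
        degradation=Degradation(
            substitution_rate=0.0003, indel_rate=0.0, truncation_range=(420, 500)
        ),
    )


@pytest.fixture(scope="session")
def db20(db20_config):
    return generate_reference(db20_config)
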