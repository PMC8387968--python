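import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import florastat as fs

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Classified 60-species synthetic dataset shared by read-only tests."""
    cfg = fs.SimulationConfig(n_species=60, n_families=8, seed=42)
    obs, species, truth = fs.simulate_dataset(cfg)
    return obs, species, truth


@pytest.fixture()
def toy_taxonomy():
    species = pd.DataFrame({
        "accepted_name": ["Trifolium pratense", "Trifolium repens",
                          "Vicia cracca", "Poa annua",
                          "Dactylorhiza majalis"],
        "genus": ["Trifolium", "Trifolium", "Vicia", "Poa", "Dactylorhiza"],
        "family": ["Fabaceae", "Fabaceae", "Fabaceae", "Poaceae",
                   "Orchidaceae"],
        "growth_form": ["herb"] * 5,
        "life_form": ["hemicryptophyte"] * 5,
        "habitat": ["grassland"] * 5,
        "frequency": [500, 480, 300, 520, 40],
        "n_training_images": [900, 800, 400, 700, 120],
    })
    taxonomy = fs.TaxonomyMap.from_species_table(
        species, synonyms={"Dactylorhiza baltica": "Dactylorhiza majalis"})
    return species, taxonomy
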