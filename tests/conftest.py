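import numpy as np
import pandas as pd
import pytest

from dielkit import events, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20210320)


@pytest.fixture(scope="session")
def small_config():
    """A downscaled survey: 3 tropical sites, 15 cameras, 14 species."""
    return synthetic.SyntheticConfig(
        n_sites=3, n_cameras_per_site=15, n_species=14, deployment_days=30, seed=42
    )


@pytest.fixture(scope="session")
def small_community(small_config):
    return synthetic.generate_community(small_config)


@pytest.fixture(scope="session")
def small_detections(small_config, small_community):
    traits, truth = small_community
    return synthetic.simulate_detections(traits, truth, small_config)


@pytest.fixture(scope="session")
def small_events(small_detections, small_community):
    traits, _ = small_community
    det, _ = small_detections
    traits_cls = events.add_species_classes(traits)
    filtered = events.filter_species(det, traits_cls)
    return events.independent_events(filtered), traits_cls


def make_traits_row(**kw):
    base = {
        "species": "sp",
        "body_mass_g": 1000.0,
        "diet_vertebrate": 0.0,
        "diet_plant": 0.0,
        "diet_invertebrate": 0.0,
        "diet_other": 0.0,
        "stratum": "ground",
    }
    base.update(kw)
    return pd.Series(base)
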