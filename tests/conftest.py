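import numpy as np
import pandas as pd
import pytest

from avistability.datamodel import DIET_NAMES, MORPHOMETRIC_NAMES
from avistability.synthetic import SynthConfig, generate_dataset, generate_species_pool


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(
        n_species_pool=120, n_landscapes=2, blocks_per_landscape=2, rng_seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(pool, surveys, truth) at a scale small enough for per-test reuse."""
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def species_pool():
    return generate_species_pool(SynthConfig(n_species_pool=500, rng_seed=11))


@pytest.fixture(scope="session")
def pool_tables(species_pool):
    traits = species_pool[list(MORPHOMETRIC_NAMES) + ["hwi"]]
    diets = species_pool[list(DIET_NAMES)]
    return traits, diets


@pytest.fixture
def toy_profiles():
    """Hand-built species profiles with controlled diets and attributes."""
    from avistability.datamodel import SpeciesProfile

    def mk(sid, diet, hwi=20.0, wing=70.0, **kw):
        morph = (15.0, 11.0, 6.0, 6.5, 60.0, 25.0, wing)
        d = np.zeros(9)
        for k, v in diet.items():
            d[DIET_NAMES.index(k)] = v
        rest = 1.0 - d.sum()
        if rest > 1e-12:
            d[d == 0] += rest / (d == 0).sum()
        return SpeciesProfile(sid, morph, hwi, tuple(d), **kw)

    return mk
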