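import numpy as np
import pytest

from topomap.genome import GenomeSpec
from topomap.synthetic import PlantedSite, ShapeParams, plant_norflip_experiment


@pytest.fixture(scope="session")
def small_genome() -> GenomeSpec:
    return GenomeSpec(length=100_000, oriC=0, dif=50_000)


@pytest.fixture(scope="session")
def canonical_exp(small_genome):
    """One noise-free canonical cleavage site at 50 kb."""
    return plant_norflip_experiment(
        small_genome,
        [PlantedSite(50_000, fold=30.0)],
        shape=ShapeParams(),
        depth=5.0,
        bg_rate=5.0,
        noise=False,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
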