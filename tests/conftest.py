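import numpy as np
import pytest

from lonebrain.atlas import Atlas, RegionRecord, load_atlas, load_tract_catalog
from lonebrain.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture(scope="session")
def catalog():
    return load_tract_catalog()


@pytest.fixture(scope="session")
def small_atlas():
    """Reduced 10-region / 2-network atlas for fast model tests."""
    regions = []
    for r in range(10):
        net = "Default" if r < 6 else "Visual"
        hemi = "left" if r % 2 == 0 else "right"
        regions.append(RegionRecord(r, f"toy_{net}_{r}", hemi, net))
    return Atlas(regions=tuple(regions), networks=("Visual", "Default"))


@pytest.fixture(scope="session")
def small_cohort():
    """Shared default-config cohort at modest n for cross-module tests."""
    return generate_cohort(GeneratorConfig(n=600, seed=20))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
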