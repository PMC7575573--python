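import warnings

import numpy as np
import pytest
from hypothesis import settings

import rimradiomics as rr

settings.register_profile("ci", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def effect_cohort():
    """Small phantom cohort with the default planted rim effect."""
    return rr.generate_cohort(rr.SimulationConfig(n_patients=60, seed=202))


@pytest.fixture(scope="session")
def effect_table(effect_cohort):
    """Extracted 200-feature table for the small planted-effect cohort."""
    return rr.extract_cohort_features(effect_cohort)


@pytest.fixture(scope="session")
def planted_phantom():
    spec = rr.LesionSpec(radii_mm=(8.0, 8.0, 8.0), rim_heterogeneity_effect=3.0)
    vol, mask = rr.generate_phantom(spec, seed=7)
    return vol, mask


def random_blob_mask(rng, shape=(24, 24, 24), n_seeds=3, r=4.0):
    """An irregular but connected test VOI: union of a few lattice balls."""
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"))
    mask = np.zeros(shape, dtype=np.uint8)
    center = np.asarray(shape) / 2
    pts = [center]
    for _ in range(n_seeds - 1):
        pts.append(center + rng.uniform(-3, 3, size=3))
    for p in pts:
        d2 = sum((grid[i] - p[i]) ** 2 for i in range(3))
        mask[d2 <= r ** 2] = 1
    return mask
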