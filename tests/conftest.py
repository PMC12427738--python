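import numpy as np
import pytest

from tissuedetect.detectors import DoublePassConfig
from tissuedetect.synthetic import generate_scenes

# Suite seeds are fixed so every test sees the same fixtures.
EASY_SEED = 11
FAINT_SEED = 13
ARTIFACT_SEED = 7


@pytest.fixture(scope="session")
def easy_suite():
    """20 easy fixtures: saturated tissue only, no artifacts or debris."""
    return list(generate_scenes(20, "easy", seed=EASY_SEED))


@pytest.fixture(scope="session")
def faint_suite():
    """20 faint fixtures: mostly pale, low-spread tissue."""
    return list(generate_scenes(20, "faint", seed=FAINT_SEED))


@pytest.fixture(scope="session")
def artifact_suite():
    """20 artifact fixtures: achromatic gray rectangles and chromatic debris."""
    return list(generate_scenes(20, "artifact", seed=ARTIFACT_SEED))


@pytest.fixture
def dp_config():
    return DoublePassConfig(random_seed=EASY_SEED)


def random_binary_mask(rng: np.random.Generator, shape=(64, 64), density=None) -> np.ndarray:
    density = rng.uniform(0.05, 0.6) if density is None else density
    return np.where(rng.random(shape) < density, 255, 0).astype(np.uint8)
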