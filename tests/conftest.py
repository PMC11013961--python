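import numpy as np
import pytest

from tasselcount.core_io import RgbImage
from tasselcount.synthetic import SceneConfig, generate_scene, generate_scenes


@pytest.fixture(scope="session")
def small_scene():
    """One default 128×256 scene with 12 tassels."""
    return generate_scene(SceneConfig(seed=11, n_tassels=12))


@pytest.fixture(scope="session")
def scene_set():
    """A dozen default scenes with varying tassel counts."""
    return generate_scenes(12, seed=101)


@pytest.fixture(scope="session")
def tiny_scenes():
    """Small 64×96 scenes for fast training tests."""
    cfg = SceneConfig(height=64, width=96, min_separation=14)
    return generate_scenes(10, seed=202, template=cfg, tassel_range=(2, 8))


@pytest.fixture()
def random_image():
    rng = np.random.default_rng(5)
    return RgbImage(rng.integers(0, 256, size=(40, 56, 3), dtype=np.uint8), "rand")
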