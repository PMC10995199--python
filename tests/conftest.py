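import numpy as np
import pytest

from filaquant.morphometry import MorphometryConfig
from filaquant.segmentation import SegmentationConfig
from filaquant.simulate import ImageSimConfig, generate_cell_image, make_toy_protomer


@pytest.fixture(scope="session")
def seg_config():
    return SegmentationConfig()


@pytest.fixture(scope="session")
def morph_config():
    return MorphometryConfig()


@pytest.fixture(scope="session")
def small_field():
    """One 10-cell field at a 50/50 filamented fraction, with ground truth."""
    cfg = ImageSimConfig(n_cells=10, frac_filamented=0.5, seed=42)
    return cfg, generate_cell_image(cfg)


@pytest.fixture(scope="session")
def protomer():
    return make_toy_protomer(30, 12.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
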