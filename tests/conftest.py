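import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from nucseg.segmentation import classical_predictor
from nucseg.synthetic import PRESETS, easy_preset, generate_scene


@pytest.fixture(scope="session")
def classical_pair():
    return classical_predictor("foreground"), classical_predictor("distance")


@pytest.fixture(scope="session")
def easy_scene():
    """One high-contrast, well-separated 63x-like scene."""
    return generate_scene(easy_preset(PRESETS["63x_oil"]), (256, 256), seed=202)


@pytest.fixture(scope="session")
def touching_scene():
    """Default 63x scene including touching nuclei and hot-spots."""
    return generate_scene(PRESETS["63x_oil"], (256, 256), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
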