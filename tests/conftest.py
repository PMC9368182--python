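import dataclasses

import numpy as np
import pytest

from qpigan.optics import OBJECTIVE_PRESETS, OpticalConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def cfg_40x() -> OpticalConfig:
    return OBJECTIVE_PRESETS["40x"]


@pytest.fixture
def cfg_40x_coherent(cfg_40x) -> OpticalConfig:
    return dataclasses.replace(cfg_40x, coherence_s=0.0)
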