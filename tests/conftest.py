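import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from hvospipe.simulate import SceneConfig, SynthCell, render_trial_stack


@pytest.fixture(scope="session")
def small_config():
    """A compact scene: 40x40 grid, 100 ms record, stimulus at 20 ms."""
    return SceneConfig(shape=(40, 40), n_frames=200, stim_time=20.0, electrode_um=(120.0, 10.0), seed=0)


@pytest.fixture(scope="session")
def noiseless_single_cell(small_config):
    """One cell at a pixel-centered location, rendered without noise."""
    cell = SynthCell(center=(20.0, 25.0), amplitude_true=0.005)
    stack, truth = render_trial_stack(small_config, [cell])
    return stack, truth, small_config


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
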