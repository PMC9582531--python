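import numpy as np
import pytest

from gaitgpm import synthetic
from gaitgpm.montage import STANDARD_16, make_layout  # noqa: F401

SMALL_MONTAGE = ["Fp1", "Fp2", "Fz", "T7", "C3", "Cz", "C4", "T8", "TP9", "TP10",
                 "Pz", "Oz"]


@pytest.fixture(scope="session")
def layout16():
    return make_layout(STANDARD_16)


@pytest.fixture(scope="session")
def clean_walk():
    """Noise-free 60-stride walk at 250 Hz with ground truth."""
    tl = synthetic.generate_timeline(1.0, 0.0, [(1.0, 61.0)], seed=0)
    left, right, truth = synthetic.generate_accel(tl, 250.0, 0.0, seed=0)
    return tl, left, right, truth


@pytest.fixture(scope="session")
def smooth_noise16(layout16):
    """Spatially correlated multichannel noise (session-cached)."""
    rng = np.random.default_rng(7)
    return synthetic._background(rng, layout16.positions, 250 * 60, 250.0,
                                 scale=10.0, sensor_noise=1.0)
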