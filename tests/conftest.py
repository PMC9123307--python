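import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from synaptoquant import synthetic_data as sd  # noqa: E402


@pytest.fixture(scope="session")
def small_puncta_spec():
    """64x64 field small enough for the brute-force oracle."""
    return sd.PunctaFieldSpec(
        image_size=(64, 64), n_puncta_a=2, n_puncta_b=2,
        coloc_fraction=0.0, punctum_radius_px=4.5,
        peak_intensity=200.0, background_sd=4.0)


@pytest.fixture(scope="session")
def default_train_spec():
    return sd.TrainSimSpec(n0=1000.0, p_release=0.3, r_replenish=300.0,
                           q_amp=4.0, noise_sd=0.0, n_sweeps=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
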