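import logging

import numpy as np
import pytest

from lungaerate.imaging import Mask, Volume
from lungaerate.synthetic import ExvivoConfig

logging.getLogger("lungaerate").setLevel(logging.ERROR)


@pytest.fixture
def unit_volume():
    """A 40 mm cube grid at 1 mm isotropic spacing, constant intensity 7."""
    return Volume(data=np.full((40, 40, 40), 7.0), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def full_mask(unit_volume):
    return Mask.from_volume(unit_volume, np.ones(unit_volume.shape, dtype=bool))


@pytest.fixture
def noiseless_exvivo_config():
    """Measurement-noise-free bench configuration (exact closed loop)."""
    return ExvivoConfig(signal_noise_frac=0.0, volume_noise_frac=0.0,
                        sample_gain_sd=0.0, inflation_jitter_sd=0.0,
                        noise_sigma_gu=0.0)
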