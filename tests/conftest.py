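import matplotlib
matplotlib.use("Agg")

import numpy as np
import pytest

from myoelast import AcquisitionConfig, FitConfig


@pytest.fixture
def noiseless_config():
    return AcquisitionConfig(noise_sd_nm=0.0)


@pytest.fixture
def noisy_config():
    return AcquisitionConfig(noise_sd_nm=0.3)


@pytest.fixture
def small_config():
    """A small, fast acquisition grid for map-level tests."""
    return AcquisitionConfig(grid_rows=8, grid_cols=10, scan_width_um=8.0,
                             scan_height_um=8.0, samples_per_curve=512,
                             noise_sd_nm=0.0, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
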