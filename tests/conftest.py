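import numpy as np
import pytest

from clcphasor import CellModel, FlimSimParams, VoltageProtocol
from clcphasor.synthgen import expected_decay
from clcphasor.flim_phasor import FlimStack


@pytest.fixture
def small_flim_params():
    """A quick-to-simulate FLIM acquisition (32x32, mono-exponential)."""
    return FlimSimParams(width=32, height=32, n_bins=256, laser_freq=80.0,
                         lifetimes=(2.5,), fractions=(1.0,),
                         photons_per_pixel=1e4, seed=7)


@pytest.fixture
def patch_protocol():
    return VoltageProtocol.clc_patch_iv()


@pytest.fixture
def passive_cell():
    return CellModel(transporter_gmax=0.0, noise_sd=5.0, seed=11)


def noiseless_stack(params: FlimSimParams) -> FlimStack:
    """Single-pixel stack holding the expected (Poisson-mean) histogram.

    Scales the expected decay so rounding to integer counts is negligible;
    used as the infinite-photon limit in phasor oracles.
    """
    lam = expected_decay(params) * 1e6 / params.photons_per_pixel
    counts = np.round(lam * 1e3).astype(np.int64)[None, None, :]
    return FlimStack(counts=counts, laser_freq=params.laser_freq,
                     bin_width=params.bin_width)
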