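import numpy as np
import pytest

from dmoct import BandSpec, BScanSeries, StackHeader
from dmoct.phantom import LayerSpec, PhantomConfig, ToxicityCourse


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_series(data, frame_rate_hz=111.0, axial_um_per_px=1.0):
    data = np.asarray(data, dtype=float)
    header = StackHeader(
        n_frames=data.shape[0], n_depth=data.shape[1], n_ascans=data.shape[2],
        frame_rate_hz=frame_rate_hz, axial_um_per_px=axial_um_per_px,
    )
    return BScanSeries(data=data, header=header)


@pytest.fixture
def small_config():
    """A tiny two-layer phantom for fast tests."""
    layers = (
        LayerSpec(name="superficial", z_range=(4, 14), mean_amplitude=1.0,
                  band_power_fractions=(0.8, 0.05, 0.05), fluctuation_strength=0.15),
        LayerSpec(name="basal", z_range=(14, 24), mean_amplitude=0.4,
                  band_power_fractions=(0.04, 0.45, 0.45), fluctuation_strength=0.38),
    )
    return PhantomConfig(layers=layers, n_frames=60, n_ascans=32, n_depth=32,
                         frame_rate_hz=111.0, noise_sigma=0.01, n_repeats=3, seed=7)


@pytest.fixture
def default_bands():
    return BandSpec()


@pytest.fixture
def course():
    return ToxicityCourse()
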