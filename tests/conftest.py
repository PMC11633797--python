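import numpy as np
import pytest

from cbctpost import GaugeSpec, PhantomSpec, Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Desk-speed phantom: same 205 mm field of view as the default on a
    coarser 128x128 / 1.6 mm grid, one-or-few slices per module."""
    return PhantomSpec(
        nx=128,
        ny=128,
        pixel_mm=1.6,
        gauges=(GaugeSpec(1.0), GaugeSpec(2.0), GaugeSpec(3.0)),
        n_sens=1,
        n_unif=2,
        n_lp=1,
        n_ramp=4,
    )


@pytest.fixture
def flat_noisy_volume(rng):
    """Flat 100 HU slice plus sigma-30 Gaussian noise."""
    return Volume3D(100.0 + rng.normal(0, 30.0, (1, 128, 128)), (2.0, 1.0, 1.0)), 30.0


def make_volume(array, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return Volume3D(np.asarray(array, dtype=float), spacing, origin)
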