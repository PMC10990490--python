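import numpy as np
import pytest

from neuritemito.imaging_io import ImageStack, StimulationProtocol
from neuritemito.synthetic_data import OpticsModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def optics():
    return OpticsModel()


@pytest.fixture
def quiet_optics():
    """Very low-noise optics for near-deterministic renders."""
    return OpticsModel(photons_per_unit=50.0, read_noise_e=0.5)


@pytest.fixture
def protocol_30s():
    """The study's stimulation timing: 1-s pulse every 30 s over 2.5 min."""
    return StimulationProtocol(pulse_duration_s=1.0, period_s=30.0,
                               total_duration_s=150.0)


@pytest.fixture
def small_stack(rng):
    pages = rng.integers(0, 1000, size=(5, 32, 40)).astype(np.uint16)
    return ImageStack(pages=pages, axis_kind="time", px_um=0.1, dt_s=0.1)
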