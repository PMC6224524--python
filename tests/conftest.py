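import numpy as np
import pytest

from placenta_vasomech import fung, synthetic, windkessel


@pytest.fixture(scope="session")
def normal_geometry() -> fung.StressFreeGeometry:
    """Stress-free sector from the normal-group ring measurements."""
    return fung.StressFreeGeometry.from_ring(2.0, 0.586, 91.48)


@pytest.fixture(scope="session")
def normal_params() -> fung.FungParameters:
    return fung.FungParameters(c=125.82, b1=20.63)


@pytest.fixture(scope="session")
def normal_curve(normal_geometry, normal_params):
    """Noiseless model-generated pressure-stretch curve (0-40 mmHg)."""
    return fung.forward_curve(normal_geometry, normal_params, 1.1)


@pytest.fixture(scope="session")
def default_network() -> windkessel.WindkesselNetwork:
    return windkessel.build_default_network()


@pytest.fixture(scope="session")
def normal_inlet() -> windkessel.PressureWaveform:
    shape = synthetic.gen_doppler_waveform(
        synthetic.WaveformConfig(target_RI=0.6))
    return windkessel.scale_pressure_waveform(shape, 50.0, 25.0)


@pytest.fixture(scope="session")
def iugr_inlet() -> windkessel.PressureWaveform:
    shape = synthetic.gen_doppler_waveform(
        synthetic.WaveformConfig(target_RI=0.6))
    return windkessel.scale_pressure_waveform(shape, 80.0, 25.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
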