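import numpy as np
import pytest

from geciquant import AnalysisConfig, DffTrace, IndicatorModel, SimulationConfig


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def model():
    """Transgenic-expression indicator parameters, noiseless."""
    return IndicatorModel(noise_sd=0.0)


@pytest.fixture
def noisy_model():
    return IndicatorModel()


def make_dff(values, frame_rate=12.0, f0=1.0, roi_id=0):
    return DffTrace(values=np.asarray(values, dtype=float), f0=f0,
                    frame_rate=frame_rate, roi_id=roi_id)


@pytest.fixture
def dff_factory():
    return make_dff
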