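import numpy as np
import pytest

from gvstim import EhcsModel, StimulusSpec, generate_waveform
from gvstim.interfaces import synth_recording


@pytest.fixture
def model():
    return EhcsModel()


@pytest.fixture
def hold_recording():
    """Synthetic 1 mA ramp-hold-ramp recording into 1481 Ohm at 50 kS/s."""
    spec = StimulusSpec(amplitude_mA=1.0, slope_ms=500, duration_ms=1000)
    profile = generate_waveform(spec, 50_000)
    return synth_recording(profile, load_ohm=1481, noise_sd_V=0.03, seed=42)


@pytest.fixture
def quiet_recording():
    """Same profile, noiseless: exact values for closed-form checks."""
    spec = StimulusSpec(amplitude_mA=1.0, slope_ms=500, duration_ms=1000)
    profile = generate_waveform(spec, 50_000)
    return synth_recording(profile, load_ohm=1481, noise_sd_V=0.0, seed=0)
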