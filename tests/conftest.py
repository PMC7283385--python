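import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from echobc import CaseMode, Site, VelocityWaveform, WaveformParams, gen_patient, gen_waveform


@pytest.fixture
def clean_pulse() -> VelocityWaveform:
    """Noise-free synthetic systolic pulse, peak 1.3 m/s at 120 BPM."""
    return gen_waveform(WaveformParams(peak_velocity=1.3, n_samples=100))


@pytest.fixture
def noisy_pulse_pair():
    """(clean, noisy) versions of the same pulse; noise sd 0.05 m/s, seed 1."""
    clean = gen_waveform(WaveformParams(peak_velocity=1.3, n_samples=100))
    noisy = gen_waveform(
        WaveformParams(peak_velocity=1.3, n_samples=100, noise_sd=0.05, seed=1)
    )
    return clean, noisy


@pytest.fixture
def full_patient():
    """Noise-free full-data synthetic patient (all six sites)."""
    return gen_patient(CaseMode.FULL_DATA, seed=7)


def ramp_waveform(site=Site.ASCENDING_AORTA, n=11, v0=0.0, v1=2.0, period=0.5):
    t = np.linspace(0.0, period, n)
    v = np.linspace(v0, v1, n)
    return VelocityWaveform(site=site, t=t, v=v)
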