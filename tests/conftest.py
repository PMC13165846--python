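import numpy as np
import pytest

from imugait import synthetic as syn
from imugait.io import TrialRecording
from imugait.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_truth():
    """The default 14-cycle synthetic walk (the study-condition fixture)."""
    return syn.generate_gait_truth()


@pytest.fixture(scope="session")
def clean_recording(default_truth):
    """Noise-free seven-node recording of the default walk."""
    streams = syn.synthesize_imu(default_truth, syn.NoiseModel.zero(seed=1))
    return TrialRecording(
        streams, fs=default_truth.fs, static_end_s=default_truth.profile.lead_in_s
    )


@pytest.fixture(scope="session")
def clean_report(clean_recording):
    """Full pipeline output on the noise-free default walk."""
    return run_pipeline(clean_recording)


@pytest.fixture(scope="session")
def small_truth():
    """A short high-rate walk for derivative-consistency checks."""
    return syn.generate_gait_truth(
        syn.GaitProfile(fs=1000.0, n_cycles=2, lead_in_s=1.0, tail_s=0.5)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
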