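import numpy as np
import pytest

from boutonpipe.behavior import LeverSession
from boutonpipe.synthetic import BehaviorSpec, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A few boutons, short segment: fast end-to-end material."""
    return SimConfig(
        n_axons=3,
        boutons_per_axon=3,
        n_frames=2000,
        noise_sd=0.03,
        seed=0,
    )


@pytest.fixture
def balanced_config():
    """Conditions with enough clean RM and UM trials to classify."""
    return SimConfig(
        n_axons=6,
        boutons_per_axon=4,
        n_frames=6000,
        noise_sd=0.05,
        response_gain=2.0,
        behavior=BehaviorSpec(p_success=0.55, p_fail_push=1.0,
                              p_iti_push=0.3),
    )


@pytest.fixture
def square_pulse_session():
    """Hand-built lever trace: pulses at known times for bout detection."""

    def make(pulse_times, pulse_width=0.5, amp=2.0, fs=100.0, duration=30.0,
             cues=(1.0,)):
        n = int(duration * fs)
        pos = np.zeros(n)
        for t in pulse_times:
            i0 = int(t * fs)
            pos[i0 : i0 + int(pulse_width * fs)] = amp
        return LeverSession(
            positions=pos,
            sample_rate=fs,
            cue_onsets=np.asarray(cues),
            task_period=10.0,
            push_threshold=1.5,
        )

    return make
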