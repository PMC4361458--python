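"""Shared fixtures: simulated sessions are expensive, so the canonical ones
are built once per test run and reused wherever possible."""

import numpy as np
import pytest
from hypothesis import settings

import prcclamp as pc

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cos_session():
    """Full-length closed-loop session on the cosine-PRC phase neuron at 50 Hz.

    The repository's core oracle configuration: z_true = 1 - cos(2 pi phi)
    (1/pC), CV 7%, 1400 pulses of 0.05 pC, PID frequency clamp at 50 Hz.
    """
    neuron = pc.PhaseNeuron(pc.PhaseNeuronConfig(z_true=pc.z_cos_peaked(1.0), seed=1))
    train, pulses, log = pc.run_closed_loop_session(
        neuron, pc.PIDConfig(f_target=50.0), n_pulses=1400,
        pulse_amplitude=100.0, pulse_duration=0.5e-3, seed=1,
    )
    return train, pulses, log


@pytest.fixture(scope="session")
def cos_fit(cos_session):
    train, pulses, _ = cos_session
    return pc.DirectPRC(train, pulses, t_start=5.0).fit(seed=1, n_boot=300)


@pytest.fixture(scope="session")
def short_session():
    """Small session for structural checks (fast)."""
    neuron = pc.PhaseNeuron(pc.PhaseNeuronConfig(seed=5))
    return pc.run_closed_loop_session(
        neuron, pc.PIDConfig(f_target=50.0), n_pulses=120, seed=5)


@pytest.fixture
def regular_train():
    """Jitter-free 100 Hz spike train, 3 s."""
    return pc.SpikeTrain(np.arange(0.0, 3.0, 0.01))
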