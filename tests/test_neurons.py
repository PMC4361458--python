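"""Synthetic neurons: phase oscillator, conductance surrogate, channel noise,
and the state-save replay protocol."""

import numpy as np
import pytest

import prcclamp as pc
from prcclamp.neurons import (ConductanceNeuron, PhaseNeuron, PhaseNeuronConfig,
                              diffusion_coefficients, exact_markov_simulation,
                              potassium_chain_scheme, replay_prc,
                              two_state_scheme)


class TestPhaseNeuron:
    def test_deterministic_isis_exact(self):
        n = PhaseNeuron(PhaseNeuronConfig(jitter_sd=0.0, seed=0))
        spikes = n.advance(1.0, i_dc=200.0)  # f = 50 Hz
        isis = np.diff(spikes)
        np.testing.assert_allclose(isis, 0.020, atol=1e-4)  # dt quantization

    def test_single_pulse_advances_next_spike(self):
        """First-order effect: a pulse of charge Q at phase phi0 shortens the
        current ISI by z(phi0) * Q cycles."""
        z0 = 1.0
        cfg = PhaseNeuronConfig(z_true=pc.z_cos_peaked(z0), jitter_sd=0.0, seed=0)
        n = PhaseNeuron(cfg)
        dt = cfg.dt
        steps = int(1.0 / dt)
        amp, dur = 50.0, 2e-4  # Q = 0.01 pC, brief
        phi0 = 0.4
        i = np.zeros(steps)
        # free run reaches phi0 at t = phi0/50 within each 20 ms cycle
        k0 = int(round((10 * 0.020 + phi0 * 0.020) / dt))
        i[k0:k0 + int(dur / dt)] = amp
        spikes = n.advance(1.0, i_dc=200.0, i_fluct=i)
        isis = np.diff(spikes)
        expected_shortening = z0 * (1 - np.cos(2 * np.pi * phi0)) * amp * dur * 0.020
        assert isis[9] == pytest.approx(0.020 - expected_shortening, abs=1e-4)
        np.testing.assert_allclose(np.delete(isis, 9), 0.020, atol=1e-4)

    def test_cv_matches_jitter_parameter(self):
        n = PhaseNeuron(PhaseNeuronConfig(jitter_sd=0.05, seed=2))
        isis = np.diff(n.advance(100.0, i_dc=200.0))
        assert isis.std() / isis.mean() == pytest.approx(0.05, abs=0.004)

    def test_silent_neuron_is_an_error(self):
        n = PhaseNeuron(PhaseNeuronConfig(seed=0))
        with pytest.raises(ValueError):
            n.advance(1.0, i_dc=-2000.0)

    def test_state_restore_replays_bitwise(self):
        n = PhaseNeuron(PhaseNeuronConfig(seed=3))
        n.advance(1.0, i_dc=200.0)
        state = n.get_state()
        a = n.advance(2.0, i_dc=200.0)
        n.set_state(state)
        b = n.advance(2.0, i_dc=200.0)
        np.testing.assert_array_equal(a, b)


class TestConductanceNeuron:
    def test_deterministic_firing_is_periodic(self):
        n = ConductanceNeuron(seed=0)
        spikes = n.advance(3.0)
        isis = np.diff(spikes[spikes > 1.0])
        assert isis.std() / isis.mean() < 1e-3

    def test_rate_increases_with_current(self):
        rates = []
        for i_ext in (-100.0, 0.0, 200.0, 500.0):
            n = ConductanceNeuron(seed=0)
            sp = n.advance(2.0, i_ext)
            sp = sp[sp > 0.5]
            rates.append((sp.size - 1) / (sp[-1] - sp[0]))
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_noisy_current_raises_cv(self):
        n = ConductanceNeuron(noise_current_sd=2.0, seed=1)
        sp = n.advance(20.0)
        isis = np.diff(sp[sp > 1.0])
        assert 0.02 < isis.std() / isis.mean() < 0.25

    def test_channel_noise_raises_cv_and_shrinks_with_channel_count(self):
        from prcclamp.neurons import potassium_chain_at_voltage

        scheme = potassium_chain_at_voltage(-50.0)
        cvs = []
        for nch in (1000, 20000):
            n = ConductanceNeuron(channel_noise=(scheme, nch), seed=1)
            sp = n.advance(10.0)
            isis = np.diff(sp[sp > 1.0])
            cvs.append(isis.std() / isis.mean())
        assert cvs[0] > 0.05          # few channels: strong fluctuations
        assert cvs[1] < cvs[0] / 2.0  # 20x channels: much more regular

    def test_state_restore_replays_bitwise(self):
        n = ConductanceNeuron(noise_current_sd=10.0, seed=4)
        n.advance(0.5)
        st = n.get_state()
        a = n.advance(0.5)
        n.set_state(st)
        b = n.advance(0.5)
        np.testing.assert_array_equal(a, b)


class TestDiffusionCoefficients:
    def test_two_state_closed_form(self):
        """alpha=beta two-state channel: single OU with tau = 1/(alpha+beta)
        and variance p(1-p)/n."""
        spec = diffusion_coefficients(two_state_scheme(100.0, 100.0), 1000)
        assert spec.taus.size == 1
        assert spec.taus[0] == pytest.approx(1.0 / 200.0, rel=1e-9)
        assert spec.sigmas[0] ** 2 == pytest.approx(0.25 / 1000, rel=1e-9)

    def test_asymmetric_two_state(self):
        a, b = 300.0, 100.0
        p = a / (a + b)
        spec = diffusion_coefficients(two_state_scheme(a, b), 500)
        assert spec.taus[0] == pytest.approx(1.0 / (a + b), rel=1e-9)
        assert spec.sigmas[0] ** 2 == pytest.approx(p * (1 - p) / 500, rel=1e-9)

    def test_channel_count_scaling(self):
        """Quadrupling the channel count halves every sigma."""
        scheme = potassium_chain_scheme(80.0, 120.0)
        s1 = diffusion_coefficients(scheme, 250)
        s4 = diffusion_coefficients(scheme, 1000)
        np.testing.assert_allclose(s4.sigmas, s1.sigmas / 2.0, rtol=1e-9)

    def test_variance_sums_to_binomial(self):
        """Total OU variance equals the stationary open-fraction variance."""
        scheme = potassium_chain_scheme(80.0, 120.0)
        n = 1000
        spec = diffusion_coefficients(scheme, n)
        pi = scheme.stationary()
        p_open = pi[4]
        assert np.sum(spec.sigmas**2) == pytest.approx(p_open * (1 - p_open) / n,
                                                       rel=1e-9)

    def test_disconnected_scheme_rejected(self):
        rates = np.zeros((3, 3))
        rates[0, 1] = rates[1, 0] = 10.0  # state 2 unreachable
        with pytest.raises(ValueError):
            diffusion_coefficients(pc.KineticScheme(rates, open_states=(1,)), 100)


class TestExactMarkov:
    def test_symmetric_two_state_half_open(self):
        tr = exact_markov_simulation(two_state_scheme(200.0, 200.0), 2000,
                                     5.0, 2e-4, seed=0)
        # SE of the mean with ~tau=2.5 ms correlation time
        assert tr.mean() == pytest.approx(0.5, abs=0.01)

    def test_binomial_variance(self):
        sch = two_state_scheme(300.0, 100.0)
        n = 2000
        tr = exact_markov_simulation(sch, n, 5.0, 2e-4, seed=1)
        p = 0.75
        assert tr.var() == pytest.approx(p * (1 - p) / n, rel=0.10)

    def test_autocovariance_decay_time(self):
        a = b = 100.0
        tr = exact_markov_simulation(two_state_scheme(a, b), 2000, 10.0,
                                     5e-4, seed=2)
        x = tr - tr.mean()
        def ac(lag):
            return np.mean(x[:x.size - lag] * x[lag:])
        tau_steps = int(round(1.0 / (a + b) / 5e-4))
        ratio = ac(tau_steps) / ac(0)
        assert ratio == pytest.approx(np.exp(-1.0), abs=0.08)

    def test_coarse_dt_rejected(self):
        with pytest.raises(ValueError):
            exact_markov_simulation(two_state_scheme(1000.0, 1000.0), 100,
                                    1.0, 1e-3)


class TestReplayPRC:
    def test_zero_amplitude_gives_zero_shift(self):
        n = PhaseNeuron(PhaseNeuronConfig(jitter_sd=0.0, seed=0))
        raw = replay_prc(n, pulse_amplitude=0.0, pulse_duration=5e-4,
                         n_trials=20, i_ext=200.0)
        np.testing.assert_allclose(raw.z, 0.0, atol=1e-6)

    def test_recovers_prescribed_prc_for_small_charge(self):
        z0 = 1.0
        n = PhaseNeuron(PhaseNeuronConfig(z_true=pc.z_cos_peaked(z0),
                                          jitter_sd=0.0, seed=0))
        raw = replay_prc(n, pulse_amplitude=20.0, pulse_duration=1e-4,
                         n_trials=50, i_ext=200.0)
        truth = z0 * (1 - np.cos(2 * np.pi * raw.phi))
        assert np.max(np.abs(raw.z - truth)) / truth.max() < 0.02

    def test_protocol_is_deterministic(self):
        outs = []
        for _ in range(2):
            n = PhaseNeuron(PhaseNeuronConfig(jitter_sd=0.0, seed=0))
            raw = replay_prc(n, pulse_amplitude=50.0, pulse_duration=5e-4,
                             n_trials=25, i_ext=200.0)
            outs.append(raw.z)
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_works_on_conductance_model(self):
        n = ConductanceNeuron(seed=3)
        raw = replay_prc(n, pulse_amplitude=100.0, pulse_duration=5e-4,
                         n_trials=30)
        assert len(raw.samples) == 30
        assert np.all(np.isfinite(raw.z))
        # a conductance model near threshold late in the cycle advances
        assert raw.z.max() > 0
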