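"""Corrected direct-method estimator: phase bookkeeping, bounds, recovery."""

import numpy as np
import pytest

import prcclamp as pc
from prcclamp.direct import (Perturbation, assign_phase, corrected_direct_prc,
                             first_order_sample, second_order_sample)


class TestAssignPhase:
    def test_pulse_at_spike_gives_phase_zero(self, regular_train):
        phi, _, _ = assign_phase(
            regular_train, Perturbation(0.100, 100.0, 5e-4), mean_isi=0.01)
        assert phi == pytest.approx(0.0)

    def test_mid_interval_arithmetic(self, regular_train):
        phi, isi_p, isi_m = assign_phase(
            regular_train, Perturbation(0.105, 100.0, 5e-4), mean_isi=0.01)
        assert phi == pytest.approx(0.5)
        assert isi_p == pytest.approx(0.01)
        assert isi_m == pytest.approx(0.01)

    def test_phase_can_exceed_one_for_long_intervals(self):
        # a stretched interval lets tau exceed <ISI>
        train = pc.SpikeTrain(np.array([0.0, 0.01, 0.025, 0.035]))
        phi, _, _ = assign_phase(train, Perturbation(0.022, 100.0, 5e-4), 0.01)
        assert phi == pytest.approx(1.2)

    def test_pulse_outside_train_rejected(self, regular_train):
        with pytest.raises(ValueError):
            assign_phase(regular_train, Perturbation(0.001, 100.0, 5e-4), 0.01)
        with pytest.raises(ValueError):
            assign_phase(regular_train, Perturbation(5.0, 100.0, 5e-4), 0.01)


class TestSampleFormulas:
    def test_unperturbed_interval_gives_zero(self):
        s = first_order_sample(0.3, 0.010, 0.010, 0.05)
        assert s.z == pytest.approx(0.0)

    def test_first_order_arithmetic(self):
        # <ISI>=10 ms, perturbed 9 ms, Q=0.05 pC -> z = 0.1/0.05 = 2/pC
        s = first_order_sample(0.3, 0.009, 0.010, 0.05)
        assert s.z == pytest.approx(2.0)

    def test_second_order_arithmetic(self):
        # <ISI>=10 ms, previous interval 9.5 ms, tau=2 ms -> phi2=1.15, z=1
        s = second_order_sample(1.15, 0.0095, 0.010, 0.05)
        assert s.z == pytest.approx(1.0)
        assert s.phi == pytest.approx(1.15)

    def test_zero_charge_is_an_error(self):
        with pytest.raises(ValueError):
            first_order_sample(0.3, 0.009, 0.010, 0.0)

    def test_out_of_band_phi2_rejected(self):
        with pytest.raises(ValueError):
            second_order_sample(0.5, 0.0095, 0.010, 0.05)

    def test_sign_convention_shortening_is_advance(self):
        s = first_order_sample(0.5, 0.010 - 0.001, 0.010, 0.05)
        assert s.z > 0


class TestCorrectedDirectPRC:
    def test_regular_train_tiny_pulses_all_zero(self, regular_train):
        pulses = [Perturbation(0.1 + 0.01 * k + 0.004, 1.0, 5e-4)
                  for k in range(100)]
        raw = corrected_direct_prc(regular_train, pulses, mean_isi=0.01)
        np.testing.assert_allclose(raw.z, 0.0, atol=1e-9)

    def test_charge_linearity(self, regular_train):
        """Doubling Q with identical spike data halves every z sample."""
        t = np.array([0.1 + 0.01 * k + (0.0002 if k == 5 else 0.0)
                      for k in range(30)])
        train = pc.SpikeTrain(t)
        mk = lambda amp: [Perturbation(0.1 + 0.01 * k + 0.004, amp, 5e-4)
                          for k in range(2, 28, 3)]
        raw1 = corrected_direct_prc(train, mk(100.0), mean_isi=0.01,
                                    phase_convention="onset")
        raw2 = corrected_direct_prc(train, mk(200.0), mean_isi=0.01,
                                    phase_convention="onset")
        np.testing.assert_allclose(raw2.z, raw1.z / 2.0, atol=1e-12)

    def test_no_valid_pulses_is_an_error(self, regular_train):
        with pytest.raises(ValueError):
            corrected_direct_prc(regular_train, [Perturbation(99.0, 100.0, 5e-4)])

    def test_bound_compliance_on_simulated_session(self, cos_session):
        """Censoring bounds hold for every sample (onset coordinates)."""
        train, pulses, _ = cos_session
        raw = corrected_direct_prc(train, pulses)
        q = raw.charge
        phi_on, z, order = raw.phi_onset, raw.z, raw.order
        o1 = order == 1
        assert np.all(z[o1] <= (1.0 - phi_on[o1]) / q + 1e-9)
        o2 = order == 2
        assert np.all(z[o2] >= (1.0 - phi_on[o2]) / q - 1e-9)
        assert np.all(z[o2] <= (2.0 - phi_on[o2]) / q + 1e-9)

    def test_second_order_restores_upper_domain(self, cos_session):
        """Completion samples populate phi near 1, above the first-order bound."""
        train, pulses, _ = cos_session
        raw = corrected_direct_prc(train, pulses)
        phi2 = raw.phi_onset[raw.order == 2]
        assert phi2.size > 10
        assert np.all(phi2 >= 0.9 - 1e-12)
        assert np.all(phi2 <= 1.0 + 1e-12)

    def test_skip_log_accounts_for_all_pulses(self, cos_session):
        train, pulses, _ = cos_session
        raw = corrected_direct_prc(train, pulses)
        n_first = int(np.sum(raw.order == 1))
        assert n_first + sum(raw.skip_log.values()) == len(pulses)

    def test_sampling_error_shrinks_with_trial_count(self):
        """Binned mean absolute error vs ground truth decreases ~ n^(-1/2)."""
        z0 = 1.0
        maes = []
        for n_pulses, seed in ((350, 21), (1400, 22), (5600, 23)):
            neuron = pc.PhaseNeuron(pc.PhaseNeuronConfig(
                z_true=pc.z_cos_peaked(z0), seed=seed))
            train, pulses, _ = pc.run_closed_loop_session(
                neuron, pc.PIDConfig(f_target=50.0), n_pulses=n_pulses, seed=seed)
            model = pc.DirectPRC(train, pulses, t_start=5.0)
            raw = corrected_direct_prc(model.train, model.pulses)
            bins = np.linspace(0, 1, 11)
            idx = np.clip(np.digitize(raw.phi, bins) - 1, 0, 9)
            centers = 0.5 * (bins[:-1] + bins[1:])
            truth = z0 * (1 - np.cos(2 * np.pi * centers))
            mae = np.nanmean([
                abs(raw.z[idx == b].mean() - truth[b])
                for b in range(10) if np.any(idx == b)
            ])
            maes.append(mae)
        assert maes[0] > maes[1] > maes[2]
        assert maes[0] / maes[2] > 2.0  # expected ~4 for a 16x trial ratio
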