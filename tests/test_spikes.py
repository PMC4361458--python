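"""Spike detection, ISI statistics and the online rate estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prcclamp as pc
from prcclamp.spikes import RateEstimator, VoltageTrace, detect_spikes, isi_stats


def make_triangle_trace(peak_times_s, fs=30000.0, dur=0.05):
    """Synthetic trace with 3-sample triangular APs crossing -20 mV."""
    n = int(dur * fs)
    v = np.full(n, -60.0)
    for tp in peak_times_s:
        k = int(round(tp * fs))
        v[k - 1], v[k], v[k + 1] = -10.0, 20.0, -40.0
    return VoltageTrace(v, fs)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        tr = VoltageTrace(np.full(3000, -60.0), 30000.0)
        assert len(detect_spikes(tr, threshold=-20.0)) == 0

    def test_triangular_spikes_detected_at_peaks(self):
        peaks = [0.010, 0.020, 0.030]
        tr = make_triangle_trace(peaks)
        out = detect_spikes(tr, threshold=-20.0)
        np.testing.assert_allclose(out.spike_times, peaks, atol=1.0 / 30000.0)

    def test_empty_trace_is_an_error(self):
        with pytest.raises(ValueError):
            detect_spikes(VoltageTrace(np.zeros(0), 30000.0))

    def test_refractory_merges_double_crossings(self):
        fs = 30000.0
        v = np.full(300, -60.0)
        v[100], v[101], v[102] = 10.0, -30.0, 15.0  # two crossings 33 us apart
        out = detect_spikes(VoltageTrace(v, fs), threshold=-20.0, refractory=1e-3)
        assert len(out) == 1

    def test_simulator_ground_truth_recovered(self):
        """>= 99.9% of simulator-emitted spikes found within one sample."""
        neuron = pc.PhaseNeuron(pc.PhaseNeuronConfig(seed=2))
        train, trace = neuron.run(20.0, i_dc=200.0, render_voltage=True)
        det = detect_spikes(trace, threshold=-20.0)
        truth = train.spike_times
        hits = sum(
            np.any(np.abs(det.spike_times - t) <= 1.001 / 30000.0) for t in truth
        )
        assert hits / truth.size >= 0.999


class TestISIStats:
    def test_regular_train(self, regular_train):
        s = isi_stats(regular_train)
        assert s.mean_isi == pytest.approx(0.01)
        assert s.cv == pytest.approx(0.0, abs=1e-12)
        assert s.rate == pytest.approx(100.0)

    def test_two_interval_arithmetic(self):
        train = pc.SpikeTrain(np.array([0.0, 0.008, 0.020]))
        s = isi_stats(train)
        assert s.mean_isi == pytest.approx(0.010)
        assert s.cv == pytest.approx(0.2)

    def test_exclusion_removes_intervals(self):
        train = pc.SpikeTrain(np.array([0.0, 0.008, 0.020, 0.030]))
        s = isi_stats(train, exclude={0, 1})
        assert s.mean_isi == pytest.approx(0.010)
        assert s.n_isi == 1

    def test_too_few_spikes_is_an_error(self):
        with pytest.raises(ValueError):
            isi_stats(pc.SpikeTrain(np.array([0.1])))

    def test_jittered_simulator_cv_matches_parameter(self):
        neuron = pc.PhaseNeuron(pc.PhaseNeuronConfig(
            z_true=pc.z_flat(0.0), jitter_sd=0.07, seed=3))
        spikes = neuron.advance(200.0, i_dc=200.0)  # ~10 000 ISIs at 50 Hz
        s = isi_stats(pc.SpikeTrain(spikes))
        assert s.cv == pytest.approx(0.07, abs=0.005)


class TestRateEstimator:
    def test_constant_isi_converges_to_inverse(self):
        est = RateEstimator(f_hat=0.0, tau=1.0)
        for _ in range(1500):
            est.update(0.020)
        assert est.f_hat == pytest.approx(50.0, rel=1e-6)

    def test_half_decay_identity(self):
        """isi = tau ln 2 from F=0 gives exactly half the inverse ISI."""
        tau = 1.0
        isi = tau * np.log(2.0)
        est = RateEstimator(f_hat=0.0, tau=tau)
        assert est.update(isi) == pytest.approx(0.5 / isi)

    def test_against_stepwise_replay_oracle(self):
        """Alternating 8/12 ms ISIs: estimator equals a literal re-evaluation."""
        isis = np.tile([0.008, 0.012], 250)
        est = RateEstimator(f_hat=50.0, tau=1.0)
        f_oracle = 50.0
        for isi in isis:
            w = np.exp(-isi / 1.0)  # independent, literal formula transcription
            f_oracle = (1.0 - w) / isi + f_oracle * w
            est.update(isi)
        assert est.f_hat == pytest.approx(f_oracle, rel=0, abs=0)

    def test_invalid_isi_rejected(self):
        with pytest.raises(ValueError):
            RateEstimator(f_hat=10.0).update(0.0)

    @given(
        f0=st.floats(0.0, 300.0),
        isis=st.lists(st.floats(1e-3, 1.0), min_size=1, max_size=50),
    )
    @settings(max_examples=100, deadline=None)
    def test_update_is_convex_combination(self, f0, isis):
        """F_k always lies between 1/ISI_k and F_{k-1} (and converges for
        constant ISI toward 1/T monotonically)."""
        est = RateEstimator(f_hat=f0, tau=1.0)
        for isi in isis:
            prev = est.f_hat
            new = est.update(isi)
            lo, hi = sorted((1.0 / isi, prev))
            assert lo - 1e-9 <= new <= hi + 1e-9

    def test_monotone_convergence_for_constant_isi(self):
        est = RateEstimator(f_hat=0.0, tau=1.0)
        vals = [est.update(0.02) for _ in range(100)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        est2 = RateEstimator(f_hat=200.0, tau=1.0)
        vals2 = [est2.update(0.02) for _ in range(100)]
        assert all(b <= a for a, b in zip(vals2, vals2[1:]))
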