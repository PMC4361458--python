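"""PID controller, Sobol scheduling and closed-loop session orchestration."""

import numpy as np
import pytest

import prcclamp as pc
from prcclamp.clamp import (ClampError, PIDConfig, PIDController,
                            SobolScheduler, sobol_gray)


class TestPIDController:
    def cfg(self, **kw):
        base = dict(f_target=50.0, g_p=0.001, g_i=0.1, g_d=0.0)
        base.update(kw)
        return PIDConfig(**base)

    def test_zero_error_zero_output(self):
        pid = PIDController(self.cfg())
        assert pid.update(0.0) == 0.0

    def test_pure_proportional(self):
        pid = PIDController(self.cfg(g_p=1.0, g_i=0.0))
        assert pid.update(5.0) == pytest.approx(5.0)

    def test_integral_telescopes(self):
        pid = PIDController(self.cfg(g_p=0.0, g_i=0.1))
        for _ in range(40):
            out = pid.update(2.0)
        assert out == pytest.approx(0.1 * 40 * 2.0)

    def test_derivative_term(self):
        pid = PIDController(self.cfg(g_p=0.0, g_i=0.0, g_d=2.0))
        pid.update(1.0)
        assert pid.update(4.0) == pytest.approx(2.0 * 3.0)

    def test_update_during_hold_is_noop_with_warning(self):
        pid = PIDController(self.cfg(g_p=1.0, g_i=0.0))
        pid.update(3.0)
        pid.enter_hold()
        with pytest.warns(UserWarning):
            out = pid.update(100.0)
        assert out == pytest.approx(3.0)

    def test_release_without_hold_is_an_error(self):
        pid = PIDController(self.cfg())
        with pytest.raises(RuntimeError):
            pid.release_hold()

    def test_anti_windup_freezes_integrator_at_clamp(self):
        pid = PIDController(self.cfg(g_p=0.0, g_i=1.0, i_max=10.0))
        for _ in range(50):
            pid.update(5.0)
        assert pid.i_holding == 10.0
        assert pid.err_sum <= 10.0 + 5.0  # stopped accumulating at the rail


class TestSobol:
    def test_first_three_values(self):
        np.testing.assert_allclose(sobol_gray(3), [0.5, 0.75, 0.25])

    def test_matches_scipy_reference_generator(self):
        """Dimension-1 Gray-code stream equals scipy's Sobol points 1..n."""
        from scipy.stats import qmc

        ours = sobol_gray(255)
        ref = qmc.Sobol(d=1, scramble=False).random(256).ravel()[1:]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_low_discrepancy_gap_bound(self):
        vals = np.sort(sobol_gray(1400))
        gaps = np.diff(np.concatenate([[0.0], vals, [1.0]]))
        assert gaps.max() < 4.0 / 1400

    def test_scheduler_reproducible(self):
        a = SobolScheduler(skip=16).take(100)
        b = SobolScheduler(skip=16).take(100)
        np.testing.assert_array_equal(a, b)

    def test_skip_discards_initial_points(self):
        full = sobol_gray(20)
        skipped = SobolScheduler(skip=5).take(15)
        np.testing.assert_array_equal(skipped, full[5:])

    def test_period_validation(self):
        with pytest.raises(ValueError):
            SobolScheduler(period_aps=1)


class TestClosedLoopSession:
    def test_session_schedule_arithmetic(self, short_session):
        train, pulses, log = short_session
        assert len(pulses) == 120
        assert len(train) >= 120 * 6  # one pulse per 6 APs

    def test_controller_reaches_target(self, short_session):
        _, _, log = short_session
        assert abs(log.mean_rate(5.0) - 50.0) / 50.0 < 0.02

    def test_hold_windows_have_constant_current(self, short_session):
        _, _, log = short_session
        assert log.hold_violations() == 0

    def test_sessions_reproducible(self):
        out = []
        for _ in range(2):
            neuron = pc.PhaseNeuron(pc.PhaseNeuronConfig(seed=6))
            train, _, log = pc.run_closed_loop_session(
                neuron, PIDConfig(f_target=50.0), n_pulses=40, seed=6)
            out.append((train.spike_times, log.pulses["t_pulse"].to_numpy()))
        np.testing.assert_array_equal(out[0][0], out[1][0])
        np.testing.assert_array_equal(out[0][1], out[1][1])

    def test_unreachable_target_aborts_with_diagnostic(self):
        neuron = pc.PhaseNeuron(pc.PhaseNeuronConfig(seed=1))
        with pytest.raises(ClampError, match="not reached|aborted"):
            pc.run_closed_loop_session(
                neuron, PIDConfig(f_target=400.0, i_max=100.0),
                n_pulses=20, seed=1, t_max=20.0)

    def test_hold_removes_controller_transients(self):
        """With the PID held during perturbation windows, the holding current
        around each pulse is flat; the same session with hold disabled (by
        releasing immediately) would not be testable, so we assert the
        logged contract directly across every pulse."""
        neuron = pc.PhaseNeuron(pc.PhaseNeuronConfig(seed=8))
        _, _, log = pc.run_closed_loop_session(
            neuron, PIDConfig(f_target=50.0), n_pulses=60, seed=8)
        t = log.spikes["t"].to_numpy()
        ih = log.spikes["i_holding"].to_numpy()
        for _, p in log.pulses.iterrows():
            j = int(p["trigger_spike"])
            after = np.flatnonzero(t > p["t_pulse"])
            k = int(after[1]) if after.size >= 2 else len(t)
            assert np.ptp(ih[j:k]) == 0.0

    def test_held_flag_marks_scheduling_to_release(self, short_session):
        _, _, log = short_session
        held = log.spikes["held"].to_numpy()
        assert held.any() and not held.all()
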