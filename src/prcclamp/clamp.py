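"""The closed-loop frequency clamp.

A tonically firing cell is held at a chosen mean rate by a PID controller
acting on the holding current: after every detected AP the online rate
estimate F_k (see :mod:`prcclamp.spikes`) is compared with the target,
e_k = F_target - F_k, and the holding current updated as

    I_holding = gP e_k + gI sum_i e_i + gD (e_k - e_{k-1})

with the experimentally used gains gP = 0.001, gI = 0.1, gD = 0 pA/Hz.  One
PRC pulse is delivered per six APs, at a delay after a trigger AP drawn from
a Gray-code Sobol sequence scaled by the current period estimate, so phases
are sampled more uniformly than with pseudo-random delays.  From the AP that
schedules a pulse to the second AP after it the controller is disconnected
and its last output held constant, keeping controller transients out of the
perturbed intervals.

``run_closed_loop_session`` orchestrates the whole protocol on a simulated
neuron and returns the artifacts the direct-method estimator consumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels as K
from .direct import Perturbation
from .neurons import ConductanceNeuron, PhaseNeuron
from .spikes import SpikeTrain

__all__ = [
    "PIDConfig",
    "PIDController",
    "SobolScheduler",
    "sobol_gray",
    "SessionLog",
    "run_closed_loop_session",
    "ClampError",
]


class ClampError(RuntimeError):
    """Raised when a closed-loop session cannot reach or hold its target."""


@dataclass(frozen=True)
class PIDConfig:
    """Controller gains (pA/Hz), target rate (Hz) and output clamp (pA)."""

    f_target: float
    g_p: float = 0.001
    g_i: float = 0.1
    g_d: float = 0.0
    i_min: float = -200.0
    i_max: float = 1000.0
    tau_estimator: float = 1.0
    freeze_integrator_in_hold: bool = True

    def __post_init__(self):
        if self.f_target <= 0:
            raise ValueError("f_target must be positive")
        if self.i_min >= self.i_max:
            raise ValueError("i_min must be below i_max")


class PIDController:
    """Reference per-AP PID with hold windows and integrator anti-windup.

    This is the plain-Python statement of the controller contract; the
    session kernels inline the same arithmetic for speed and are checked
    against it in the tests.
    """

    def __init__(self, config: PIDConfig):
        self.config = config
        self.err_sum = 0.0
        self.err_prev = 0.0
        self.i_holding = 0.0
        self.held = False

    def update(self, e_k: float) -> float:
        """One per-AP update; a no-op (with a warning) while held."""
        if self.held:
            warnings.warn("PID update ignored: controller is held", stacklevel=2)
            return self.i_holding
        cfg = self.config
        s_try = self.err_sum + e_k
        i_raw = cfg.g_p * e_k + cfg.g_i * s_try + cfg.g_d * (e_k - self.err_prev)
        if i_raw > cfg.i_max:
            self.i_holding = cfg.i_max
        elif i_raw < cfg.i_min:
            self.i_holding = cfg.i_min
        else:
            self.i_holding = i_raw
            self.err_sum = s_try  # integrator frozen while output is clamped
        self.err_prev = e_k
        return self.i_holding

    def enter_hold(self):
        if self.held:
            raise RuntimeError("already held")
        self.held = True

    def release_hold(self):
        if not self.held:
            raise RuntimeError("release without enter_hold")
        self.held = False


# ---------------------------------------------------------------------------
# Gray-code Sobol sequence, dimension 1
# ---------------------------------------------------------------------------

_SOBOL_BITS = 32


def sobol_gray(n: int, skip: int = 0) -> np.ndarray:
    """First ``n`` points of the 1-D Gray-code Sobol sequence after ``skip`` discards.

    In dimension 1 the direction numbers are v_j = 2^(-j-1) and the Gray-code
    update XORs the direction number indexed by the lowest zero bit of the
    running counter; with no discards the stream opens 0.5, 0.75, 0.25, ...
    """
    out = np.empty(n)
    cur = np.uint64(0)
    m = 0
    for k in range(skip + n):
        j = (~m & (m + 1)).bit_length() - 1  # index of lowest zero bit of m
        m += 1
        cur ^= np.uint64(1) << np.uint64(_SOBOL_BITS - 1 - j)
        if k >= skip:
            out[k - skip] = float(cur) / float(1 << _SOBOL_BITS)
    return out


@dataclass
class SobolScheduler:
    """Reactive-clamp pulse scheduler.

    Emits quasi-random delays in [0, 1) (fractions of the current period
    estimate), one per ``period_aps`` APs, from the Gray-code Sobol sequence
    after discarding ``skip`` initial points.
    """

    skip: int = 16
    period_aps: int = 6
    index: int = 0  # number of delays emitted so far

    def __post_init__(self):
        if self.period_aps < 2:
            raise ValueError("period_aps must be >= 2")
        self._cur = np.uint64(0)
        self._m = 0
        for _ in range(self.skip):
            self._advance()

    def _advance(self) -> float:
        j = (~self._m & (self._m + 1)).bit_length() - 1
        self._m += 1
        self._cur = self._cur ^ (np.uint64(1) << np.uint64(_SOBOL_BITS - 1 - j))
        return float(self._cur) / float(1 << _SOBOL_BITS)

    def next_delay(self) -> float:
        self.index += 1
        return self._advance()

    def take(self, n: int) -> np.ndarray:
        return np.array([self.next_delay() for _ in range(n)])


# ---------------------------------------------------------------------------
# session orchestration
# ---------------------------------------------------------------------------


@dataclass
class SessionLog:
    """Complete closed-loop record: per-spike controller state and pulses.

    ``spikes`` columns: t, isi, f_hat, e, i_holding, held.
    ``pulses`` columns: t_pulse, amplitude, duration, scheduled_delay,
    trigger_spike.
    """

    spikes: pd.DataFrame
    pulses: pd.DataFrame
    config: dict = field(default_factory=dict)

    @property
    def n_pulses(self) -> int:
        return len(self.pulses)

    def mean_rate(self, t_start: float = 0.0) -> float:
        t = self.spikes["t"].to_numpy()
        t = t[t >= t_start]
        if t.size < 2:
            raise ValueError("not enough spikes after t_start")
        return (t.size - 1) / (t[-1] - t[0])

    def hold_violations(self, atol: float = 0.0) -> int:
        """Number of perturbation windows in which the holding current moved.

        Scans, for every pulse, the spikes from the scheduling AP to the
        second AP after delivery and counts windows where i_holding is not
        constant.  The hold contract requires this to be zero.
        """
        t = self.spikes["t"].to_numpy()
        i_hold = self.spikes["i_holding"].to_numpy()
        bad = 0
        for _, p in self.pulses.iterrows():
            j = int(p["trigger_spike"])
            after = np.flatnonzero(t > p["t_pulse"])
            if after.size < 2:
                continue
            k = int(after[1])  # second spike after the pulse: hold ends here
            # i_hold[m] is the current in effect during (t_m, t_{m+1}); the
            # hold covers (t_j, t_k), i.e. entries j..k-1
            window = i_hold[j:k]
            if window.size and np.max(np.abs(window - window[0])) > atol:
                bad += 1
        return bad

    def perturbations(self) -> list:
        return [
            Perturbation(t_pulse=row["t_pulse"], amplitude=row["amplitude"],
                         duration=row["duration"])
            for _, row in self.pulses.iterrows()
        ]

    def spike_train(self, source_id: str = "session") -> SpikeTrain:
        return SpikeTrain(self.spikes["t"].to_numpy(), source_id=source_id)


def run_closed_loop_session(
    neuron,
    pid: PIDConfig,
    n_pulses: int = 1400,
    pulse_amplitude: float = 100.0,
    pulse_duration: float = 0.5e-3,
    scheduler: SobolScheduler | None = None,
    seed: int = 0,
    pid_enabled: bool = True,
    i_const: float = 0.0,
    t_max: float | None = None,
):
    """Run a complete frequency-clamped PRC session on a simulated neuron.

    Returns ``(SpikeTrain, list[Perturbation], SessionLog)``.  With
    ``pid_enabled=False`` the holding current stays at ``i_const`` (the
    open-loop control condition); scheduling and hold bookkeeping proceed
    identically.

    Raises :class:`ClampError` if the neuron cannot complete the schedule
    (silent, saturated against the output clamp, or out of time).
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    sched = scheduler or SobolScheduler()
    delays = sched.take(n_pulses)
    if t_max is None:
        t_max = 4.0 * (n_pulses + 10) * sched.period_aps / pid.f_target + 120.0

    if isinstance(neuron, PhaseNeuron):
        cfg = neuron.config
        out = K.phase_closed_loop(
            cfg.dt, cfg.rate_at_rest, cfg.rate_slope, neuron.z_table,
            float(cfg.jitter_sd), 0 if cfg.jitter_mode == "cycle" else 1,
            int(seed),
            1 if pid_enabled else 0, float(i_const),
            pid.g_p, pid.g_i, pid.g_d, pid.f_target, pid.i_min, pid.i_max,
            pid.tau_estimator, 1 if pid.freeze_integrator_in_hold else 0,
            delays, int(sched.period_aps),
            float(pulse_amplitude), float(pulse_duration), float(t_max),
        )
        model_desc = {"model": "phase", "dt": cfg.dt,
                      "jitter_sd": cfg.jitter_sd}
    elif isinstance(neuron, ConductanceNeuron):
        out = K.wb_closed_loop(
            neuron.dt, neuron.state, neuron.i_intrinsic, neuron.area,
            neuron.noise_current_sd, neuron.eta_taus, neuron.eta_sigmas,
            int(seed),
            1 if pid_enabled else 0, float(i_const),
            pid.g_p, pid.g_i, pid.g_d, pid.f_target, pid.i_min, pid.i_max,
            pid.tau_estimator, 1 if pid.freeze_integrator_in_hold else 0,
            delays, int(sched.period_aps),
            float(pulse_amplitude), float(pulse_duration), float(t_max),
            neuron.V_THRESH, neuron.REFRACTORY,
        )
        model_desc = {"model": "conductance", "dt": neuron.dt,
                      "noise_current_sd": neuron.noise_current_sd}
    else:
        raise TypeError(f"unsupported neuron type {type(neuron).__name__}")

    sp_t, sp_f, sp_e, sp_i, sp_held, pu_t, pu_trig, n_sp, n_done, aborted = out
    if not aborted and pid_enabled and n_sp > 20:
        # the schedule can complete even when the target is out of reach
        # (pulses are per-AP); flag sessions that never clamped
        tail = sp_t[n_sp // 2:]
        achieved = (tail.size - 1) / (tail[-1] - tail[0])
        if abs(achieved - pid.f_target) / pid.f_target > 0.2:
            raise ClampError(
                f"target rate not reached: {achieved:.1f} Hz vs "
                f"{pid.f_target:.1f} Hz over the second half of the session "
                f"(output clamp [{pid.i_min}, {pid.i_max}] pA)"
            )
    if aborted or n_done < n_pulses:
        achieved = float("nan")
        if n_sp > 10:
            achieved = (n_sp - 1) / (sp_t[-1] - sp_t[0])
        raise ClampError(
            f"session aborted after {n_done}/{n_pulses} pulses, {n_sp} APs; "
            f"achieved rate {achieved:.1f} Hz vs target {pid.f_target:.1f} Hz "
            f"(output clamp [{pid.i_min}, {pid.i_max}] pA)"
        )

    isi = np.concatenate([[np.nan], np.diff(sp_t)])
    spikes_df = pd.DataFrame({
        "t": sp_t, "isi": isi, "f_hat": sp_f, "e": sp_e,
        "i_holding": sp_i, "held": sp_held.astype(bool),
    })
    pulses_df = pd.DataFrame({
        "t_pulse": pu_t,
        "amplitude": pulse_amplitude,
        "duration": pulse_duration,
        "scheduled_delay": delays[: pu_t.size],
        "trigger_spike": pu_trig,
    })
    config = {
        "pid": asdict(pid),
        "pid_enabled": bool(pid_enabled),
        "i_const": float(i_const),
        "n_pulses": int(n_pulses),
        "pulse_amplitude": float(pulse_amplitude),
        "pulse_duration": float(pulse_duration),
        "scheduler": {"skip": sched.skip, "period_aps": sched.period_aps},
        "seed": int(seed),
        **model_desc,
    }
    log = SessionLog(spikes=spikes_df, pulses=pulses_df, config=config)
    train = log.spike_train()
    return train, log.perturbations(), log
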