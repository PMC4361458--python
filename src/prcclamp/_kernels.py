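"""Numerical inner loops for the simulators.

Everything here is plain-array, sample-by-sample code, jitted with numba when
it is available and run as ordinary Python otherwise.  The two closed-loop
session kernels (phase oscillator and conductance surrogate) duplicate the
small controller skeleton on purpose: the controller state is scalar and
keeping each kernel self-contained lets numba compile them independently.

Controller skeleton (identical in both kernels, one update per detected AP):

* rate estimator  F_k = (1/ISI_k)(1 - e^(-ISI_k/tau)) + F_{k-1} e^(-ISI_k/tau)
* PID             I_hold = gP e_k + gI sum(e) + gD (e_k - e_{k-1}),
                  clamped to [i_min, i_max] with a frozen integrator while
                  clamped (anti-windup) and while a hold window is open
* hold window     from the AP that schedules a pulse to the second AP after
                  the pulse: the PID output is frozen and the integrator does
                  not accumulate
* scheduling      one pulse per `period_aps` APs, delivered `delay * 1/F_k`
                  after the scheduling AP, `delay` drawn from a supplied
                  low-discrepancy stream
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


# ---------------------------------------------------------------------------
# phase-oscillator neuron
# ---------------------------------------------------------------------------


@njit(cache=True)
def _z_interp(z_table, phi):
    """Linear interpolation of the PRC lookup table on phi in [0, 1)."""
    n = z_table.size - 1
    x = phi * n
    i = int(x)
    if i < 0:
        i = 0
    if i >= n:
        i = n - 1
    frac = x - i
    return z_table[i] * (1.0 - frac) + z_table[i + 1] * frac


@njit(cache=True)
def _draw_cycle_scale(jitter_sd):
    """Speed multiplier for one firing cycle: ISI_k = (1 + xi_k) / f."""
    xi = jitter_sd * np.random.normal()
    if xi < -0.5:
        xi = -0.5
    if xi > 0.5:
        xi = 0.5
    return 1.0 / (1.0 + xi)


@njit(cache=True)
def phase_free_run(
    phi0,
    n_steps,
    dt,
    f0,
    slope,
    i_dc,
    i_fluct,          # per-sample fluctuating current (pA); size n_steps or 0
    z_table,
    jitter_sd,
    jitter_mode,      # 0 = per-cycle ISI scaling, 1 = per-step phase diffusion
    seed,
    record_phase,     # 0/1: fill and return the phase trace
):
    """Free-running phase oscillator; returns (spike_times, phi_end, phase_trace).

    dphi/dt = f(I_dc) * s_k + z(phi) * I_fluct(t) + jitter, spike and reset
    at phi = 1.  In cycle mode (default) s_k = 1/(1 + xi_k) with one
    xi_k ~ N(0, jitter_sd) per cycle, so the unperturbed ISI CV equals
    jitter_sd exactly; diffusion mode adds white phase noise per step
    instead.  Spike times are sub-sample (linear interpolation of the
    crossing); the phase trace (optional) is sampled on the step grid.
    """
    np.random.seed(seed)
    have_fluct = i_fluct.size > 0
    phases = np.empty(n_steps if record_phase == 1 else 0)
    spikes = np.empty(n_steps // 2 + 2)
    n_sp = 0
    phi = phi0
    sqrt_dt = np.sqrt(dt)
    f = f0 + slope * i_dc
    if f < 0.0:
        f = 0.0
    scale = 1.0
    if jitter_mode == 0 and jitter_sd > 0.0:
        scale = _draw_cycle_scale(jitter_sd)
    for k in range(n_steps):
        zp = _z_interp(z_table, phi)
        dphi = f * scale * dt
        if have_fluct:
            dphi += zp * i_fluct[k] * dt
        if jitter_mode == 1 and jitter_sd > 0.0 and f > 0.0:
            dphi += jitter_sd * np.sqrt(f) * sqrt_dt * np.random.normal()
        phi += dphi
        if phi >= 1.0:
            over = phi - 1.0
            frac = over / dphi if dphi > 1e-300 else 0.0
            spikes[n_sp] = (k + 1 - frac) * dt
            n_sp += 1
            phi -= 1.0
            if phi >= 1.0:  # pathological kick; clip
                phi = 0.999999
            if jitter_mode == 0 and jitter_sd > 0.0:
                scale = _draw_cycle_scale(jitter_sd)
        if record_phase == 1:
            phases[k] = phi
    return spikes[:n_sp], phi, phases


@njit(cache=True)
def phase_closed_loop(
    dt,
    f0,
    slope,
    z_table,
    jitter_sd,
    jitter_mode,
    seed,
    # controller
    pid_enabled,      # 0/1; when 0, i_hold stays at i_const
    i_const,
    g_p,
    g_i,
    g_d,
    f_target,
    i_min,
    i_max,
    tau_est,
    freeze_integrator_in_hold,  # 0/1
    # stimulation
    delays,           # low-discrepancy delays in [0,1), one per pulse
    period_aps,
    pulse_amp,
    pulse_dur,
    t_max,
):
    """Closed-loop frequency-clamp session on the phase neuron.

    Returns (spike_times, f_hat, e_k, i_hold, held_flag, pulse_times,
    pulse_trigger_spike, n_spikes, n_pulses_delivered, aborted).
    Per-spike arrays are aligned with spike_times; pulse_times are actual
    delivery (onset) times.
    """
    np.random.seed(seed)
    n_pulses = delays.size
    max_sp = int((n_pulses + 4) * period_aps + 4000)
    sp_t = np.empty(max_sp)
    sp_f = np.empty(max_sp)
    sp_e = np.empty(max_sp)
    sp_i = np.empty(max_sp)
    sp_held = np.zeros(max_sp, dtype=np.int8)
    pu_t = np.empty(n_pulses)
    pu_trig = np.empty(n_pulses, dtype=np.int64)

    phi = 0.0
    t = 0.0
    f_hat = f_target
    err_sum = 0.0
    err_prev = 0.0
    i_hold = 0.0 if pid_enabled == 1 else i_const
    held = False
    pending = False       # pulse scheduled, not yet fully delivered
    pulse_t = 0.0
    n_sched = 0
    n_done = 0
    spikes_after_pulse = 0
    aps_since_trigger = 0
    n_sp = 0
    last_sp = 0.0
    sqrt_dt = np.sqrt(dt)
    aborted = 0
    scale = 1.0
    if jitter_mode == 0 and jitter_sd > 0.0:
        scale = _draw_cycle_scale(jitter_sd)

    while True:
        if n_done >= n_pulses and not held and not pending:
            break
        if t >= t_max or n_sp >= max_sp - 2:
            aborted = 1
            break
        i_p = 0.0
        if pending and t >= pulse_t and t < pulse_t + pulse_dur:
            i_p = pulse_amp
        f = f0 + slope * i_hold
        if f < 0.0:
            f = 0.0
        dphi = f * scale * dt + _z_interp(z_table, phi) * i_p * dt
        if jitter_mode == 1 and jitter_sd > 0.0 and f > 0.0:
            dphi += jitter_sd * np.sqrt(f) * sqrt_dt * np.random.normal()
        phi += dphi
        t += dt
        if pending and t >= pulse_t + pulse_dur:
            pending = False  # delivery complete; hold stays until 2nd AP after
        if phi >= 1.0:
            over = phi - 1.0
            frac = over / dphi if dphi > 1e-300 else 0.0
            t_sp = t - frac * dt
            phi -= 1.0
            if phi >= 1.0:
                phi = 0.999999
            if jitter_mode == 0 and jitter_sd > 0.0:
                scale = _draw_cycle_scale(jitter_sd)
            isi = t_sp - last_sp
            if n_sp > 0 and isi > 0.0:
                w = np.exp(-isi / tau_est)
                f_hat = (1.0 - w) / isi + f_hat * w
            last_sp = t_sp
            e = f_target - f_hat
            if held and t_sp >= pulse_t:
                spikes_after_pulse += 1
                if spikes_after_pulse >= 2 and not pending:
                    held = False
                    n_done += 1
            if pid_enabled == 1 and not held:
                if freeze_integrator_in_hold == 1:
                    s_try = err_sum + e
                else:
                    s_try = err_sum + e
                i_raw = g_p * e + g_i * s_try + g_d * (e - err_prev)
                if i_raw > i_max:
                    i_hold = i_max  # integrator frozen while clamped
                elif i_raw < i_min:
                    i_hold = i_min
                else:
                    i_hold = i_raw
                    err_sum = s_try
                err_prev = e
            elif pid_enabled == 1 and held and freeze_integrator_in_hold == 0:
                # optional variant: integrator keeps accumulating during hold,
                # output still frozen
                err_sum += e
                err_prev = e
            sp_t[n_sp] = t_sp
            sp_f[n_sp] = f_hat
            sp_e[n_sp] = e
            sp_i[n_sp] = i_hold
            sp_held[n_sp] = 1 if held else 0
            n_sp += 1
            aps_since_trigger += 1
            if (
                (not held)
                and (not pending)
                and n_sched < n_pulses
                and aps_since_trigger >= period_aps
            ):
                delay = delays[n_sched] / f_hat
                pulse_t = t_sp + delay
                pu_t[n_sched] = pulse_t
                pu_trig[n_sched] = n_sp - 1
                pending = True
                held = True
                spikes_after_pulse = 0
                aps_since_trigger = 0
                n_sched += 1
    return (
        sp_t[:n_sp],
        sp_f[:n_sp],
        sp_e[:n_sp],
        sp_i[:n_sp],
        sp_held[:n_sp],
        pu_t[:n_sched],
        pu_trig[:n_sched],
        n_sp,
        n_done,
        aborted,
    )


# ---------------------------------------------------------------------------
# conductance-based surrogate (Wang-Buzsaki-style single compartment)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _wb_rates(v):
    """Gating rates (1/ms) of the surrogate at membrane potential v (mV)."""
    # m gate (activation of Na, instantaneous)
    if abs(v + 35.0) < 1e-9:
        am = 1.0
    else:
        am = -0.1 * (v + 35.0) / (np.exp(-0.1 * (v + 35.0)) - 1.0)
    bm = 4.0 * np.exp(-(v + 60.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 58.0) / 20.0)
    bh = 1.0 / (np.exp(-0.1 * (v + 28.0)) + 1.0)
    if abs(v + 34.0) < 1e-9:
        an = 0.1
    else:
        an = -0.01 * (v + 34.0) / (np.exp(-0.1 * (v + 34.0)) - 1.0)
    bn = 0.125 * np.exp(-(v + 44.0) / 80.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def wb_step(state, i_density, dt_ms, gk_extra):
    """One integration step; state = (v, h, n); i_density in uA/cm2, dt in ms.

    ``gk_extra`` is an additive fluctuation of the open K fraction (channel
    noise); the effective K conductance is gK * max(n^4 + gk_extra, 0).
    """
    v, h, n = state
    am, bm, ah, bh, an, bn = _wb_rates(v)
    m_inf = am / (am + bm)
    g_na = 35.0
    g_k = 9.0
    g_l = 0.1
    e_na = 55.0
    e_k = -90.0
    e_l = -65.0
    phi_gate = 5.0
    pk = n**4 + gk_extra
    if pk < 0.0:
        pk = 0.0
    i_ion = (
        g_na * m_inf**3 * h * (v - e_na)
        + g_k * pk * (v - e_k)
        + g_l * (v - e_l)
    )
    dv = (-i_ion + i_density) * dt_ms  # C = 1 uF/cm2
    dh = phi_gate * (ah * (1.0 - h) - bh * h) * dt_ms
    dn = phi_gate * (an * (1.0 - n) - bn * n) * dt_ms
    return v + dv, h + dh, n + dn


@njit(cache=True)
def wb_free_run(
    state0,           # (v, h, n)
    n_steps,
    dt,               # seconds
    i_intrinsic,      # pA, constant depolarizing drive (tonic firing)
    i_ext,            # pA per-sample external current (size n_steps or 1)
    area,             # cm^2
    noise_current_sd,  # pA * sqrt(s): additive white-noise current scale
    eta_taus,         # OU time constants (s) for channel-noise terms (may be empty)
    eta_sigmas,       # matching stationary SDs (open-fraction units)
    eta0,             # initial OU values
    seed,
    record_v,         # 0/1
    v_thresh,
    refractory,
):
    """Free-running conductance surrogate.

    Returns (spike_times, state_end, eta_end, v_trace).  Spike times are the
    upward crossings of ``v_thresh`` on the sample grid, separated by at
    least ``refractory``.
    """
    np.random.seed(seed)
    dt_ms = dt * 1e3
    n_eta = eta_taus.size
    eta = eta0.copy()
    rho = np.empty(n_eta)
    drv = np.empty(n_eta)
    for j in range(n_eta):
        rho[j] = np.exp(-dt / eta_taus[j])
        drv[j] = eta_sigmas[j] * np.sqrt(1.0 - rho[j] * rho[j])
    v, h, n = state0[0], state0[1], state0[2]
    vtr = np.empty(n_steps if record_v == 1 else 0)
    spikes = np.empty(n_steps // 10 + 2)
    n_sp = 0
    last_sp = -1e9
    inv_area = 1.0e-6 / area  # pA -> uA/cm2
    white = noise_current_sd > 0.0
    sqdt = np.sqrt(dt)
    ext_scalar = i_ext.size == 1
    for k in range(n_steps):
        gk_extra = 0.0
        for j in range(n_eta):
            eta[j] = eta[j] * rho[j] + drv[j] * np.random.normal()
            gk_extra += eta[j]
        i_pa = i_intrinsic + (i_ext[0] if ext_scalar else i_ext[k])
        if white:
            i_pa += noise_current_sd * np.random.normal() / sqdt
        vprev = v
        v, h, n = wb_step((v, h, n), i_pa * inv_area, dt_ms, gk_extra)
        t = (k + 1) * dt
        if vprev < v_thresh and v >= v_thresh and t - last_sp >= refractory:
            spikes[n_sp] = t
            n_sp += 1
            last_sp = t
        if record_v == 1:
            vtr[k] = v
    state_end = np.array([v, h, n])
    return spikes[:n_sp], state_end, eta, vtr


@njit(cache=True)
def wb_closed_loop(
    dt,
    state0,
    i_intrinsic,
    area,
    noise_current_sd,
    eta_taus,
    eta_sigmas,
    seed,
    pid_enabled,
    i_const,
    g_p,
    g_i,
    g_d,
    f_target,
    i_min,
    i_max,
    tau_est,
    freeze_integrator_in_hold,
    delays,
    period_aps,
    pulse_amp,
    pulse_dur,
    t_max,
    v_thresh,
    refractory,
):
    """Closed-loop frequency-clamp session on the conductance surrogate.

    Same contract and return layout as ``phase_closed_loop``.
    """
    np.random.seed(seed)
    dt_ms = dt * 1e3
    n_pulses = delays.size
    max_sp = int((n_pulses + 4) * period_aps + 8000)
    sp_t = np.empty(max_sp)
    sp_f = np.empty(max_sp)
    sp_e = np.empty(max_sp)
    sp_i = np.empty(max_sp)
    sp_held = np.zeros(max_sp, dtype=np.int8)
    pu_t = np.empty(n_pulses)
    pu_trig = np.empty(n_pulses, dtype=np.int64)

    n_eta = eta_taus.size
    eta = np.zeros(n_eta)
    rho = np.empty(n_eta)
    drv = np.empty(n_eta)
    for j in range(n_eta):
        rho[j] = np.exp(-dt / eta_taus[j])
        drv[j] = eta_sigmas[j] * np.sqrt(1.0 - rho[j] * rho[j])
    v, h, n = state0[0], state0[1], state0[2]
    inv_area = 1.0e-6 / area
    white = noise_current_sd > 0.0
    sqdt = np.sqrt(dt)

    t = 0.0
    f_hat = f_target
    err_sum = 0.0
    err_prev = 0.0
    i_hold = 0.0 if pid_enabled == 1 else i_const
    held = False
    pending = False
    pulse_t = 0.0
    n_sched = 0
    n_done = 0
    spikes_after_pulse = 0
    aps_since_trigger = 0
    n_sp = 0
    last_sp = -1e9
    aborted = 0

    while True:
        if n_done >= n_pulses and not held and not pending:
            break
        if t >= t_max or n_sp >= max_sp - 2:
            aborted = 1
            break
        i_p = 0.0
        if pending and t >= pulse_t and t < pulse_t + pulse_dur:
            i_p = pulse_amp
        gk_extra = 0.0
        for j in range(n_eta):
            eta[j] = eta[j] * rho[j] + drv[j] * np.random.normal()
            gk_extra += eta[j]
        i_pa = i_intrinsic + i_hold + i_p
        if white:
            i_pa += noise_current_sd * np.random.normal() / sqdt
        vprev = v
        v, h, n = wb_step((v, h, n), i_pa * inv_area, dt_ms, gk_extra)
        t += dt
        if pending and t >= pulse_t + pulse_dur:
            pending = False
        if vprev < v_thresh and v >= v_thresh and t - last_sp >= refractory:
            t_sp = t
            isi = t_sp - last_sp
            if n_sp > 0 and isi > 0.0:
                w = np.exp(-isi / tau_est)
                f_hat = (1.0 - w) / isi + f_hat * w
            last_sp = t_sp
            e = f_target - f_hat
            if held and t_sp >= pulse_t:
                spikes_after_pulse += 1
                if spikes_after_pulse >= 2 and not pending:
                    held = False
                    n_done += 1
            if pid_enabled == 1 and not held:
                s_try = err_sum + e
                i_raw = g_p * e + g_i * s_try + g_d * (e - err_prev)
                if i_raw > i_max:
                    i_hold = i_max
                elif i_raw < i_min:
                    i_hold = i_min
                else:
                    i_hold = i_raw
                    err_sum = s_try
                err_prev = e
            elif pid_enabled == 1 and held and freeze_integrator_in_hold == 0:
                err_sum += e
                err_prev = e
            sp_t[n_sp] = t_sp
            sp_f[n_sp] = f_hat
            sp_e[n_sp] = e
            sp_i[n_sp] = i_hold
            sp_held[n_sp] = 1 if held else 0
            n_sp += 1
            aps_since_trigger += 1
            if (
                (not held)
                and (not pending)
                and n_sched < n_pulses
                and aps_since_trigger >= period_aps
            ):
                delay = delays[n_sched] / f_hat
                pulse_t = t_sp + delay
                pu_t[n_sched] = pulse_t
                pu_trig[n_sched] = n_sp - 1
                pending = True
                held = True
                spikes_after_pulse = 0
                aps_since_trigger = 0
                n_sched += 1
    return (
        sp_t[:n_sp],
        sp_f[:n_sp],
        sp_e[:n_sp],
        sp_i[:n_sp],
        sp_held[:n_sp],
        pu_t[:n_sched],
        pu_trig[:n_sched],
        n_sp,
        n_done,
        aborted,
    )
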