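"""Indirect PRC estimation: OU stimulus synthesis and the weighted STA.

The indirect route estimates the PRC from the spike response to a weak,
exponentially correlated noise current

    tau_I dI/dt = -I + s * sqrt(2 tau_I) xi(t),

an Ornstein-Uhlenbeck process with stationary SD ``s`` and correlation time
``tau_I`` (4 ms here, much shorter than the firing period).  For every
inter-spike interval the current segment is rescaled onto a common phase
grid and the weighted spike-triggered average

    Z(phi) ~= sum_k alpha_k I_k(phi) / (2 s^2 tau_I),   alpha_k = <ISI>/ISI_k - 1

is formed: intervals shortened by favourable noise (alpha_k > 0) pull the
average toward the stimulus shapes that advance spiking, and the
normalization by the autocovariance area 2 s^2 tau_I converts the result to
phase shift per unit charge (1/pC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OUStimulus", "WSTAEstimate", "generate_ou_current", "wsta_prc"]


@dataclass(frozen=True)
class OUStimulus:
    """An exponentially filtered white-noise current trace.

    ``values`` includes the constant ``offset`` used to set the discharge
    rate; the fluctuating part (values - offset) has stationary mean 0,
    SD ``s`` and autocorrelation time ``tau_i``.
    """

    values: np.ndarray
    dt: float
    s: float
    tau_i: float
    offset: float = 0.0
    seed: int = 0

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    @property
    def fluctuation(self) -> np.ndarray:
        return self.values - self.offset


def generate_ou_current(
    s: float,
    tau_i: float = 4e-3,
    duration: float = 30.0,
    dt: float = 1.0 / 30000.0,
    offset: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> OUStimulus:
    """Exact-discretization OU current.

    The update I_{n+1} = I_n e^(-dt/tau) + s sqrt(1 - e^(-2 dt/tau)) N(0,1)
    samples the continuous process exactly at the grid points, so the
    stationary SD equals ``s`` for any dt; the grid is still required to
    resolve the correlation time (dt <= tau_i/10).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt > tau_i / 10.0:
        raise ValueError("dt must be <= tau_i/10 to resolve the correlation time")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration / dt))
    rho = np.exp(-dt / tau_i)
    if s == 0.0:
        vals = np.full(n, float(offset))
        return OUStimulus(vals, dt, 0.0, tau_i, offset,
                          seed if isinstance(seed, int) else -1)
    drive = s * np.sqrt(1.0 - rho * rho)
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x0 = s * rng.standard_normal()  # start in the stationary distribution
    # scipy.signal.lfilter would do, but the recurrence is clearer and fast enough
    acc = x0
    for i in range(n):
        acc = acc * rho + drive * eps[i]
        x[i] = acc
    return OUStimulus(x + offset, dt, float(s), float(tau_i), float(offset),
                      seed if isinstance(seed, int) else -1)


@dataclass(frozen=True)
class WSTAEstimate:
    """WSTA output curve on a uniform phase grid, 1/pC."""

    phi_grid: np.ndarray
    z: np.ndarray
    n_isi_used: int
    mean_isi: float

    def at(self, phi: float) -> float:
        return float(np.interp(phi, self.phi_grid, self.z))


def wsta_prc(
    stimulus: OUStimulus,
    train,
    grid_size: int = 100,
    mean_isi: float | None = None,
) -> WSTAEstimate:
    """Weighted spike-triggered average PRC from one stimulus realization.

    Each complete ISI inside the stimulus window contributes its
    mean-subtracted, phase-rescaled current segment weighted by
    alpha_k = <ISI>/ISI_k - 1; <ISI> is computed over the same ISIs unless
    supplied.  Only the fluctuating part of the stimulus enters (the DC
    offset sets the firing rate and would otherwise leak into the estimate).

    Notes
    -----
    Units: sum_k alpha_k I_k is pA; dividing by 2 s^2 tau_I (pA^2 s) gives
    1/(pA s) = 1/pC, directly comparable with the direct method.
    """
    t = np.asarray(train.spike_times if hasattr(train, "spike_times") else train,
                   dtype=float)
    t = t[(t >= 0.0) & (t <= stimulus.duration)]
    if t.size < 2:
        raise ValueError("need at least two spikes inside the stimulus window")
    isis = np.diff(t)
    if mean_isi is None:
        mean_isi = float(np.mean(isis))
    alphas = mean_isi / isis - 1.0

    grid = np.linspace(0.0, 1.0, grid_size)
    fluct = stimulus.fluctuation
    times = stimulus.times
    acc = np.zeros(grid_size)
    used = 0
    for k in range(isis.size):
        seg_t = t[k] + grid * isis[k]
        seg = np.interp(seg_t, times, fluct)
        seg = seg - seg.mean()
        acc += alphas[k] * seg
        used += 1
    # Average over intervals: each interval's expected contribution is already
    # Z(phi) * 2 s^2 tau_I, so the interval count normalizes out.
    z = acc / used / (2.0 * stimulus.s**2 * stimulus.tau_i)
    return WSTAEstimate(phi_grid=grid, z=z, n_isi_used=used, mean_isi=mean_isi)


def pooled_wsta(estimates) -> WSTAEstimate:
    """Pool WSTA curves from several stimulus realizations.

    Each curve is an average over its own intervals, so pooling with
    interval-count weights is equivalent to concatenating the interval sets
    (for equal rates) while letting each realization keep its own <ISI>.
    """
    ests = list(estimates)
    if not ests:
        raise ValueError("no estimates to pool")
    grid = ests[0].phi_grid
    w = np.array([e.n_isi_used for e in ests], dtype=float)
    z = sum(wi * e.z for wi, e in zip(w, ests)) / w.sum()
    m = float(np.average([e.mean_isi for e in ests], weights=w))
    return WSTAEstimate(phi_grid=grid, z=z, n_isi_used=int(w.sum()), mean_isi=m)
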