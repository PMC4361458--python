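"""Spike detection, inter-spike-interval statistics and the online rate estimator.

This module holds the low-level spike bookkeeping shared by every estimator in
the package: threshold-crossing spike detection on a voltage trace, ISI
statistics (mean, CV, rate) over a selectable subset of intervals, and the
exponentially weighted instantaneous-rate estimator

    F_k = (1/ISI_k) * (1 - exp(-ISI_k/tau)) + F_{k-1} * exp(-ISI_k/tau)

that the closed-loop frequency clamp consumes after every action potential.

Units are seconds, Hz, pA and pC throughout; conversion happens at the I/O
boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "VoltageTrace",
    "SpikeTrain",
    "ISIStats",
    "RateEstimator",
    "detect_spikes",
    "isi_stats",
    "perturbed_isi_indices",
]


@dataclass(frozen=True)
class VoltageTrace:
    """A uniformly sampled membrane-potential trace.

    Parameters
    ----------
    values : ndarray
        Membrane potential in mV.
    sample_rate : float
        Sampling rate in Hz (the recordings this emulates were acquired at
        30 kHz).
    t0 : float
        Time of the first sample, seconds.
    """

    values: np.ndarray
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("voltage trace must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise ValueError("voltage trace contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.values.size / self.sample_rate


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing action-potential peak times, in seconds."""

    spike_times: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", t)
        if t.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.spike_times.size)

    @property
    def isis(self) -> np.ndarray:
        """Inter-spike intervals ISI_k = t_{k+1} - t_k, seconds."""
        return np.diff(self.spike_times)

    def restricted(self, t_start: float, t_stop: float) -> "SpikeTrain":
        t = self.spike_times
        return SpikeTrain(t[(t >= t_start) & (t <= t_stop)], self.source_id)


@dataclass(frozen=True)
class ISIStats:
    """Summary of an inter-spike-interval distribution."""

    mean_isi: float  # <ISI>, seconds
    cv: float        # SD / mean, dimensionless
    n_isi: int

    @property
    def rate(self) -> float:
        """Mean firing rate 1/<ISI>, Hz."""
        return 1.0 / self.mean_isi


def detect_spikes(
    trace: VoltageTrace,
    threshold: float = -20.0,
    refractory: float = 1e-3,
) -> SpikeTrain:
    """Detect action potentials as positive threshold crossings.

    Each reported spike time is the local maximum of the suprathreshold
    interval that follows an upward crossing (the AP peak), quantized to the
    sample grid.  Crossings closer than ``refractory`` to the previous
    accepted peak are discarded, which prevents double counting a single AP.

    Returns an empty train (not an error) when the threshold is never
    crossed.
    """
    if refractory < 0:
        raise ValueError("refractory must be non-negative")
    v = trace.values
    if v.size == 0:
        raise ValueError("cannot detect spikes in an empty trace")
    above = v >= threshold
    # upward crossings: sample i-1 below, sample i at/above threshold
    ups = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        ups = np.concatenate([[0], ups])
    downs = np.flatnonzero(above[:-1] & ~above[1:]) + 1

    peaks = []
    last_peak_t = -np.inf
    dt = 1.0 / trace.sample_rate
    for i in ups:
        j = downs[np.searchsorted(downs, i, side="right"):][:1]
        stop = int(j[0]) if j.size else v.size
        k = i + int(np.argmax(v[i:stop]))
        t_peak = trace.t0 + k * dt
        if t_peak - last_peak_t >= refractory:
            peaks.append(t_peak)
            last_peak_t = t_peak
    return SpikeTrain(np.asarray(peaks), source_id="detected")


def isi_stats(train: SpikeTrain, exclude: Iterable[int] = ()) -> ISIStats:
    """Mean, CV and rate of the ISI distribution.

    ``exclude`` lists ISI indices (into ``train.isis``) left out of the
    statistics — typically every interval that contains a stimulation pulse
    and the interval immediately after it, so that <ISI> reflects the
    unperturbed firing period.
    """
    isis = train.isis
    mask = np.ones(isis.size, dtype=bool)
    excl = np.asarray(sorted(set(int(i) for i in exclude)), dtype=int)
    if excl.size:
        excl = excl[(excl >= 0) & (excl < isis.size)]
        mask[excl] = False
    used = isis[mask]
    if used.size < 1 or train.spike_times.size < 2:
        raise ValueError("need at least two spikes (one usable ISI) for statistics")
    mean = float(np.mean(used))
    cv = float(np.std(used) / mean)
    return ISIStats(mean_isi=mean, cv=cv, n_isi=int(used.size))


def perturbed_isi_indices(
    train: SpikeTrain, pulse_times: Sequence[float], pad_following: int = 1
) -> set:
    """Indices of ISIs that contain a pulse, plus the ``pad_following`` ISIs after each.

    Used to restrict <ISI> to unperturbed intervals: a pulse inside ISI_k
    perturbs ISI_k directly, and the controller hold window extends into the
    next interval.
    """
    t = train.spike_times
    out: set = set()
    for tp in np.asarray(pulse_times, dtype=float):
        j = int(np.searchsorted(t, tp)) - 1  # last spike before the pulse
        if 0 <= j < t.size - 1:
            for k in range(j, min(j + 1 + pad_following, t.size - 1)):
                out.add(k)
    return out


@dataclass
class RateEstimator:
    """Online instantaneous-firing-rate estimator, updated once per AP.

    The estimate is a convex combination of the latest inverse ISI and the
    previous estimate, with a weight set by the estimator time scale ``tau``
    (1 s in the experiments this emulates):

        F_k = (1/ISI_k) * (1 - exp(-ISI_k/tau)) + F_{k-1} * exp(-ISI_k/tau)

    ``f_hat`` is initialised to the clamp's target rate to suppress startup
    transients.
    """

    f_hat: float
    tau: float = 1.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.f_hat < 0:
            raise ValueError("initial rate estimate must be non-negative")

    def update(self, isi_k: float) -> float:
        """Consume one ISI (seconds); return and store the new estimate."""
        if isi_k <= 0:
            raise ValueError("isi_k must be positive")
        w = np.exp(-isi_k / self.tau)
        self.f_hat = (1.0 - w) / isi_k + self.f_hat * w
        return self.f_hat

    def copy(self) -> "RateEstimator":
        return replace(self)
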