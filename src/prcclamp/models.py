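"""Model/Results front end for PRC estimation.

The two estimation routes are exposed as model classes in the statsmodels
idiom: construct the model from data, call ``fit()``, get a results object
carrying the curve, its uncertainty and the shape diagnostics.

>>> model = DirectPRC(train, pulses)            # spike train + stimulus log
>>> res = model.fit(seed=1)
>>> res.peak_to_baseline().r, res.peak_location().tau_peak
>>> print(res.summary())

``WSTAPRC`` mirrors this for the indirect (weighted spike-triggered average)
route, and ``fit_rate_dependence`` summarizes how the peak-to-baseline ratio
of a family of results grows with firing rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .direct import Perturbation, RawPRC, corrected_direct_prc
from .metrics import (PeakBaselineResult, PeakLocation, SigmoidFit,
                      fit_sigmoid, peak_time, peak_to_baseline)
from .smoothing import SmoothedPRC, kernel_bandwidth, smooth, bootstrap_ci
from .spikes import SpikeTrain
from .wsta import OUStimulus, WSTAEstimate, pooled_wsta, wsta_prc

__all__ = ["DirectPRC", "WSTAPRC", "PRCResult", "fit_rate_dependence"]


@dataclass
class PRCResult:
    """Fitted PRC: smoothed curve, 68% CI, raw samples and diagnostics."""

    curve: SmoothedPRC
    raw: RawPRC | WSTAEstimate
    method: str
    mean_isi: float
    n_trials: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def phi_grid(self) -> np.ndarray:
        return self.curve.phi_grid

    @property
    def z(self) -> np.ndarray:
        return self.curve.z_smooth

    @property
    def firing_rate(self) -> float:
        return 1.0 / self.mean_isi

    def peak_to_baseline(self) -> PeakBaselineResult:
        return peak_to_baseline(self.curve)

    def peak_location(self) -> PeakLocation:
        return peak_time(self.curve, self.mean_isi)

    def summary(self) -> str:
        pb = self.peak_to_baseline()
        pk = self.peak_location()
        lines = [
            f"{'Phase response curve':^62}",
            "=" * 62,
            f"method:              {self.method}",
            f"firing rate:         {self.firing_rate:8.2f} Hz   "
            f"(<ISI> = {self.mean_isi*1e3:.2f} ms)",
            f"trials / samples:    {self.n_trials} / {self.curve.n_samples}",
            f"bandwidth h:         {self.curve.bandwidth:8.4f} (phase units)",
            f"peak-to-baseline r:  {pb.r:8.3f}   "
            f"(m_e = {pb.m_e:+.3f}, m_l = {pb.m_l:+.3f} 1/pC)",
            f"peak location:       phi = {pk.phi_peak:.3f},  "
            f"tau_peak = {pk.tau_peak*1e3:+.2f} ms",
        ]
        for k, v in self.diagnostics.items():
            lines.append(f"{k + ':':<21}{v}")
        lines.append("=" * 62)
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        d = {"phi": self.curve.phi_grid, "z": self.curve.z_smooth}
        if self.curve.ci68_lo is not None:
            d["ci68_lo"] = self.curve.ci68_lo
            d["ci68_hi"] = self.curve.ci68_hi
        return pd.DataFrame(d)

    def plot(self, ax=None, show_raw: bool = True, **kwargs):
        """Quick-look plot of the smoothed curve, CI band and raw samples."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.2))
        if show_raw and isinstance(self.raw, RawPRC):
            ax.plot(self.raw.phi, self.raw.z, ".", ms=2, alpha=0.25,
                    color="0.6", label="raw samples")
        if self.curve.ci68_lo is not None:
            ax.fill_between(self.phi_grid, self.curve.ci68_lo,
                            self.curve.ci68_hi, alpha=0.3, label="68% CI")
        ax.plot(self.phi_grid, self.z, lw=2, label=f"{self.method} PRC",
                **kwargs)
        ax.axhline(0.0, color="k", lw=0.5, ls="--")
        ax.set_xlabel(r"phase $\varphi$")
        ax.set_ylabel(r"$Z(\varphi)$  (1/pC)")
        ax.legend(frameon=False, fontsize=8)
        return ax


class DirectPRC:
    """Corrected direct-method PRC model.

    Parameters
    ----------
    train : SpikeTrain
        AP peak times of the session.
    pulses : sequence of Perturbation
        Stimulus log (onset, amplitude, duration per pulse).
    mean_isi : float, optional
        Override the unperturbed-ISI mean (computed from the data otherwise).
    t_start : float
        Discard pulses before this time (controller settling window).
    """

    def __init__(
        self,
        train: SpikeTrain,
        pulses: Sequence[Perturbation],
        mean_isi: float | None = None,
        t_start: float = 0.0,
    ):
        if t_start > 0.0:
            # drop the controller settling window from the spikes as well, so
            # <ISI> is not contaminated by the approach to the target rate
            # (keep a short margin so early pulses still have two preceding APs)
            train = train.restricted(t_start - 0.2, np.inf)
        self.train = train
        self.pulses = [p for p in pulses if p.t_pulse >= t_start]
        self.mean_isi = mean_isi
        if not self.pulses:
            raise ValueError("no pulses after t_start")

    @classmethod
    def from_session(cls, log, t_start: float = 5.0) -> "DirectPRC":
        """Build from a closed-loop :class:`~prcclamp.clamp.SessionLog`."""
        return cls(log.spike_train(), log.perturbations(), t_start=t_start)

    @classmethod
    def from_dataframes(cls, spikes: pd.DataFrame, stimuli: pd.DataFrame,
                        **kwargs) -> "DirectPRC":
        """Build from tidy frames: spikes(time_s), stimuli(t_pulse_s, amplitude_pA, duration_s)."""
        train = SpikeTrain(spikes["time_s"].to_numpy())
        pulses = [
            Perturbation(r["t_pulse_s"], r["amplitude_pA"], r["duration_s"])
            for _, r in stimuli.iterrows()
        ]
        return cls(train, pulses, **kwargs)

    def fit(
        self,
        bandwidth: float | None = None,
        bandwidth_method: str = "phase",
        grid_size: int = 201,
        n_boot: int = 1000,
        seed: int | np.random.Generator = 0,
    ) -> PRCResult:
        raw = corrected_direct_prc(self.train, self.pulses,
                                   mean_isi=self.mean_isi)
        phi, z = raw.phi, raw.z
        h = bandwidth if bandwidth is not None else kernel_bandwidth(
            phi, z, method=bandwidth_method)
        curve = smooth(phi, z, h, grid_size)
        lo, hi = bootstrap_ci(phi, z, h, grid_size, n_boot=n_boot, seed=seed)
        curve = SmoothedPRC(curve.phi_grid, curve.z_smooth, curve.bandwidth,
                            lo, hi, curve.n_samples)
        n2 = int(np.sum(raw.order == 2))
        return PRCResult(
            curve=curve, raw=raw, method="corrected-direct",
            mean_isi=raw.mean_isi, n_trials=raw.n_trials,
            diagnostics={
                "second-order samples": n2,
                "skipped trials": dict(raw.skip_log),
                "pulse charge (pC)": raw.charge,
            },
        )


class WSTAPRC:
    """Weighted spike-triggered average PRC model.

    Accepts one or more (stimulus, spike train) realizations; realizations
    are pooled with ISI-count weights.  Spike times are interpreted relative
    to each stimulus onset.
    """

    def __init__(self, stimuli, trains):
        if isinstance(stimuli, OUStimulus):
            stimuli, trains = [stimuli], [trains]
        if len(stimuli) != len(trains):
            raise ValueError("need one spike train per stimulus realization")
        self.pairs = list(zip(stimuli, trains))

    def fit(self, grid_size: int = 100) -> PRCResult:
        ests = [wsta_prc(s, tr, grid_size=grid_size) for s, tr in self.pairs]
        pooled = pooled_wsta(ests)
        # present through the common result type; WSTA has no bootstrap band here
        curve = SmoothedPRC(
            phi_grid=pooled.phi_grid, z_smooth=pooled.z,
            bandwidth=1.0 / grid_size, n_samples=pooled.n_isi_used,
        )
        return PRCResult(
            curve=curve, raw=pooled, method="wsta",
            mean_isi=pooled.mean_isi, n_trials=pooled.n_isi_used,
            diagnostics={"realizations": len(self.pairs)},
        )


def summarize_results(results: Sequence[PRCResult]) -> pd.DataFrame:
    """Tidy per-result summary (firing_rate_Hz, r, m_e, m_l, phi_peak, ...)."""
    rows = []
    for res in results:
        pb = res.peak_to_baseline()
        pk = res.peak_location()
        rows.append({
            "firing_rate_Hz": res.firing_rate,
            "r": pb.r, "m_e": pb.m_e, "m_l": pb.m_l,
            "phi_peak": pk.phi_peak, "tau_peak_ms": pk.tau_peak * 1e3,
            "n_trials": res.n_trials,
        })
    return pd.DataFrame(rows).sort_values("firing_rate_Hz").reset_index(drop=True)


def fit_rate_dependence(results: Sequence[PRCResult]) -> tuple[SigmoidFit, pd.DataFrame]:
    """Sigmoid fit of peak-to-baseline ratio vs firing rate across results."""
    table = summarize_results(results)
    fit = fit_sigmoid(table["firing_rate_Hz"], table["r"])
    return fit, table
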