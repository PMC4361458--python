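"""Scalar summaries of PRC shape.

Three summaries recur in rate-dependence analyses of tonically firing cells:

* the peak-to-baseline ratio r = |m_l - m_e| / (|m_l| + |m_e|), where m_e and
  m_l are the largest-|z| extrema of the early (phi in [0, 0.5]) and late
  (phi in [0.5, 1]) halves of the curve.  r = 0 for a flat curve, r = 1 when
  the two extrema have opposite signs (type-II-like);
* the sigmoidal fit r(F) ~ 1 / (1 + exp(-(F - a)/b)) describing how r grows
  with firing rate F;
* the peak location transformed to time before the next AP,
  tau_peak = (phi_peak - 1) * <ISI>  (<= 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .smoothing import SmoothedPRC

__all__ = [
    "PeakBaselineResult",
    "SigmoidFit",
    "PeakLocation",
    "peak_to_baseline",
    "fit_sigmoid",
    "peak_time",
]


@dataclass(frozen=True)
class PeakBaselineResult:
    m_e: float   # early-half extremum of largest |z|, 1/pC
    m_l: float   # late-half extremum of largest |z|, 1/pC
    r: float     # peak-to-baseline ratio in [0, 1]
    degenerate: bool = False  # True when the curve was identically zero


@dataclass(frozen=True)
class SigmoidFit:
    """Two-parameter logistic fit of r(F): midpoint a (Hz) and slope scale b (Hz)."""

    a: float
    b: float
    rss: float

    def predict(self, rates) -> np.ndarray:
        rates = np.asarray(rates, dtype=float)
        return 1.0 / (1.0 + np.exp(-(rates - self.a) / self.b))


@dataclass(frozen=True)
class PeakLocation:
    phi_peak: float
    tau_peak: float  # (phi_peak - 1) * <ISI>, seconds, <= 0 for phi_peak <= 1


def _largest_abs_extremum(z: np.ndarray) -> float:
    return float(z[np.argmax(np.abs(z))])


def peak_to_baseline(curve: SmoothedPRC | tuple) -> PeakBaselineResult:
    """Peak-to-baseline ratio of a PRC defined on [0, 1].

    phi = 0.5 belongs to both halves; when the extremum lies exactly there it
    contributes to both m_e and m_l (and r = 0 accordingly).  An identically
    zero curve has no defined ratio; it is flagged and reported as r = 0.
    """
    if isinstance(curve, SmoothedPRC):
        phi, z = curve.phi_grid, curve.z_smooth
    else:
        phi, z = (np.asarray(a, dtype=float) for a in curve)
    early = z[phi <= 0.5]
    late = z[phi >= 0.5]
    if early.size == 0 or late.size == 0:
        raise ValueError("curve must cover both halves of [0, 1]")
    m_e = _largest_abs_extremum(early)
    m_l = _largest_abs_extremum(late)
    denom = abs(m_l) + abs(m_e)
    if denom == 0.0:
        warnings.warn("curve is identically zero; peak-to-baseline undefined",
                      stacklevel=2)
        return PeakBaselineResult(m_e=0.0, m_l=0.0, r=0.0, degenerate=True)
    return PeakBaselineResult(m_e=m_e, m_l=m_l, r=abs(m_l - m_e) / denom)


def fit_sigmoid(rates, r_values) -> SigmoidFit:
    """Least-squares fit of r(F) = (1 + exp(-(F-a)/b))^-1.

    Deterministic multi-start: a coarse grid of (a, b) initial guesses is
    refined with trust-region least squares and the best solution returned.
    Requires >= 3 points spanning at least 20 Hz and non-degenerate r values.
    """
    F = np.asarray(rates, dtype=float)
    r = np.asarray(r_values, dtype=float)
    if F.size < 3:
        raise ValueError("need at least three (rate, r) points")
    if np.ptp(F) < 20.0:
        raise ValueError("rates must span at least 20 Hz")
    if np.ptp(r) < 1e-12:
        raise ValueError("degenerate input: all r values equal")

    def resid(p):
        a, b = p
        return 1.0 / (1.0 + np.exp(-(F - a) / b)) - r

    best = None
    a_grid = np.linspace(F.min(), F.max(), 7)
    for a0 in a_grid:
        for b0 in (5.0, 10.0, 20.0, 40.0, -20.0):
            sol = least_squares(resid, x0=[a0, b0], xtol=1e-15, ftol=1e-15,
                                gtol=1e-15, max_nfev=2000)
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0] - 1e-15:
                best = (rss, sol.x)
    rss, (a, b) = best
    return SigmoidFit(a=float(a), b=float(b), rss=rss)


def peak_time(curve: SmoothedPRC | tuple, mean_isi: float) -> PeakLocation:
    """Location of the PRC global maximum, in phase and in time before the next AP."""
    if isinstance(curve, SmoothedPRC):
        phi, z = curve.phi_grid, curve.z_smooth
    else:
        phi, z = (np.asarray(a, dtype=float) for a in curve)
    zmax = z.max()
    at_max = np.flatnonzero(z >= zmax - 1e-15 * max(1.0, abs(zmax)))
    if at_max.size > 1 and np.all(np.diff(at_max) == 1):
        warnings.warn("plateau maximum; using the plateau midpoint", stacklevel=2)
        phi_peak = float(0.5 * (phi[at_max[0]] + phi[at_max[-1]]))
    else:
        phi_peak = float(phi[int(at_max[0])] if at_max.size == 1
                         else phi[int(np.argmax(z))])
    return PeakLocation(phi_peak=phi_peak, tau_peak=(phi_peak - 1.0) * mean_isi)
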