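"""Corrected direct-method estimation of the phase response curve.

The direct method perturbs a tonically firing cell with brief charge-balanced
current pulses and measures the induced shift of the next action potential.
With the last AP before a pulse at t_j and the mean unperturbed interval
<ISI>, the pulse phase is phi = (t_pulse - t_j)/<ISI> and the first-order
sample is

    Z(phi) = (<ISI> - ISI_perturbed) / (<ISI> * Q),        ISI_perturbed = t_{j+1} - t_j

normalized by the injected charge Q so that different pulse amplitudes are
comparable; positive Z is a phase advance.  Because the next AP cannot
precede the pulse, Z(phi) <= (1 - phi)/Q: the estimate is censored near
phi = 1 (large advances make the AP fire *before* a late pulse, and the trial
is re-referenced to that AP at a small phi).  The censored mass is restored
by second-order samples referenced to the second AP before the pulse,
phi2 = (t_pulse - t_{j-1})/<ISI>:

    Z2(phi2) = (<ISI> - ISI_perturbed-1) / (<ISI> * Q),    ISI_perturbed-1 = t_j - t_{j-1}

Samples with phi2 in [1 - eps, 1] are exactly the trials in which the AP
anticipated a pulse scheduled late in the cycle; plotted at phi2 they
repopulate the region just below phi = 1 above the first-order bound, and
obey (1 - phi2)/Q <= Z2 <= (2 - phi2)/Q.  The joined set Z(phi) u Z2(phi2)
restricted to [0, 1] is the corrected direct estimate.

Finite pulses are not delta functions: while the charge is being delivered
the oscillator keeps moving (by the pulse width in time, plus the advance
the pulse itself produces), so a sample attributed to the pulse *onset*
phase reports the response averaged over [phi, phi + dphi].  By default each
first-order sample is therefore plotted at the mid-perturbation phase

    phi_mid = (t_pulse + T_pulse/2 - t_j)/<ISI> + Q * Z_pilot(phi)/2

(Z_pilot a first-pass smooth), which cancels the O(Q) abscissa bias without
correlating abscissa and ordinate noise; the onset phase is kept on every
sample because the censoring bound Z <= (1 - phi)/Q is a statement about
onset phases.  ``phase_convention="onset"`` restores the uncorrected plain
assignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spikes import SpikeTrain, isi_stats, perturbed_isi_indices

__all__ = [
    "Perturbation",
    "PRCSample",
    "RawPRC",
    "assign_phase",
    "first_order_sample",
    "second_order_sample",
    "corrected_direct_prc",
    "PHASE_TOLERANCE",
]

#: tolerance eps for phases slightly outside their theoretical range
#: (AP jitter lets phi exceed 1 and phi2 exceed its band by a few percent)
PHASE_TOLERANCE = 0.1


@dataclass(frozen=True)
class Perturbation:
    """One brief current pulse: onset time (s), amplitude (pA), duration (s)."""

    t_pulse: float
    amplitude: float
    duration: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")

    @property
    def charge(self) -> float:
        """Injected charge Q = I_pulse * T_pulse in pC (pA x s = pC; 100 pA x 0.5 ms = 0.05 pC)."""
        return self.amplitude * self.duration


@dataclass(frozen=True)
class PRCSample:
    """One (phase, normalized phase shift) pair from a single trial.

    ``phi`` is the plotting phase in [0, 1]; ``z`` the shift per unit charge
    (1/pC); ``order`` is 1 for samples referenced to the AP immediately
    before the pulse and 2 for the censoring-completion samples referenced to
    the second AP back (for those, ``phi`` is phi2 itself, which lies just
    below 1).  ``phi_onset`` is the uncorrected onset phase (phi or phi2 as
    the coordinate of the censoring bounds).
    """

    phi: float
    z: float
    order: int
    trial_id: int = -1
    phi_onset: float = float("nan")


@dataclass
class RawPRC:
    """The joined sample set of a corrected direct-method session."""

    samples: list
    mean_isi: float
    charge: float           # modal pulse charge, pC
    n_trials: int           # distinct pulses that produced >= 1 kept sample
    skip_log: Counter = field(default_factory=Counter)

    @property
    def firing_rate(self) -> float:
        return 1.0 / self.mean_isi

    @property
    def phi(self) -> np.ndarray:
        return np.array([s.phi for s in self.samples])

    @property
    def z(self) -> np.ndarray:
        return np.array([s.z for s in self.samples])

    @property
    def order(self) -> np.ndarray:
        return np.array([s.order for s in self.samples], dtype=int)

    @property
    def phi_onset(self) -> np.ndarray:
        """Onset phases (the coordinate in which the censoring bounds hold)."""
        return np.array([
            s.phi if np.isnan(s.phi_onset) else s.phi_onset for s in self.samples
        ])


def _apply_midpoint_phases(samples: list, mean_isi: float, pulses: list) -> None:
    """Re-plot first-order samples at the mid-perturbation phase (in place).

    The abscissa shift is half the pulse width plus half the *pilot-smoothed*
    response at the onset phase (shifting by each trial's own noisy shift
    would sort the noise by sign near the domain boundaries and bias the
    curve there; the pilot estimate carries no such correlation).
    """
    from .smoothing import kernel_bandwidth, smooth

    first = [k for k, s in enumerate(samples) if s.order == 1]
    if len(first) < 2:
        return
    phi = np.array([samples[k].phi for k in first])
    z = np.array([samples[k].z for k in first])
    try:
        h = kernel_bandwidth(phi, z)
    except ValueError:
        return
    pilot = smooth(phi, z, h)
    for k, p0 in zip(first, phi):
        s = samples[k]
        pulse = pulses[s.trial_id]
        shift = 0.5 * pulse.duration / mean_isi + 0.5 * pulse.charge * pilot.at(p0)
        samples[k] = PRCSample(phi=max(p0 + shift, 0.0), z=s.z, order=1,
                               trial_id=s.trial_id, phi_onset=p0)


def assign_phase(train: SpikeTrain, pulse: Perturbation, mean_isi: float):
    """Locate a pulse within the spike train.

    Returns ``(phi, isi_perturbed, isi_perturbed_minus_1)`` where phi is
    relative to the last AP before the pulse.  Raises ``ValueError`` when the
    pulse does not fall strictly between the second spike and the last spike
    (the caller logs and skips such trials).
    """
    t = train.spike_times
    # side="right": a pulse exactly at an AP peak belongs to the cycle that
    # starts there (phase 0)
    j = int(np.searchsorted(t, pulse.t_pulse, side="right")) - 1
    if j < 1:
        raise ValueError("pulse before second spike")
    if j >= t.size - 1:
        raise ValueError("pulse after last spike")
    tau = pulse.t_pulse - t[j]
    phi = tau / mean_isi
    isi_perturbed = t[j + 1] - t[j]
    isi_prev = t[j] - t[j - 1]
    return phi, isi_perturbed, isi_prev


def first_order_sample(
    phi: float, isi_perturbed: float, mean_isi: float, charge: float,
    trial_id: int = -1, phi_plot: float | None = None,
) -> PRCSample:
    """Traditional direct estimate for one trial: Z = (<ISI> - ISI_pert)/(<ISI> Q).

    ``phi`` is the onset phase; ``phi_plot`` (default: same) is the plotting
    abscissa, e.g. the mid-perturbation phase.
    """
    if charge <= 0:
        raise ValueError("charge must be positive")
    z = (mean_isi - isi_perturbed) / (mean_isi * charge)
    return PRCSample(phi=phi if phi_plot is None else phi_plot, z=z, order=1,
                     trial_id=trial_id, phi_onset=phi)


def second_order_sample(
    phi2: float, isi_perturbed_minus_1: float, mean_isi: float, charge: float,
    trial_id: int = -1, eps: float = PHASE_TOLERANCE,
) -> PRCSample:
    """Second-order (censoring-completion) sample: Z2 = (<ISI> - ISI_pert-1)/(<ISI> Q).

    Only meaningful for phi2 in [1 - eps, 2 + eps]; raises ``ValueError``
    outside that band.  The sample is stored at plotting phase phi2 (kept in
    the joined set only when phi2 <= 1, i.e. where it completes the censored
    region of the first-order estimate).
    """
    if charge <= 0:
        raise ValueError("charge must be positive")
    if not (1.0 - eps <= phi2 <= 2.0 + eps):
        raise ValueError("phi2 outside [1-eps, 2+eps]")
    z = (mean_isi - isi_perturbed_minus_1) / (mean_isi * charge)
    return PRCSample(phi=phi2, z=z, order=2, trial_id=trial_id, phi_onset=phi2)


def corrected_direct_prc(
    train: SpikeTrain,
    pulses: Sequence[Perturbation],
    mean_isi: float | None = None,
    eps: float = PHASE_TOLERANCE,
    phase_convention: str = "midpoint",
    spike_overlap_window: float | None = None,
) -> RawPRC:
    """Build the joined first/second-order sample set from one session.

    <ISI> is computed over unperturbed intervals only (every ISI containing a
    pulse and the one after it are excluded) unless ``mean_isi`` is given.
    Pulses that cannot be phased (too early/late, out-of-band phases, or
    overlapping an AP peak) are counted in ``skip_log`` by reason.  A pulse
    whose onset falls within ``spike_overlap_window`` of an AP peak has an
    ambiguous phase attribution and is discarded; the default window is the
    pulse's own duration (pass 0 to keep every pulse).

    ``phase_convention="midpoint"`` (default) plots first-order samples at
    the mid-perturbation phase (onset + half pulse width + half the
    pilot-smoothed response), cancelling the O(Q) finite-pulse abscissa
    bias; ``"onset"`` is the plain assignment.  Onset phases are retained on
    every sample either way.
    """
    pulses = list(pulses)
    if not pulses:
        raise ValueError("no pulses supplied")
    if phase_convention not in ("midpoint", "onset"):
        raise ValueError(f"unknown phase_convention {phase_convention!r}")

    if mean_isi is None:
        excl = perturbed_isi_indices(train, [p.t_pulse for p in pulses])
        mean_isi = isi_stats(train, exclude=excl).mean_isi

    charges = [p.charge for p in pulses]
    modal_charge = Counter(np.round(charges, 12)).most_common(1)[0][0]

    samples: list = []
    skip = Counter()
    contributing: set = set()
    spike_t = train.spike_times
    for i, p in enumerate(pulses):
        if p.charge <= 0:
            skip["zero_charge"] += 1
            continue
        window = p.duration if spike_overlap_window is None else spike_overlap_window
        if window > 0.0:
            k = int(np.searchsorted(spike_t, p.t_pulse))
            near = []
            if k < spike_t.size:
                near.append(abs(spike_t[k] - p.t_pulse))
            if k > 0:
                near.append(abs(spike_t[k - 1] - p.t_pulse))
            if near and min(near) <= window:
                skip["overlaps_spike"] += 1
                continue
        try:
            phi, isi_pert, isi_prev = assign_phase(train, p, mean_isi)
        except ValueError as e:
            skip[str(e).replace(" ", "_")] += 1
            continue

        kept = False
        if phi <= 1.0:
            samples.append(first_order_sample(phi, isi_pert, mean_isi, p.charge, i))
            kept = True
        elif phi <= 1.0 + eps:
            skip["phi_in_(1,1+eps]"] += 1  # valid but outside the joined domain
        else:
            skip["phi_above_1+eps"] += 1

        phi2 = phi + isi_prev / mean_isi
        if 1.0 - eps <= phi2 <= 1.0:
            samples.append(
                second_order_sample(phi2, isi_prev, mean_isi, p.charge, i, eps=eps)
            )
            kept = True
        if kept:
            contributing.add(i)

    if not samples:
        raise ValueError(f"no valid pulses (skips: {dict(skip)})")

    if phase_convention == "midpoint":
        _apply_midpoint_phases(samples, mean_isi, pulses)

    return RawPRC(
        samples=samples,
        mean_isi=float(mean_isi),
        charge=float(modal_charge),
        n_trials=len(contributing),
        skip_log=skip,
    )
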