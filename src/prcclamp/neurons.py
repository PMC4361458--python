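"""Synthetic neurons with known ground truth.

Two surrogate tonically firing cells drive every validation in this package:

* ``PhaseNeuron`` — a phase oscillator with a *prescribed* infinitesimal PRC,

      dphi/dt = f(I_dc) + z_true(phi) * I_perturb(t) + jitter,

  spiking and resetting at phi = 1.  Because z_true is an input, every
  estimator in the package can be validated by recovering it.  ``jitter_sd``
  is the per-cycle phase diffusion (in cycles), which equals the ISI CV to
  first order, emulating the 5-10% CV of tonically firing Purkinje cells.

* ``ConductanceNeuron`` — a small Wang-Buzsaki-style single compartment with
  an intrinsic depolarizing drive so it fires spontaneously (~30 Hz at zero
  external current) and speeds up monotonically with injected current.
  Spiking variability can come from an additive white-noise current or
  from channel noise: the potassium gate's population fluctuation is
  represented by the diffusion approximation — a sum of N-1
  Ornstein-Uhlenbeck processes whose (tau_i, sigma_i) derive from the
  eigendecomposition of the gate's N-state kinetic scheme, matched to the
  open-fraction autocovariance for the chosen channel count.

The module also provides the exact Markov channel simulator used as the
oracle for the diffusion approximation, and the state-save replay PRC
protocol (deliver one pulse per trial at i/N of a reference ISI, restarting
from a saved model state each time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _kernels as K
from .direct import Perturbation, PRCSample, RawPRC
from .spikes import SpikeTrain, VoltageTrace

__all__ = [
    "PhaseNeuronConfig",
    "PhaseNeuron",
    "ConductanceNeuron",
    "KineticScheme",
    "DiffusionNoiseSpec",
    "diffusion_coefficients",
    "exact_markov_simulation",
    "replay_prc",
    "two_state_scheme",
    "potassium_chain_scheme",
    "potassium_chain_at_voltage",
    "z_flat",
    "z_cos_peaked",
    "z_late_peaked",
    "rate_interpolating_z",
    "PRESETS",
]

_ZTABLE_SIZE = 513


# ---------------------------------------------------------------------------
# ground-truth PRC shapes
# ---------------------------------------------------------------------------

def z_flat(z0: float = 1.0) -> Callable[[np.ndarray], np.ndarray]:
    """Phase-independent PRC (the low-rate, 'perfect integrator' phenotype)."""
    return lambda phi: np.full_like(np.asarray(phi, dtype=float), z0)


def z_cos_peaked(z0: float = 1.0) -> Callable[[np.ndarray], np.ndarray]:
    """Z0 * (1 - cos 2 pi phi): smooth, zero at the AP, peaked mid-cycle."""
    return lambda phi: z0 * (1.0 - np.cos(2.0 * np.pi * np.asarray(phi, dtype=float)))


def z_late_peaked(z0: float = 1.0, phi_peak: float = 0.75,
                  early_dip: float = 0.3) -> Callable[[np.ndarray], np.ndarray]:
    """Biphasic, late-peaked PRC (the high-rate phenotype).

    A narrow positive lobe at ``phi_peak`` plus a shallow negative early
    lobe, giving opposite-signed half-curve extrema (peak-to-baseline -> 1).
    The default peak at phi = 0.75 corresponds to ~5 ms before the next AP
    at 50 Hz, in the physiological range for fast tonically firing cells.
    """
    def z(phi):
        phi = np.asarray(phi, dtype=float)
        late = np.exp(-0.5 * ((phi - phi_peak) / 0.10) ** 2)
        early = np.exp(-0.5 * ((phi - 0.20) / 0.15) ** 2)
        return z0 * (late - early_dip * early)
    return z


def rate_interpolating_z(rate_hz: float, z0: float = 1.0,
                         a: float = 47.6, b: float = 21.7):
    """Flat-to-late-peaked PRC interpolated by a logistic weight in rate.

    Emulates the empirical phenotype family: flat near 20 Hz, biphasic and
    late-peaked near 100+ Hz, with the transition midpoint/scale of the
    population sigmoid.
    """
    w = 1.0 / (1.0 + np.exp(-(rate_hz - a) / b))
    flat = z_flat(z0)
    peaked = z_late_peaked(z0 * 2.0)
    return lambda phi: (1.0 - w) * flat(phi) + w * peaked(phi)


def _z_table(z_fn: Callable, size: int = _ZTABLE_SIZE) -> np.ndarray:
    return np.asarray(z_fn(np.linspace(0.0, 1.0, size)), dtype=float)


# ---------------------------------------------------------------------------
# phase-oscillator neuron
# ---------------------------------------------------------------------------


@dataclass
class PhaseNeuronConfig:
    """Configuration of the known-PRC phase oscillator.

    ``rate_at_rest`` and ``rate_slope`` define the monotone holding-current
    -> intrinsic-rate map f(I) = max(rate_at_rest + rate_slope * I, 0),
    mirroring a cell that fires ~30 Hz spontaneously and spans 20-150 Hz
    over the -200..1000 pA holding range.  ``z_true`` is the ground-truth
    PRC in 1/pC.  ``jitter_sd`` (cycles per cycle) sets the ISI CV.
    """

    z_true: Callable = field(default_factory=lambda: z_cos_peaked(1.0))
    rate_at_rest: float = 30.0       # Hz at zero holding current
    rate_slope: float = 0.1          # Hz / pA
    jitter_sd: float = 0.07
    jitter_mode: str = "cycle"       # "cycle": ISI_k = (1+xi_k)/f, CV = jitter_sd
    dt: float = 1.0 / 30000.0        # "diffusion": per-step white phase noise
    seed: int = 0

    def __post_init__(self):
        if self.jitter_mode not in ("cycle", "diffusion"):
            raise ValueError("jitter_mode must be 'cycle' or 'diffusion'")

    def base_rate(self, i_pa: float) -> float:
        return max(self.rate_at_rest + self.rate_slope * i_pa, 0.0)


class PhaseNeuron:
    """Stateful phase-oscillator simulator (see module docstring).

    The internal state is (phi, rng cursor); ``get_state``/``set_state``
    snapshot it exactly, so a restored neuron replays bit-identically.
    """

    def __init__(self, config: PhaseNeuronConfig | None = None, **kwargs):
        self.config = config or PhaseNeuronConfig(**kwargs)
        self.z_table = _z_table(self.config.z_true)
        self.phi = 0.0
        self.t = 0.0
        self._rng_cursor = 0  # per-advance sub-seed; part of the state

    # -- state snapshot -----------------------------------------------------
    def get_state(self):
        return (self.phi, self.t, self._rng_cursor)

    def set_state(self, state):
        self.phi, self.t, self._rng_cursor = state

    # -- simulation ---------------------------------------------------------
    def _subseed(self) -> int:
        s = (self.config.seed * 1_000_003 + self._rng_cursor) % (2**31 - 1)
        self._rng_cursor += 1
        return int(s)

    def advance(
        self,
        duration: float,
        i_dc: float = 0.0,
        i_fluct: np.ndarray | None = None,
        record_phase: bool = False,
    ):
        """Integrate for ``duration`` seconds; returns absolute spike times.

        ``i_fluct`` (pA, per sample) enters through z_true; ``i_dc`` through
        the rate map.  When ``record_phase`` is set the per-sample phase
        trace is returned as well.
        """
        cfg = self.config
        if cfg.base_rate(i_dc) <= 0 and (i_fluct is None or not np.any(i_fluct)):
            raise ValueError("neuron is silent at this holding current (f(I) <= 0)")
        n_steps = int(round(duration / cfg.dt))
        fl = (np.zeros(0) if i_fluct is None
              else np.ascontiguousarray(i_fluct, dtype=float))
        spikes, phi_end, phases = K.phase_free_run(
            self.phi, n_steps, cfg.dt, cfg.rate_at_rest, cfg.rate_slope,
            float(i_dc), fl, self.z_table,
            float(cfg.jitter_sd), 0 if cfg.jitter_mode == "cycle" else 1,
            self._subseed(), 1 if record_phase else 0,
        )
        spikes = spikes + self.t
        self.phi = float(phi_end)
        self.t += n_steps * cfg.dt
        if record_phase:
            return spikes, phases
        return spikes

    def run(
        self,
        duration: float,
        i_dc: float = 0.0,
        i_fluct: np.ndarray | None = None,
        render_voltage: bool = False,
    ):
        """Run and return (SpikeTrain, VoltageTrace|None) for the window."""
        t0 = self.t
        if render_voltage:
            spikes, phases = self.advance(duration, i_dc, i_fluct, record_phase=True)
            v = render_phase_voltage(phases, spikes - t0, self.config.dt)
            trace = VoltageTrace(v, 1.0 / self.config.dt, t0=t0)
        else:
            spikes = self.advance(duration, i_dc, i_fluct)
            trace = None
        return SpikeTrain(spikes, source_id="phase"), trace


def render_phase_voltage(phases: np.ndarray, spike_times: np.ndarray,
                         dt: float) -> np.ndarray:
    """Render a plausible membrane potential from a phase trace.

    Subthreshold ramp from -65 to -50 mV across the cycle, with a one-sample
    +30 mV AP peak at each spike followed by a -72 mV afterhyperpolarization
    sample.  Good enough to exercise threshold-crossing detection; not a
    biophysical waveform.
    """
    v = -65.0 + 15.0 * phases
    n = v.size
    for ts in spike_times:
        k = int(round(ts / dt))
        if 0 <= k < n:
            v[k] = 30.0
            if k + 1 < n:
                v[k + 1] = -72.0
    return v


# ---------------------------------------------------------------------------
# kinetic schemes and the channel-noise diffusion approximation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticScheme:
    """An N-state Markov channel scheme.

    ``rates[i, j]`` is the transition rate (1/s) from state i to state j
    (off-diagonal; the diagonal is ignored and rebuilt as -row sum).
    ``open_states`` lists the conducting states.
    """

    rates: np.ndarray
    open_states: tuple
    name: str = ""

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", r)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("rates must be a square matrix")
        off = r - np.diag(np.diag(r))
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        if len(self.open_states) == 0:
            raise ValueError("open_states must be non-empty")

    @property
    def n_states(self) -> int:
        return self.rates.shape[0]

    def generator(self) -> np.ndarray:
        """Generator matrix G: G[i,j] = rate i->j, G[i,i] = -sum of row."""
        g = self.rates.copy()
        np.fill_diagonal(g, 0.0)
        np.fill_diagonal(g, -g.sum(axis=1))
        return g

    def stationary(self) -> np.ndarray:
        g = self.generator()
        w, vl = np.linalg.eig(g.T)
        k = int(np.argmin(np.abs(w)))
        pi = np.real(vl[:, k])
        pi = pi / pi.sum()
        if np.any(pi < -1e-9):
            raise ValueError("scheme has no valid stationary distribution")
        return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


@dataclass(frozen=True)
class DiffusionNoiseSpec:
    """N-1 OU components (tau_i seconds, sigma_i open-fraction units)."""

    taus: np.ndarray
    sigmas: np.ndarray

    def autocovariance(self, lags) -> np.ndarray:
        lags = np.abs(np.asarray(lags, dtype=float))
        return np.sum(
            self.sigmas[:, None] ** 2 * np.exp(-lags[None, :] / self.taus[:, None]),
            axis=0,
        )


def two_state_scheme(alpha: float, beta: float) -> KineticScheme:
    """closed <-> open with opening rate alpha and closing rate beta (1/s)."""
    return KineticScheme(np.array([[0.0, alpha], [beta, 0.0]]),
                         open_states=(1,), name="two_state")


def potassium_chain_scheme(alpha: float, beta: float,
                           n_subunits: int = 4) -> KineticScheme:
    """Linear chain for a channel of identical two-state subunits.

    State i = number of open subunits; i -> i+1 at (n-i) alpha and
    i -> i-1 at i beta; only the fully open state conducts (HH n^4-type
    potassium channel at a frozen voltage).
    """
    n = n_subunits + 1
    r = np.zeros((n, n))
    for i in range(n - 1):
        r[i, i + 1] = (n_subunits - i) * alpha
        r[i + 1, i] = (i + 1) * beta
    return KineticScheme(r, open_states=(n_subunits,), name=f"chain{n_subunits}")


def potassium_chain_at_voltage(v_mv: float = -50.0,
                               n_subunits: int = 4) -> KineticScheme:
    """Potassium-gate chain scheme frozen at a membrane voltage.

    Uses the conductance surrogate's n-gate rates (including its temperature
    factor) evaluated at ``v_mv`` — the quasi-static operating point for the
    channel-noise diffusion approximation, typically the limit-cycle mean
    voltage.
    """
    am, bm, ah, bh, an, bn = K._wb_rates(float(v_mv))
    phi_gate = 5.0
    alpha = an * phi_gate * 1e3  # 1/ms -> 1/s
    beta = bn * phi_gate * 1e3
    return potassium_chain_scheme(alpha, beta, n_subunits)


def diffusion_coefficients(scheme: KineticScheme, n_channels: int) -> DiffusionNoiseSpec:
    """(tau_i, sigma_i) pairs matching the open-fraction autocovariance.

    The stationary autocovariance of a single channel's open indicator is a
    mixture of N-1 exponentials whose time constants are -1/lambda_i for the
    nonzero eigenvalues of the generator and whose amplitudes come from the
    spectral decomposition; for ``n_channels`` independent channels the
    amplitudes scale as 1/n.  The returned OU sum reproduces that
    autocovariance exactly (for reversible schemes, where the modes are real).
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    g = scheme.generator()
    n = scheme.n_states
    w, r = np.linalg.eig(g.T)  # columns of r: left eigenvectors of P-dynamics
    # work with the generator acting on distributions: d pi/dt = pi G
    # use G directly: right eigendecomposition of G
    w, R = np.linalg.eig(g)
    order = np.argsort(np.abs(w))
    if np.sum(np.abs(w) < 1e-9 * max(1.0, np.abs(w).max())) != 1:
        raise ValueError("scheme is not irreducible at this voltage")
    L = np.linalg.inv(R)
    pi = scheme.stationary()
    f = np.zeros(n)
    f[list(scheme.open_states)] = 1.0
    taus, amps = [], []
    for j in range(n):
        lam = w[j]
        if np.abs(lam) < 1e-9 * max(1.0, np.abs(w).max()):
            continue
        if np.abs(np.imag(lam)) > 1e-9 * np.abs(lam):
            raise ValueError(
                "complex relaxation modes (non-reversible scheme); the OU "
                "diffusion approximation needs real modes"
            )
        # C(t) = sum_j e^{lam_j t} [ (pi*f) . R_j ] [ L_j . f ]
        c = np.real(np.dot(pi * f, R[:, j]) * np.dot(L[j, :], f))
        if c < -1e-10 * max(1.0, abs(c)):
            warnings.warn("negative spectral amplitude clipped to zero", stacklevel=2)
            c = 0.0
        taus.append(float(-1.0 / np.real(lam)))
        amps.append(max(c, 0.0))
    taus = np.asarray(taus)
    amps = np.asarray(amps)
    sigmas = np.sqrt(amps / n_channels)
    return DiffusionNoiseSpec(taus=taus, sigmas=sigmas)


def exact_markov_simulation(
    scheme: KineticScheme,
    n_channels: int,
    duration: float,
    dt: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Exact (multinomial) population simulation; returns the open-fraction trace.

    Per step, the channels in each state redistribute according to the
    one-step transition probabilities rate*dt; requires dt * max total exit
    rate <= 0.1 so those linearized probabilities are valid.
    """
    g = scheme.generator()
    exit_rates = -np.diag(g)
    if dt * exit_rates.max() > 0.1:
        raise ValueError("dt too coarse: dt * max exit rate must be <= 0.1")
    if n_channels > 10_000:
        raise ValueError("exact simulation is intended for <= 1e4 channels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = scheme.n_states
    P = g * dt
    np.fill_diagonal(P, 0.0)
    stay = 1.0 - P.sum(axis=1)
    probs = P + np.diag(stay)
    pi = scheme.stationary()
    counts = rng.multinomial(n_channels, pi)
    n_steps = int(round(duration / dt))
    f_open = np.zeros(n_steps)
    open_idx = np.asarray(scheme.open_states, dtype=int)
    for k in range(n_steps):
        new = np.zeros(n, dtype=np.int64)
        for i in range(n):
            if counts[i] > 0:
                new += rng.multinomial(counts[i], probs[i])
        counts = new
        f_open[k] = counts[open_idx].sum() / n_channels
    return f_open


# ---------------------------------------------------------------------------
# conductance-based surrogate
# ---------------------------------------------------------------------------


class ConductanceNeuron:
    """Wang-Buzsaki-style tonically firing single compartment.

    Parameters
    ----------
    area : float
        Membrane area in cm^2; sets how many pA produce one uA/cm^2.
    i_intrinsic : float
        Constant depolarizing drive (pA) giving spontaneous ~30 Hz firing.
    noise_current_sd : float
        White-noise current scale, pA*sqrt(s) (the injected
        current is i_intrinsic + I_ext + sd * xi(t) with <xi(t)xi(t')> =
        delta(t - t')).
    channel_noise : (KineticScheme, n_channels) or None
        When given, the potassium conductance fluctuates as
        gK (n^4 + sum eta_i) with OU coefficients from
        ``diffusion_coefficients`` evaluated on the supplied scheme.
    """

    V_THRESH = 0.0     # mV, online spike threshold
    REFRACTORY = 2e-3  # s

    def __init__(
        self,
        area: float = 2.0e-4,
        i_intrinsic: float = 150.0,
        noise_current_sd: float = 0.0,
        channel_noise: tuple | None = None,
        dt: float = 25e-6,
        seed: int = 0,
    ):
        self.area = float(area)
        self.i_intrinsic = float(i_intrinsic)
        self.noise_current_sd = float(noise_current_sd)
        self.dt = float(dt)
        self.seed = int(seed)
        if channel_noise is not None:
            scheme, n_ch = channel_noise
            spec = diffusion_coefficients(scheme, n_ch)
            self.eta_taus = spec.taus
            self.eta_sigmas = spec.sigmas
        else:
            self.eta_taus = np.zeros(0)
            self.eta_sigmas = np.zeros(0)
        self.state = np.array([-64.0, 0.78, 0.09])  # v, h, n near rest
        self.eta = np.zeros(self.eta_taus.size)
        self.t = 0.0
        self._rng_cursor = 0

    def get_state(self):
        return (self.state.copy(), self.eta.copy(), self.t, self._rng_cursor)

    def set_state(self, state):
        s, e, t, c = state
        self.state = s.copy()
        self.eta = e.copy()
        self.t = t
        self._rng_cursor = c

    def _subseed(self) -> int:
        s = (self.seed * 1_000_003 + self._rng_cursor) % (2**31 - 1)
        self._rng_cursor += 1
        return int(s)

    def advance(self, duration: float, i_ext=0.0, record_voltage: bool = False):
        """Integrate for ``duration`` s; i_ext is a scalar or per-sample pA array.

        Returns absolute spike times (and the voltage trace when requested).
        """
        n_steps = int(round(duration / self.dt))
        if np.isscalar(i_ext):
            ext = np.array([float(i_ext)])
        else:
            ext = np.ascontiguousarray(i_ext, dtype=float)
            if ext.size != n_steps:
                raise ValueError("i_ext array must have one sample per step")
        spikes, st, eta, vtr = K.wb_free_run(
            self.state, n_steps, self.dt, self.i_intrinsic, ext, self.area,
            self.noise_current_sd, self.eta_taus, self.eta_sigmas, self.eta,
            self._subseed(), 1 if record_voltage else 0,
            self.V_THRESH, self.REFRACTORY,
        )
        if not np.all(np.isfinite(st)):
            raise RuntimeError("numerical blow-up in conductance surrogate "
                               f"(state={st}); reduce dt or current")
        spikes = spikes + self.t
        self.state = st
        self.eta = eta
        self.t += n_steps * self.dt
        if record_voltage:
            return spikes, VoltageTrace(vtr, 1.0 / self.dt, t0=self.t - n_steps * self.dt)
        return spikes

    def run(self, duration: float, i_ext=0.0, render_voltage: bool = False):
        if render_voltage:
            spikes, trace = self.advance(duration, i_ext, record_voltage=True)
        else:
            spikes = self.advance(duration, i_ext)
            trace = None
        return SpikeTrain(spikes, source_id="conductance"), trace


# ---------------------------------------------------------------------------
# state-save replay PRC protocol
# ---------------------------------------------------------------------------


def replay_prc(
    neuron,
    pulse_amplitude: float = 100.0,
    pulse_duration: float = 0.5e-3,
    n_trials: int = 50,
    target_isi: float | None = None,
    isi_tol: float = 0.05,
    settle_time: float = 1.0,
    search_time: float = 5.0,
    i_ext: float = 0.0,
) -> RawPRC:
    """PRC by state-save replay of a single reference inter-spike interval.

    After ``settle_time`` of free running, an unperturbed ISI [t0, t1] is
    located (matching ``target_isi`` within a relative ``isi_tol`` when one
    is requested, else the first complete ISI).  The model state is saved at
    t0 - 5 ms; each of ``n_trials`` trials restores it, delivers one pulse at
    t_p^i = t0 + i (t1 - t0)/N, and simulates to t1 + 10 ms.  The perturbed
    time of the AP ending the interval gives a first-order PRC sample at
    phi = (t_p - t0)/(t1 - t0).

    ``neuron`` must expose ``advance(duration, i_ext=...)`` returning spike
    times, and exact ``get_state``/``set_state``.
    """
    pre = 5e-3
    post = 10e-3

    def _adv(duration: float, pulse: np.ndarray | None = None):
        # the phase oscillator couples pulses through z_true and DC through
        # its rate map; the conductance model sums both into one current
        if isinstance(neuron, PhaseNeuron):
            return neuron.advance(duration, i_dc=i_ext, i_fluct=pulse)
        cur = i_ext if pulse is None else pulse + i_ext
        return neuron.advance(duration, cur)

    if settle_time > 0:
        _adv(settle_time)
    state_t0 = neuron.get_state()
    spikes = np.asarray(_adv(search_time))
    if spikes.size < 3:
        raise ValueError("not enough spikes to locate a reference ISI")
    isis = np.diff(spikes)
    if target_isi is None:
        j = 1 if spikes[0] - _state_time(state_t0) < pre else 0
    else:
        ok = np.flatnonzero(np.abs(isis - target_isi) <= isi_tol * target_isi)
        ok = ok[spikes[ok] - _state_time(state_t0) >= pre]
        if ok.size == 0:
            raise ValueError(
                f"no ISI within {isi_tol:.0%} of {target_isi*1e3:.1f} ms found"
            )
        j = int(ok[0])
    t0, t1 = float(spikes[j]), float(spikes[j + 1])
    ref_isi = t1 - t0

    # position the saved state exactly at t0 - 5 ms
    neuron.set_state(state_t0)
    _adv(t0 - pre - _state_time(state_t0))
    saved = neuron.get_state()

    q = pulse_amplitude * pulse_duration  # pC
    samples = []
    dt = getattr(neuron, "dt", getattr(getattr(neuron, "config", None), "dt", 1e-4))
    for i in range(1, n_trials + 1):
        neuron.set_state(saved)
        t_p = t0 + i * ref_isi / n_trials
        dur = (t_p - (t0 - pre)) + (t1 + post - t_p)
        n_steps = int(round(dur / dt))
        i_arr = np.zeros(n_steps)
        k0 = int(round((t_p - (t0 - pre)) / dt))
        k1 = min(k0 + max(int(round(pulse_duration / dt)), 1), n_steps)
        i_arr[k0:k1] = pulse_amplitude
        tr = np.asarray(_adv(n_steps * dt, i_arr))
        after = tr[tr > t0 + 1e-9]
        if after.size == 0:
            continue
        t_pert = float(after[0])
        phi = min((t_p - t0) / ref_isi, 1.0)
        z = (ref_isi - (t_pert - t0)) / (ref_isi * q) if q != 0 else 0.0
        if q == 0:
            z = (ref_isi - (t_pert - t0)) / ref_isi  # raw delta-phi, uncharged
        samples.append(PRCSample(phi=phi, z=z, order=1, trial_id=i - 1))
    if not samples:
        raise ValueError("replay produced no perturbed spikes")
    return RawPRC(samples=samples, mean_isi=ref_isi, charge=q,
                  n_trials=len(samples))


def _state_time(state) -> float:
    # both neuron classes store absolute time second from the end of the tuple
    return float(state[-2])


#: named simulator presets used by the CLI and the rate-sweep pipeline
PRESETS = {
    "phase-flat": lambda seed=0: PhaseNeuron(PhaseNeuronConfig(
        z_true=z_flat(1.0), seed=seed)),
    "phase-cos": lambda seed=0: PhaseNeuron(PhaseNeuronConfig(
        z_true=z_cos_peaked(1.0), seed=seed)),
    "phase-late": lambda seed=0: PhaseNeuron(PhaseNeuronConfig(
        z_true=z_late_peaked(2.0), seed=seed)),
    "conductance": lambda seed=0: ConductanceNeuron(seed=seed),
}
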