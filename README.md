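# prcclamp

Phase-response-curve (PRC) estimation for tonically firing neurons, with an
in-silico closed-loop laboratory for validating every estimator against a
known ground truth.

## The problem

The PRC Z(φ) of a tonically firing cell (the canonical example being the
cerebellar Purkinje cell, which fires regularly at 20–150 Hz with an ISI
coefficient of variation of 5–10%) gives the normalized shift of the next
action potential caused by a brief current pulse delivered at phase
φ = τ/⟨ISI⟩ of the firing cycle, normalized by the injected charge
Q = I·T (1/pC units); positive values are phase advances.  The PRC links
single-cell biophysics to network synchronization: a flat PRC is a perfect
integrator, a biphasic late-peaked PRC a phase-dependent one.

Estimating Z(φ) well is hard: thousands of trials are needed, the estimate is
censored near φ = 1 (an AP cannot precede the pulse that would have shifted
it), and the cell's firing rate — which shapes the PRC itself — drifts over
the tens of minutes those trials take.  This package implements the
estimation stack used to solve these problems:

* **corrected direct method** — per-trial samples
  Z(φ) = (⟨ISI⟩ − ISI_perturbed)/(⟨ISI⟩·Q), joined with second-order samples
  Z₂(φ₂) referenced to the second AP before the pulse, which restore the
  censored region near φ = 1;
* **Gaussian-kernel smoothing** — Nadaraya–Watson regression with the
  rule-of-thumb bandwidth h = (4/3N)^{1/5}·MAD/0.6745 inferred from the
  data, plus bootstrap 68% confidence bands;
* **WSTA** — the weighted spike-triggered average
  Z(φ) ≈ ⟨α_k I_k(φ)⟩ / (2 s² τ_I), α_k = ⟨ISI⟩/ISI_k − 1, an indirect
  estimate from the response to weak Ornstein–Uhlenbeck current noise
  (SD s, correlation time τ_I);
* **frequency clamp** — a per-AP PID controller
  I_holding = g_P e_k + g_I Σe + g_D Δe acting on the online rate estimate
  F̃_k = ISI_k⁻¹(1−e^{−ISI_k/τ}) + F̃_{k−1} e^{−ISI_k/τ}, with Sobol-sequenced
  reactive pulse delivery (one pulse per 6 APs) and a hold window that
  freezes the controller from the AP before each pulse to the second AP
  after it;
* **shape metrics** — the peak-to-baseline ratio
  r = |m_l − m_e|/(|m_l| + |m_e|) of the two half-curve extrema, its
  sigmoidal rate dependence r(F) ~ (1 + e^{−(F−a)/b})⁻¹, and the peak-time
  transform τ_peak = (φ_peak − 1)·⟨ISI⟩.

Because no recordings ship with the package, every method is validated on
simulated neurons with *prescribed* PRCs: a phase oscillator whose z_true is
an input, and a conductance-based surrogate with optional channel noise
(diffusion approximation of an N-state kinetic scheme, validated against an
exact Markov population simulation).

## Worked example

Run a closed-loop session on the phase neuron whose ground truth is
Z(φ) = 1 − cos 2πφ (1/pC) at 50 Hz, then estimate the PRC from the spike
train and stimulus log alone:

```python
import numpy as np
import prcclamp as pc

neuron = pc.PhaseNeuron(pc.PhaseNeuronConfig(z_true=pc.z_cos_peaked(1.0), seed=1))
train, pulses, log = pc.run_closed_loop_session(
    neuron, pc.PIDConfig(f_target=50.0), n_pulses=1400,
    pulse_amplitude=100.0, pulse_duration=0.5e-3, seed=1)
print(round(log.mean_rate(t_start=5.0), 2))      # 50.0  (Hz, clamped)

res = pc.DirectPRC(train, pulses, t_start=5.0).fit(seed=1)
print(res.summary())
```

```
                     Phase response curve
==============================================================
method:              corrected-direct
firing rate:            49.59 Hz   (<ISI> = 20.17 ms)
trials / samples:    1304 / 1343
bandwidth h:           0.0876 (phase units)
peak-to-baseline r:     0.000   (m_e = +1.803, m_l = +1.803 1/pC)
peak location:       phi = 0.505,  tau_peak = -9.98 ms
second-order samples:39
skipped trials:      {'overlaps_spike': 64, 'phi_in_(1,1+eps]': 1}
pulse charge (pC):   0.05
==============================================================
```

The estimate recovers the prescribed curve: its peak sits at φ ≈ 0.5 with
amplitude ≈ 1.8/pC (the data-driven kernel attenuates the true peak of
2.0/pC by the expected ~10%), the symmetric halves give a peak-to-baseline
ratio of 0, and the RMS error against z_true is 0.16/pC — 8% of the peak.
`res.plot()` shows the raw sample cloud, the smoothed curve and its 68%
bootstrap band; `pc.WSTAPRC(stimuli, trains).fit()` is the indirect
counterpart, and `pc.run_rate_sweep(...)` chains sessions over a list of
target rates and fits r(F).

The same pipeline is available from the shell:

```bash
prcclamp simulate --model phase-cos --target-rate 50 --n-pulses 1400 \
    --seed 7 --out session.h5
prcclamp estimate-direct session.h5 --out raw.h5
prcclamp smooth raw.h5 --out curve.h5
prcclamp metrics curve.h5 --mean-isi 0.02
prcclamp sweep --rates 20,50,100 --rate-dependent-z --out-dir sweep/
```

## Layout

| module | contents |
| --- | --- |
| `prcclamp.spikes` | spike detection, ISI statistics, online rate estimator |
| `prcclamp.direct` | corrected direct-method PRC samples and bounds |
| `prcclamp.smoothing` | kernel bandwidth rule, Nadaraya–Watson smooth, bootstrap CI |
| `prcclamp.wsta` | OU stimulus synthesis, weighted spike-triggered average |
| `prcclamp.metrics` | peak-to-baseline ratio, rate sigmoid, peak timing |
| `prcclamp.clamp` | PID frequency clamp, Sobol scheduler, session orchestration |
| `prcclamp.neurons` | phase-oscillator and conductance surrogates, channel noise, replay protocol |
| `prcclamp.models` | `DirectPRC` / `WSTAPRC` model classes and `PRCResult` |
| `prcclamp.pipeline` / `prcclamp.cli` / `prcclamp.io` | rate sweep, command line, file formats |

See `docs/methods.md` for the models, estimator conventions and numerical
choices.
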