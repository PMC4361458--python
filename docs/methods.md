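# Methods

This note documents the models, estimator conventions, numerical choices and
known limitations of `prcclamp`.  Everything quantitative stated here is
computed by the test suite or the worked example; nothing is quoted from
external data.

## 1. Definitions and conventions

A tonically firing cell with AP peak times t_k has intervals
ISI_k = t_{k+1} − t_k, mean ⟨ISI⟩ and CV = SD/mean.  A pulse at time t_pulse
with last preceding AP t_j has phase φ = (t_pulse − t_j)/⟨ISI⟩.  The phase
response curve Z(φ) is the phase shift of the next AP per unit injected
charge, Δφ/Q with Q = I_pulse·T_pulse in pC; advances are positive.  Internal
units are seconds, Hz, pA, pC and mV throughout; conversions happen only in
`io`.

⟨ISI⟩ is computed over *unperturbed* intervals: every interval containing a
pulse, and the interval immediately after it, is excluded.  Including
perturbed intervals would drag ⟨ISI⟩ toward the stimulated mean and bias
every Δφ toward zero.  The mean can be recomputed per recording block or
supplied globally (`DirectPRC(mean_isi=...)`); per-session is the default.

## 2. Corrected direct method

Each pulse yields a first-order sample

    Z(φ) = (⟨ISI⟩ − ISI_perturbed) / (⟨ISI⟩ · Q).

Because the next AP cannot precede the pulse, ISI_perturbed ≥ τ, so
Z(φ) ≤ (1 − φ)/Q: near φ = 1 large advances are unobservable — the AP fires
*before* the late pulse and the trial is re-referenced to that AP at a small
φ of the next cycle.  The correction recovers the censored mass from
second-order samples referenced to the second AP back,
φ₂ = (t_pulse − t_{j−1})/⟨ISI⟩ and Z₂(φ₂) = (⟨ISI⟩ − ISI_{perturbed−1})/(⟨ISI⟩·Q):

* Samples with φ₂ ∈ [1 − ε, 1] (ε = 0.1) are exactly the trials in which the
  AP anticipated a pulse scheduled late in the cycle.  Plotted at φ₂ they
  complete the ensemble just below φ = 1, between the bounds
  (1 − φ₂)/Q ≤ Z₂ ≤ (2 − φ₂)/Q.  In a null model (no PRC, jitter only) the
  truncated-negative first-order mean and the positive completion mean cancel
  exactly at every plotted phase — the package's null-control simulation
  confirms the joined estimate is unbiased there to within sampling noise.
* Samples with φ₂ > 1 carry no information about the pulse (the interval
  they measure ended before the pulse was delivered; in expectation they are
  zero-mean noise across the whole domain) and are not added to the joined
  set.  Folding them in at φ₂ − 1 would dilute the estimate toward zero by
  roughly a factor of two.

**Mid-perturbation phase.**  A finite pulse is not a delta function: during
delivery the oscillator advances by the pulse width in time plus the shift
the pulse itself produces, so a sample plotted at the onset phase reports the
response averaged over [φ, φ + Δφ] and the recovered curve is displaced
toward early phases by O(Q).  By default each first-order sample is plotted
at

    φ_mid = φ_onset + T_pulse/(2⟨ISI⟩) + Q·Ẑ_pilot(φ_onset)/2,

where Ẑ_pilot is a first-pass smooth of the onset-phase samples.  Using the
pilot estimate rather than each trial's own noisy shift matters: shifting by
the trial's own Δφ/2 correlates abscissa and ordinate noise and sorts samples
by noise sign at the domain boundaries, producing edge artifacts of the order
of the per-sample noise.  The onset phase is retained on every sample
(`phi_onset`) because the censoring bounds above are statements about onset
phases; `phase_convention="onset"` disables the correction.

**Discard rules.**  Pulses before the second spike or after the last spike
are skipped; first-order phases above 1 + ε are skipped; a pulse whose onset
falls within one pulse-duration of an AP peak is discarded (phase attribution
ambiguous when the stimulus rides on the spike) — this window is
configurable and can be set to zero for simulated data where attribution is
exact.  All skips are counted by reason in `RawPRC.skip_log`.

## 3. Smoothing and uncertainty

The raw cloud is smoothed by Nadaraya–Watson regression with a Gaussian
kernel (the conditional mean of a product-kernel bivariate density
estimate); the denominator renormalizes the truncated kernel mass at the
[0, 1] boundaries, with no reflection.  The bandwidth follows the robust
normal-reference rule per coordinate,

    h_x = (4/(3N))^{1/5} · median|x − median x| / 0.6745.

The default bandwidth is h = h_φ: in the conditional mean of a product
kernel the z-coordinate bandwidth cancels, so only the phase bandwidth
matters.  The geometric combination sqrt(h_φ·h_Z) is available
(`bandwidth_method="geometric"`) but mixes the (dimensionful) z scale into
the phase coordinate and oversmooths markedly when the samples are noisy —
with per-sample noise of SD ≈ CV/Q it roughly doubles h and halves the
recovered amplitude of a cosine-shaped PRC.

Known properties of this smoother, visible in the validation battery: a
frequency-1 cosine component is attenuated by e^{−(2πh)²/2} (≈ 0.85 at
N = 1400), and the boundary points carry an upward bias of order
(1 − attenuation)·curvature because only half the kernel is populated there.
Both are properties of the estimator itself, not implementation error; the
recovery criterion (RMSE < 10% of the true peak) is met with them included.

68% confidence bands are pointwise 16th/84th percentiles over bootstrap
resamples of the trials (default n_boot = 1000), computed as multinomial
reweightings against a single precomputed kernel matrix.  Whether the
reference analyses used bootstrap or analytic bands is not documented; ours
are bootstrap and are not claimed equivalent.

## 4. WSTA

The OU stimulus solves τ_I dI/dt = −I + s√(2τ_I) ξ(t) and is synthesized by
exact discretization (I_{n+1} = I_n e^{−dt/τ} + s√(1−e^{−2dt/τ}) N(0,1)), so
its stationary SD equals s for any step; dt ≤ τ_I/10 is enforced so the
correlation time is resolved.  For each interval the mean-subtracted current
segment is linearly resampled onto a common phase grid (default 100 points)
and weighted by α_k = ⟨ISI⟩/ISI_k − 1.  In linear response
E[α_k I_k(φ)] = Z(φ)·∫C(t)dt = Z(φ)·2s²τ_I for *each* interval, so the
estimator is the interval **mean** of α_k I_k(φ) divided by 2s²τ_I (a bare
sum would grow with recording length); the result is in 1/pC directly.
Segments are mean-subtracted so the DC offset used to set the firing rate
cannot leak into the estimate; ⟨ISI⟩ is computed per stimulus realization and
realizations are pooled with interval-count weights.

The WSTA resolves phase only to ~τ_I/⟨ISI⟩, i.e. the recovered curve is the
true PRC smeared by the normalized stimulus autocorrelation — at 50 Hz with
τ_I = 4 ms the frequency-1 component is attenuated to roughly
1/(1 + (2πτ_I/⟨ISI⟩)²) ≈ 0.4.  Peak location and shape correlation with the
direct method are therefore the meaningful comparisons, not amplitude.

## 5. Frequency clamp

After every detected AP the instantaneous rate estimate is updated,

    F̃_k = ISI_k⁻¹(1 − e^{−ISI_k/τ}) + F̃_{k−1} e^{−ISI_k/τ},   τ = 1 s,

initialized at the target rate to suppress startup transients, and the
holding current follows the PID law I = g_P e_k + g_I Σe + g_D (e_k−e_{k−1})
with the experimentally used gains g_P = 0.001, g_I = 0.1, g_D = 0 pA/Hz and
output clamp −200..1000 pA (the integrator freezes while the output is
railed).  One pulse is scheduled per 6 APs: at the scheduling AP a delay
d·(1/F̃) is drawn from the 1-D Gray-code Sobol sequence (16 initial points
discarded by default), and from that AP until the second AP after the pulse
the controller is disconnected with its output held — so no controller
transient is locked to the stimulus.  The integrator does not accumulate
during the hold (a flag restores accumulate-while-held behaviour).  Scheduled
delays only shape the *sampling density*; the analyzed phase is always
recomputed post hoc from the actual spikes.

With these gains the integral loop has a time constant of ~100 APs (≈ 5 s at
20 Hz), so short sessions at low rates converge slowly; clamp accuracy is
asserted on full-session averages after a 5 s transient, and estimation
drops the first 5 s of every session (`t_start`).  A session whose
second-half mean rate misses the target by more than 20% raises a
diagnostic error rather than returning a silently unclamped recording.

## 6. Synthetic neurons (what they emulate, and what they do not)

**Phase oscillator.**  dφ/dt = f(I_dc)·s_k + z_true(φ)·I_perturb(t), spike
and reset at φ = 1, integrated at 30 kHz with sub-sample spike
interpolation.  f(I) = max(30 + 0.1·I, 0) Hz emulates a cell firing ~30 Hz
spontaneously and spanning ~20–130 Hz over the −200..1000 pA holding range.
Intrinsic variability is per-cycle by default: ISI_k = (1 + ξ_k)/f with
ξ_k ~ N(0, jitter_sd), so the CV equals jitter_sd (default 0.07, the middle
of the tonic-firing range this emulates) exactly and seed-matched sessions
share their jitter cycle-for-cycle — that is what makes "same seed, PID on
vs constant current" comparisons cancel intrinsic noise.  A per-step
Brownian phase-diffusion mode is available (`jitter_mode="diffusion"`).
Ground-truth shapes shipped: flat (low-rate phenotype), 1 − cos 2πφ
(smooth mid-peaked reference), a biphasic late-peaked profile (peak at
φ = 0.75 ≈ 5 ms before the AP at 50 Hz, with a shallow negative early
lobe), and a rate-interpolating family that morphs flat → late-peaked with a
logistic midpoint at ~48 Hz.  Default amplitudes keep the response
perturbative: peak z of order 1/pC gives per-pulse advances (≤ 0.1 cycle at
0.05 pC) comparable to the intrinsic jitter.

The phase model is a caricature: it has no refractory dynamics, no
rate-dependent PRC shape unless prescribed, and its response to strong
inputs is exactly linear in charge through z_true.  Passing the recovery
tests shows the *estimators* are correct, not that any biological claim
holds.

**Conductance surrogate.**  A Wang–Buzsáki-style single compartment
(gNa = 35, gK = 9, gL = 0.1 mS/cm², instantaneous m, gating temperature
factor 5) with area 2·10⁻⁴ cm² and an intrinsic 150 pA drive so it fires
tonically (~43 Hz at zero external current, type-I-like monotone f–I from
~13 Hz at −100 pA to ~195 Hz at +1000 pA), integrated by forward Euler at
25 µs with 0 mV upward-crossing spike detection.  It is *not* a Purkinje
cell model; it is the minimal conductance-based cell on which the clamp,
replay and channel-noise machinery can be exercised.

**Channel noise.**  Conductance fluctuations from stochastic gating are
approximated by g(t) = ḡ(p_o(t) + Ση_i(t)) with N−1 OU processes whose
(τ_i, σ_i) come from the eigendecomposition of the N-state scheme's
generator: τ_i = −1/λ_i and σ_i² the spectral amplitude of the single-channel
open-indicator autocovariance divided by the channel count.  The scheme is
frozen at a fixed voltage (quasi-static approximation; default −50 mV, near
the interspike mean), unlike treatments that recompute the coefficients
along the trajectory — a documented simplification.  Reversible schemes only
(real modes); the exact multinomial population simulator
(`exact_markov_simulation`, valid for dt·max exit rate ≤ 0.1) is the oracle:
summed-OU autocovariance matches it within 10% at lags {0, τ_min, τ_max}
for the shipped two-state and five-state chain schemes at 1000 channels.
An additive noisy current I = I_m + I_s ξ(t) (I_s in pA·√s; the
variance of injected charge grows as I_s²·t) is the additive-noise
alternative; I_s ≈ 1–2 pA·√s gives CV ≈ 4–9% in the surrogate.

**Replay protocol.**  For models with exact state snapshot/restore: locate
an unperturbed reference ISI [t₀, t₁] (optionally matching a requested
duration), save the state at t₀ − 5 ms, and for i = 1..N (default 50)
restore, deliver one pulse at t₀ + i(t₁−t₀)/N, simulate to t₁ + 10 ms and
record the perturbed AP time.  On the deterministic phase neuron this
recovers z_true within 2% of its peak at small charge; determinism of
restore makes repeated protocols bit-identical.

## 7. Problem sizes and tolerances

The validation battery runs at desk scale, chosen so the whole suite
completes in minutes: ground-truth recovery uses one 1400-pulse session at
50 Hz (the standard trial count for this protocol); bound compliance uses
ten 400-pulse sessions; clamp convergence uses 300-pulse sessions per target
rate; the PID-vs-constant comparison uses seed-matched 1400-pulse sessions;
the Markov oracle uses 1000 channels for 10 s.  Acceptance-style tolerances:
recovery RMSE < 10% of the true peak, bounds exact to 1e−9, direct/WSTA
Pearson > 0.8 with peak agreement within 0.1 phase, clamp within 2%,
OU SD within 3% and autocorrelation time within 10%, diffusion-vs-Markov
autocovariance within 10%, sigmoid refit exact to 1e−6.

Numerical details: phase model Euler at 30 kHz (spike times interpolated
within a step); conductance model Euler at 25 µs; PRC lookup tables with 513
points and linear interpolation; sigmoid fitting by multi-start trust-region
least squares over a fixed initial grid (deterministic); peak ties at
φ = 0.5 assign to the late half; plateau maxima report the plateau midpoint
with a warning; an identically zero curve reports r = 0 flagged degenerate.

## 8. Known limitations

* The smoother's boundary bias (Section 3) can pull the argmax of strongly
  late-peaked curves toward φ = 1; peak-location comparisons are most
  reliable for peaks at φ ≲ 0.8.
* Second-order completion is only collected in [1 − ε, 1]; PRCs of order
  higher than 2 are out of scope.
* The WSTA amplitude is attenuated by the stimulus correlation time and is
  not corrected for it.
* Simulators are validated for the regimes used here (20–150 Hz, CV ≤ ~0.2);
  the conductance surrogate's behaviour far outside its f–I range is
  unchecked.
* Real recordings bring artifacts none of the simulators emulate: electrode
  drift, AP waveform changes with rate, true rate adaptation, and synaptic
  bombardment.  Passing the in-silico battery demonstrates estimator
  correctness under the stated noise models, nothing more.
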