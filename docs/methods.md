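# Methods

This note documents the models, algorithms and numerical choices behind
`phonolvp`: what the pipeline computes, what the synthetic-data generator
emulates, which parameters matter, and where the design was genuinely open.

## 1. The estimation problem

Left-ventricular pressure indices — end-diastolic pressure (EDP [mmHg]),
end-systolic pressure (ESP [mmHg]) and the peak pressure-rise rate
(dP/dt_max [mmHg/s]) — can only be measured with an intraventricular
catheter. The pipeline predicts them per heartbeat from three non-invasive
channels recorded on a common 1 kHz clock: ECG [V], a phonocardiogram
(MIC [mmHg]) and a pulse-oximetry waveform (POX [mmHg]). The invasive LVP
channel is used only to extract the per-beat regression targets and, in
simulation, to validate recovery.

Per pacing step (spontaneous rhythm, then 100/120/140/160 beats/min), the
model is ordinary least squares on 18 predictors: invPTT (reciprocal pulse
transit time) plus 17 mel-spectral descriptors of the beat-phase
phonocardiogram — set A (spectral flux, kurtosis, skewness, slope) and
set B (13 delta-delta MFCCs). Systolic sounds predict the preceding EDP and
the contemporary dP/dt_max; diastolic sounds predict the preceding ESP.
Evaluation is in-sample (no hold-out): each step is a separate, short,
stationary recording, and the report compares nested models (invPTT alone
versus all 18) whose in-sample R² ordering is guaranteed.

## 2. Beat segmentation from the envelope difference (MED)

The MIC signal is up- and down-enveloped with a sliding-extrema estimator
(moving maximum/minimum over a 50 ms window followed by moving-average
smoothing of the same width; guarantees `upper >= lower`, hence MED =
upper − lower >= 0). A cubic-spline-through-peaks variant is available for
comparison but offers no ordering guarantee. MED is band-pass filtered with
a 4-pole Butterworth (passband 0.7–1.3 × the HR fundamental) applied
forward–backward, so minima timing is phase-true; the residual mean (edge
transients, incomplete last cycle) is removed explicitly. For each RR
interval the boundary between systole and diastole is the deepest local
minimum of the filtered MED within [0.2, 0.6]·RR after the R peak (earliest
on ties); beats without such a minimum are flagged `no_med_minimum`, beats
shorter than 250 ms `rr_too_short`.

Why this works: the band-passed MED is essentially the HR-fundamental
Fourier component of the acoustic amplitude envelope. For a cycle whose
acoustic energy is concentrated in two bursts (S1 near the R peak, S2 at
end-systole), writing the burst phases as phasors shows the fundamental's
minimum always falls between half a cycle and half a cycle past S2, and it
coincides with end-systole exactly when systole occupies half the cycle —
in which case the minimum is *pinned* there for any S1-louder-than-S2
loudness ratio, independent of beat-to-beat loudness jitter. This is the
regime the simulator renders (Section 5), and the regime in which the MED
minimum is a faithful systole/diastole boundary.

R peaks come from a Pan–Tompkins-style detector (band-pass 5–30 Hz,
differentiate, square, 120 ms integration, threshold at 0.4 × a blockwise
95th percentile, 240 ms refractory, refinement to the local energy
maximum). The threshold is relative, so detection is invariant to positive
rescaling of the ECG. HR = 60 / median RR.

Hemodynamic stability selection (`select_stable_segment`) finds the longest
contiguous window (default >= 180 s) in which every beat's stability proxy —
per-beat LVP maximum, else POX pulse amplitude — stays within ±10% of the
window median. The search greedily extends each candidate start and stops at
the first violation; the window median is recomputed as the window grows.

## 3. Features

**invPTT.** PTT is the delay from the R peak to the maximum of the
(25 ms-smoothed) POX first derivative within (r, r + 0.6·RR], refined to
sub-sample precision by a parabolic fit through the derivative peak;
invPTT = 1/PTT. Maximum upslope is robust to baseline drift and, with the
symmetric smoothing, unbiased for symmetric upstrokes.

**Mel spectrogram.** 50 ms Hann frames, 10 ms hop (about 14 frames even for
a systole at 160 beats/min), FFT zero-padded to >= 256 points, 32 triangular
mel bands spanning 20–150 Hz on the HTK mel scale m = 2595·log10(1+f/700).
Three defaults deserve comment, all exposed in `SpectroConfig`:

* *Frame length 50 ms.* At 1 kHz, shorter frames (e.g. 25 ms) give a raw
  spectral resolution of tens of Hz — coarser than the mel bands themselves —
  and unstable band energies; 50 ms frames roughly halve the bin width and
  double the in-band SNR while still resolving the beat phases.
* *Band range 20–150 Hz.* S1/S2 energy in large mammals lies below
  ~150 Hz. Extending the filterbank to 500 Hz only adds bands that, on real
  (noisy) sensors, carry no signal; their energies then dominate the
  spectral moments with noise.
* *FFT zero-padding to 256.* A 50-sample FFT would leave most mel triangles
  without a single bin.

**Set A.** Per frame with band energies `s_k` at centres `f_k`: the
energy-weighted centroid and spread define skewness (third standardized
moment) and kurtosis (fourth); slope is the least-squares slope of `s`
against `f`; flux is the Euclidean norm of the difference of unit-sum
normalized energies between consecutive frames. Features are arithmetic
means over frames; empty frames (zero total energy) are skipped everywhere
and zero-spread frames contribute no skewness/kurtosis; a beat phase whose
every frame is degenerate is flagged. Kurtosis, skewness and flux are
invariant to rescaling the input; slope scales with the energy gain
(i.e. with the square of an amplitude factor), which is the one
amplitude-sensitive channel in the set.

**Set B.** Per frame, cepstra are the orthonormal DCT-II of
log(E + floor), keeping 13 coefficients (configurable offset for dropping
the energy-like coefficient 0); the regression delta operator (window 2,
edge replication) is applied twice; the result is the frame mean of the
delta-delta vectors. The floor is the larger of an absolute epsilon (1e-10)
and a *dynamic-range floor* 27 dB below the segment's peak band energy —
the cepstral analogue of the top-dB convention in audio processing. Without
it, bands containing only sensor noise fluctuate O(1) in the log domain *at
any SNR*; with it, such bands saturate at a constant. Because the floor
scales with the signal, a gain change still adds a pure constant to the log
energies, so the delta operator removes it and set B remains exactly
scale-invariant.

## 4. Targets from the invasive channel

Per valid beat: EDP = LVP at the R-peak instant (the standard
catheterization end-diastole surrogate); dP/dt_max = maximum of the
pressure derivative (moving-average smoothing over 5 samples, central
differences, replicated edges) within systole; ESP = LVP at the
minimum-dP/dt instant within the beat (end-systole surrogate), computed
from LVP alone so ground truth never depends on the MED boundary. The
5-sample smoothing attenuates a 20 Hz component by ~1.6%; pass
`smooth_window=1` to disable.

## 5. The synthetic study generator

The generator emulates the study conditions the pipeline is built for: two
subjects' presets (healthy: EDP 5.70, ESP 64.81, dP/dt_max 1168.75 mmHg/s;
HFrEF: 15.45, 77.65, 581.55; both at HR 78), a five-step protocol
(spontaneous, 100–160 beats/min in 20 beats/min steps) with 180 s per step —
a few hundred beats per regression — and four channels at 1 kHz.

**Hemodynamics.** Per step, beat times follow the pacing rate with 0.5%
white multiplicative RR jitter (anesthetized, largely paced rhythm). EDP,
ESP and dP/dt_max are independent stationary AR(1) series around the preset
means (marginal σ = 5% of the mean, lag-1 autocorrelation 0.5, clipped at
±3σ). PTT follows a reciprocal-affine law in ESP — invPTT is exactly affine
in ESP with d(PTT)/d(ESP) = −2 ms/mmHg at the operating point (PTT shortens
as pressure rises), intercept 150 ms, floor 50 ms.

**LVP.** A C¹ piecewise template per beat: a slope-blended linear upstroke
whose maximum slope is exactly the beat's dP/dt_max, rising from EDP to
ESP + 8 mmHg; a plateau; a 30 ms raised-cosine isovolumic fall whose
midpoint — the most negative slope, i.e. the ESP fiducial — sits at
end-systole; and a slow raised-cosine decay to the next beat's EDP. The
fall is steeper than any diastolic decay the presets can produce, so the
minimum-dP/dt instant is unambiguous. End-systole is half the RR interval
(Section 2); if an extreme beat's upstroke would not fit, end-systole is
stretched just enough, which never occurred under the default presets.

**MIC.** S1 and S2 are Hann-windowed, exponentially damped tone bursts
(120 ms support, 80 ms decay), support-centred on the R peak and
end-systole. Their couplings encode the indices in the spectrum: S1
frequency 40 Hz × (1 + 3.5·ΔEDP/EDP̄) — a stiffer, pressure-loaded ventricle
transmits higher-pitched closure sounds; S1 gain ∝ dP/dt_max (louder S1
with stronger contraction; HFrEF renders louder sounds overall, gain 0.08
vs 0.04 mmHg); S2 frequency 65 Hz × (1 + 1.2·Δ(dP/dt_max)); S2 gain ∝ ESP
(louder closure against higher aortic pressure) at 1/1.8 of the S1 gain.
Optional fixed-frequency ejection-murmur/diastolic-rumble components exist
in the configuration but are off by default. Outside burst supports the
noise-free MIC is exactly zero.

**POX.** An asymmetric plethysmographic pulse per beat: a 100 ms
raised-cosine anacrotic rise whose maximum upslope lags the R peak by
exactly that beat's PTT, then a slower raised-cosine decay; pulse amplitude
responds mildly to ESP.

**ECG.** A narrow Gaussian R bump per beat plus a broader T bump before
end-systole.

**Noise.** Additive white Gaussian noise per channel at a configured SNR
(std = rms/10^(SNR/20)). `NoiseConfig.noninvasive(20.0)` — the pipeline
default — degrades ECG/MIC/POX and leaves LVP clean, because the catheter
pressure is the reference measurement, not part of the degraded
non-invasive acquisition.

All randomness flows from explicit integer seeds through spawned
`SeedSequence`s; identical seeds reproduce every sample bit-for-bit.

**What the generator does and does not emulate.** It reproduces the
*structure* of the study — synchronized channels, pacing steps, beat-scale
hemodynamic variability, pressure-coupled acoustics, pressure-dependent
pulse arrival — with couplings chosen so that the information the pipeline
is supposed to extract is genuinely present in the rendered signals.
It does not attempt physiological completeness: no PV-loop volume channel,
no respiration or baseline wander, no ectopy or arrhythmia, no murmur
pathology by default, stylized waveform morphologies, and index-to-sound
couplings that are affine by construction rather than measured. Passing
recovery tests therefore demonstrates that the *pipeline* is correct and
self-consistent (segmentation finds the true boundaries, features carry the
encoded information, regression recovers it), not that real animals encode
their pressures this way; performance numbers on simulated data are not
forecasts for real recordings.

## 6. Regression and reporting

Predictors are standardized internally for conditioning only; coefficients
are reported on the original scale. R² is in-sample; RMSE defaults to the
degrees-of-freedom-corrected residual standard error
`sqrt(SS_res/(n-p-1))` — the only convention under which a richer model can
simultaneously show higher R² and higher RMSE, a pattern per-step tables of
this kind do exhibit — with a plain `sqrt(SS_res/n)` variant by flag. A fit
is reported `not_available` (never silently dropped) when n < p + 2, the
design is rank-deficient, or an upstream stage failed; the reason is
carried along. 95% bounds are for the mean prediction along the fitted
"whole model" axis, on a 100-point grid (prediction intervals by flag).
A zero-variance response reports R² = 0 with a warning.

## 7. Numerical choices and degenerate inputs

* Zero-phase (forward–backward) filtering everywhere timing matters; SOS
  biquads for the very-low-frequency MED band-pass.
* Envelope smoothing can produce last-bit ordering violations between the
  upper and lower envelope; the lower envelope is clamped.
* Rolling ECG thresholds use 5 s blockwise percentiles (O(n)).
* EDF export encodes int16 with per-channel physical ranges widened to
  their 8-character header representation, so a round trip is exact to the
  quantization step (~1.5e-5 of the range) — a property of the format, not
  of the codec. CSV round trips are exact (17 significant digits).
* Empty/constant inputs: constant ECG yields no beats (a warning, fatal
  downstream per step); constant POX flags `no_pox_upstroke`; a constant
  filtered MED flags `no_med_minimum`; an all-zero spectrogram raises a
  degenerate-spectrum error that the feature table records per beat-phase.

## 8. Known limitations

* In-sample evaluation by design; the optional k-fold switch is off by
  default and untested against any external truth.
* The MED boundary argument assumes a two-burst acoustic cycle with systole
  near half the RR interval; rhythms or pathologies violating that (long
  diastole at slow rates with loud S3/S4, heavy murmurs) will bias the
  boundary, which is why per-beat validity flags and the not_available
  accounting exist.
* The 18-feature OLS on a few hundred beats is deliberately simple; with
  correlated acoustic features its coefficients are not individually
  interpretable (conditioning is handled, inference on coefficients is not
  offered).
* Channel units are treated as opaque labels; no calibration of the MIC
  channel is attempted.
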