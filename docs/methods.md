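# Methods

`motionerp` implements a complete analysis chain for simple visuomotor
reaction experiments with radial motion-onset stimuli: continuous 63-channel
EEG + EOG + EMG recordings at 1000 Hz are reduced to component latencies and
amplitudes (N1, N2, N2-r over the visual motion area MT; an early positivity
and later negativity over the pre-/supplementary motor region BA6), to
behavioral measures (EMG onset, visuomotor reaction time, motor time), and to
the group statistics linking them. A synthetic-data generator produces
recordings with exact ground truth so that every stage is verifiable.

## Signal pipeline

**Filtering.** EEG and EOG channels are band-passed 0.3–35 Hz with a
4th-order Butterworth filter applied forward–backward (`sosfiltfilt`):
monotone passband, zero phase, so peak latencies are not shifted. The EMG
channel is never run through this filter; it has its own detection path.

**Epoching and baseline.** Stimulus-locked epochs span −500..1000 ms
(half-open sample ranges at 1 ms resolution; event time 0 is the marker
sample). The −500..0 ms mean is subtracted per trial and channel. Events too
close to a recording edge yield flagged, not dropped, trials.

**Trial exclusion.** Flags are additive metadata; data are only omitted at
averaging. Reasons, in precedence order: `eeg_artifact` (any EEG channel with
an adjacent-sample step > 50 µV or |amplitude| > 150 µV within −500..500 ms),
`blink` (EOG deviation within −500..200 ms beyond 4× the robust SD of the EOG
baseline — blinks in this interval impair the task-relevant perception),
`no_onset`, `onset_lt_100` (EMG onset < 100 ms is too fast to be
stimulus-driven), `vmrt_range` (VMRT outside 100–500 ms), `vmrt_outlier` and
`motor_outlier` (|z| > 3 against the mean/SD of range-surviving trials, one
pass, per condition). Each trial is counted once under its first triggering
reason, so `n_trials = included + Σ excluded` holds exactly.

The published protocol identified blinks with an ocular-correction ICA; this
package replaces that with EOG thresholding plus exclusion, preserving the
interval and the exclusion logic. ICA is deliberately out of scope.

**Bad channels.** A channel artifactual in > 25 % of trials is rebuilt by
spherical-spline interpolation from the remaining channels, after which
artifact flags are recomputed from the repaired data. More than 20 % bad
channels is a hard error: interpolation at that scale is fabrication.

**Current source density.** Scalp potentials are converted to a
reference-free surface Laplacian via spherical splines (stiffness order
m = 4, 10 Legendre terms, λ = 1e−5). The CSD kernel uses
h(x) = Σ (2n+1)/(n(n+1))^(m−1) P_n(x)/4π so that a degree-n spherical
harmonic map is returned scaled by the analytic eigenvalue n(n+1)/r², and
constant maps are annihilated (rows of the operator sum to 0). The head
radius defaults to 1 m for documentation-scaled µV/m² units; all amplitude
comparisons in this package are relative, and a physical radius of 0.092 m
would rescale every CSD value by the same 1/r². On an upper-head electrode
cap the spline is least faithful for maps with strong equatorial/vertical
structure (cap-edge truncation); the closed-form checks therefore use the
sectoral degree-3 harmonic y(3x²−y²), the best-sampled one, where the fitted
eigenvalue is within ~0.5 % of 12 and the pointwise residual ~9 %.

A **CSD bypass** flag runs ROI pooling on sensor potentials instead. It
exists because the generator's ground truth is defined at the sensor level;
recovery tests use it, while CSD correctness is established separately by
the closed-form tests.

**Regions of interest.** Area MT: mean of PO7, P7, P5, PO8, P8, P6, or — for
subjects with a more anterior MT projection — TP9, TP7, T7, TP10, TP8, P8.
The published choice between the two pools was visual; the objective
surrogate here selects the pool with the more negative pooled minimum inside
the N2 window, ties to the standard pool, and logs the choice. BA6: FC1,
FCz, FC2 at weight 1 plus F1, F2, Fz, FC3, FC5, FC6, FC4 weighted 0.61,
0.69, 0.82, 0.75, 0.63, 0.57, 0.82 (their probability of overlying BA6);
pooling is Σwᵢxᵢ/Σwᵢ.

**Peaks.** N1: most negative sample in 50–150 ms; N2: 100–300 ms; BA6
positivity: most positive in 50–150 ms; BA6 negativity: most negative in
100–300 ms — all on the stimulus-locked average. N2-r: most negative sample
in −50..50 ms of the response-locked average, built by re-cutting each
included trial's (CSD or sensor) epoch at its detected EMG onset
(−500..200 ms, no re-baselining; the stimulus-locked baseline carries over).
Windows are closed, ties go to the earliest sample, and an extremum sitting
on a window edge with the slope continuing outward is flagged `edge-peak` —
the automated replacement for visual peak checking. Amplitude is the value
at the peak sample.

**EMG onset.** The detector rectifies the signal, low-passes at 50 Hz,
smooths with a 25 ms moving average, and takes the first post-stimulus time
at which this envelope exceeds the baseline (−500..0 ms) mean by 3 baseline
SDs and stays above threshold for ≥ 10 ms (an objective persistence rule in
place of manual onset checking). Three design points deserve explanation:

1. *Threshold statistics come from the pre-smoothing (rectified,
   low-passed) baseline.* The 25 ms average collapses baseline variance so
   far that 3 SDs of the smoothed envelope sit just above its mean, and
   noise crosses such a threshold constantly. The pre-smoothing SD restores
   the intended strictness of the 3-SD rule.
2. *The detection path is causal* (one-pass filter, trailing window).
   Symmetric smoothing spreads the burst backward in time, so a
   near-baseline threshold is crossed systematically *before* the true
   onset — and the earlier the higher the burst SNR, because the crossing
   happens in the Gaussian tail of the smeared rise. A causal path turns
   this unbounded early bias into a small, positive, bounded delay.
3. *The crossing is bias-corrected with the chain's own step response.* For
   an envelope step of measured height the crossing delay of the causal
   chain is a deterministic constant (the time its unit-step response needs
   to reach the threshold ratio); the detector estimates the burst plateau
   just after the crossing and subtracts that delay. On the generator's
   burst model (baseline noise of SD σ₀ switching to 8σ₀ at onset) the
   residual error is ≈ 0.2 ± 1.5 ms; the correction is exact for ideal
   steps up to interpolation error.

VMRT is button press minus stimulus onset (first press before the next
stimulus); motor time is VMRT − EMG onset, identically, on every trial where
both exist.

## Statistics

Paired t-tests compare the 13 condition-level parameters (EMG onset, VMRT,
motor time; latency and amplitude of N1, N2, N2-r, BA6 positivity, BA6
negativity) between conditions, with Cohen's d = mean(diff)/sd(diff) ≡ t/√n
and Benjamini–Hochberg FDR adjustment across the 13-test family. ERP
parameters are screened by Pearson correlation (p < 0.05 against EMG onset
or VMRT) before entering regression; collinear predictors (tolerance
= 1 − R²ⱼ < 0.4, i.e. VIF > 2.5) are dropped worst-first. Stepwise forward
OLS adds, at each step, the candidate with the smallest partial-F p-value
while it is below 0.05 (no removal step); the partial F for one added
predictor equals the squared t of its coefficient in the augmented model.
Adjusted R² is 1 − (1−R²)(n−1)/(n−k−1). Residual diagnostics: Breusch–Pagan
(homoskedasticity), Durbin–Watson (autocorrelation), and Lilliefors-
corrected Kolmogorov–Smirnov normality (parameters are estimated from the
residuals, so the uncorrected KS test would be anticonservative). Every
candidate evaluation is recorded in a step log.

## Synthetic data generator

The generator emulates the reaction protocol: per condition 80 trials,
inter-stimulus intervals uniform on 2–6 s (ISIs shorter than the 1.5 s
analysis epoch are rejected at generation), a 200 ms motion stimulus, and
condition parameter defaults equal to the published group means (slow/fast
EMG onset 206.4/181.2 ms, motor time 51.9/51.3 ms, N1 107.3/103.4 ms, N2
193.4/187.1 ms, BA6 positivity 88.9/87.7 ms, BA6 negativity 161.8/164.5 ms).

ERP components are raised-cosine bumps (full width 80 ms for N1/BA6
positivity, 120 ms for N2/BA6 negativity — smooth, single-peaked,
analytically known maximum), placed at per-trial latencies drawn around the
condition mean (trial SD 8 ms, a typical trial-to-trial jitter for strong
sensory components) on fixed spatial patterns: Gaussian angular falloff
(σ = 28°) around PO7/PO8 for the MT components (TP7/TP8 for anterior-MT
subjects) and around FCz for the BA6 components. No biophysical forward
model is implied; the patterns exist to make ROI pooling meaningful.
Sensor-level amplitudes are free parameters (the published amplitudes are
post-CSD); defaults (N1 −8/−14 µV, N2 −15/−18 µV, BA6 +6/+7 and −10/−13 µV
for slow/fast) mirror the published post-CSD amplitude ratios.

Background EEG noise is a Gaussian process whose PSD is an equal-power (at
10 Hz) mixture of white and 1/f^α (α = 1) components, 8 µV RMS per channel
by default — realistic broadband posterior EEG in the 0.3–35 Hz band —
independent across channels. The EMG channel is Gaussian noise whose SD
steps from σ₀ to 8σ₀ at the drawn onset; the button press is placed at
onset + motor time *exactly*, so ground truth satisfies the motor-time
identity by construction. Blinks are 300 ms raised-cosine waveforms
(~180 µV) at Poisson times on the EOG, propagated at gain 0.35 to
frontopolar channels; a designated fraction of trials (default 5 %,
matching the published ~4 excluded segments of 80) receives high-amplitude
excursions (> 150 µV) or electrode-pop steps (350–600 µV, large enough that
the > 50 µV/ms step criterion still fires after the 35 Hz low-pass spreads
the edge). All randomness flows from explicit seeds through numpy's
splittable `SeedSequence`, so identical specs and seeds give bit-identical
recordings.

**Cohorts.** Subject-level parameters are drawn per condition with
between-subject SDs equal to the published group SDs (N2 6.0 ms, N2-r
7.4 ms, motor time 3.2 ms, ...). EMG onset follows a linear coupling on the
drawn N2 and N2-r latencies, EMG = mean + b·(N2−μ) + c·(N2r−μ) + ε with
defaults b = 0.7, c = −0.9, residual SD 3.2 ms — chosen so the generating
model's R² is ≈ 0.85 and the implied between-subject EMG SD matches the
published 8.4 ms. The drawn N2-r is a *latent* covariate: since the
generator models one MT component per trial, the waveform-level
response-locked latency the pipeline measures is structurally
N2 − EMG onset at the subject level. Measured N2-r group means therefore
differ from the published ones while preserving every direction and
coupling sign the tests assert (fast > slow N2-r latency; negative N2-r
coefficient for EMG onset). In real data the two quantities decouple
through asymmetric latency smearing and genuinely response-locked activity,
which this single-component model does not attempt to reproduce.

## What passing tests do and do not show

Recovery tests demonstrate that the pipeline returns the truth its input
encodes — under Gaussian, channel-independent noise, stereotyped artifact
shapes, and cosine-bump components. Real EEG has spatially correlated
noise, non-stationary artifacts, overlapping components, and subject-
specific topographies; passing here shows algorithmic correctness, not
field performance. The condition-direction cohort check is a scaled-down
analogue of the published group comparison: it verifies signs and
significance under the published means/SDs, not the published numerical
values, which depend on the unavailable raw data.

## Numerical choices and degenerate inputs

Windows given in ms map to half-open sample ranges except component search
windows, which are closed (inclusive ends, ties to earliest). A flat EMG
baseline (SD = 0) raises a degenerate-baseline error rather than detecting
at an undefined threshold. All-equal behavioral values yield no outlier
flags (z undefined → skipped). Zero-variance paired differences are an
error, not t = 0. The CSD solve adds λ to the g-matrix diagonal; a singular
system raises an error naming λ. Problem sizes in the heavy verification
runs (100 noisy replicates, 200 stepwise cohorts, one 37-subject pipeline
cohort) were chosen to give stable Monte-Carlo estimates at comfortable
runtimes on a single CPU.

## Known limitations

No ICA, no re-referencing, no resampling, no source localization, no
realistic head geometry, no eye movements beyond stereotyped blinks, no
stimulus rendering. The BrainVision dialect covers the multiplexed IEEE
float32 variant this package writes (the common modern layout), not vendor
INT_16 files. Single-condition amplitude statistics at the sensor level are
arbitrary up to the free amplitude scale.
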