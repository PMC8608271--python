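# Methods

This note records the models, the numerical choices, and what the
synthetic-data validation does and does not establish.

## Acoustic front end

The auditory spectrogram models early auditory processing as a bank of 128
bandpass filters geometrically spaced over 180 Hz–5.5 kHz.  The upper edge
reflects the Nyquist limit of 11.025 kHz speech material; speech carries
little energy above 5 kHz, so the truncation costs little.  Filters are
asymmetric log-frequency Gaussians (shallow low-frequency skirt,
σ = 0.25 oct; cliff-like high-frequency skirt, σ = 0.03 oct), so a tone
excites channels at and above its place, as in cochlear excitation
patterns.  Channel envelopes (analytic-signal magnitude) are compressed
(cube root by default; the compression is configurable because only
"compressive" is physiologically constrained), then passed through a
rectified first difference toward the next-lower channel.  This lateral
inhibition localises the sharp low-frequency edge of the excitation
pattern at the tone's place; the derivative direction matters — taken the
other way the peak lands one band high.  Envelopes are integrated into
10 ms frames (100 Hz; supports modulation analysis to 50 Hz, beyond the
32 Hz grid analysed) and averaged into 16 contiguous log-spaced bands
whose centres are the geometric means of their 8 channels.

## Neural front end

Raw recordings are resampled to 500 Hz, high-passed at 1 Hz (first-order
Butterworth), notch-filtered at 60/120/180/240 Hz (second-order IIR, 1 Hz
bandwidth), split into eight equal 10 Hz bands spanning 70–150 Hz,
converted to analytic-signal magnitudes, and averaged across bands before
z-scoring — averaging first keeps the estimate of the broadband envelope
unbiased by per-band scale.  All filters run forward–backward: response
latency is a headline output and zero-phase filtering keeps it unbiased by
group delay.  The final envelope is resampled to the spectrogram frame
rate and z-scored per electrode by the mean and SD of a prestimulus silent
window; a zero-variance baseline raises a flagged-channel error rather
than propagating infinities.

## STRF estimation

The encoding model is linear in the lagged spectrogram with lags 0–300 ms
(latencies in this region of cortex reach 200 ms; the window leaves
margin).  "Normalized reverse correlation" is implemented as ridge
regression on the lagged-stimulus Gram matrix — the algebraically
equivalent form — with 20 contiguous-block cross-validation folds.  The
ridge grid spans six decades, scaled by the mean eigenvalue of the
training Gram matrix so the grid is invariant to stimulus power;
sparseness is an element-wise soft-shrinkage threshold (0, 5 or 10 % of
the peak weight) applied to the ridge solution and selected on the same
held-out folds.  Each leave-one-fold-out Gram matrix is eigendecomposed
once and shared across electrodes, so a 100-electrode array costs seconds
rather than hours.  Per-fold held-out Pearson correlations are retained;
the electrode-inclusion gate is a one-sided one-sample t-test of those 20
correlations against zero, Benjamini–Hochberg corrected across electrodes
at α = 0.01.  Degenerate cases error out (constant response, length
mismatch) rather than returning silent garbage.

## Tuning extraction

**BF and latency.**  The excitatory region is the contiguous set of
weights ≥ 50 % of the maximal positive weight containing that maximum
(threshold configurable; recovery is stable over 30–70 %).  BF is the
power-weighted centroid along log2 frequency, latency along lag.
Negative (inhibitory) regions never enter the centroid, so delayed
inhibitory sidebands do not bias it.

**BTM.**  The STRF is decomposed by a bank of directional modulation
filters applied in the 2-D Fourier domain over (time, log-frequency):
constant-Q Gaussians in log2 rate and log2 scale (σ = 0.5 oct) on the
grids {1, 2, 4, 8, 16, 32} Hz × {0.25, 0.5, 1, 2, 4, 8} cyc/oct, with
upward and downward sweep quadrants collapsed by magnitude (the rate axis
is unsigned; BTM of a time-reversed STRF equals that of the original).
The temporal axis is zero-padded to 512 samples so low rates are resolved.
BTM is the power-weighted centroid of the rate marginal (mean over scale,
time and band).  The defining sentence of the rate summary admits two
readings (weights = power at each rate vs weights = the rates themselves);
the power-weighted centroid is implemented because the alternative is a
constant of the grid, independent of the STRF.  The centroid reads high by
up to ~10 % at 2 Hz (log-asymmetric leakage of finite-window spectra);
planted gratings at 2–16 Hz are recovered within that error.

**Speech sensitivity.**  Per-trial responses are z-scored by the mean/SD
of the silent interval, time-averaged per trial, and contrasted
speech-vs-nonspeech by an unpaired equal-variance t statistic (Welch
optional; the statistic is invariant to common affine transforms, so the
silence normalisation affects interpretation, not the t-value).
Significance flags use BH-FDR across sites at q < 0.01 with t > 0.
Predicted sensitivity applies the identical statistic to STRF-predicted
responses, normalised by the prediction's own silent-interval output so
the comparison is internally consistent; an all-zero filter or degenerate
silent prediction yields a flagged NaN.

**Speaker invariance.**  Phoneme windows are half-open [start, end) ms
after onset, frames `floor(onset·fr) + floor(start·fr/1000) …
floor(onset·fr) + floor(end·fr/1000) − 1` (0-based); decoding uses
70–180 ms, onset-aligned population geometry 90–150 ms (neural) and
10–70 ms (acoustic), with the data-driven alternative available through
the F-statistic window selector (ties break to the earlier window).  The
RLS classifier is one-vs-rest ridge on ±1 targets with argmax decision,
features standardised on the training set and the ridge parameter chosen
on a 10 % validation split.  SI divides pooled-training leave-one-speaker-
out phonetic-attribute accuracy by within-speaker 10 %-cross-validated
accuracy, averaged over speakers and the five attributes (manner, place,
voicing, height, backness; attribute values inapplicable to a segment
class are excluded, classes below a minimum count dropped).  Per-site SI
uses the site's own windowed samples; a population variant exists.  The
ratio form makes SI invariant to per-site affine response scaling.  When
within-speaker accuracy does not beat chance the result is flagged
unreliable but still returned.

**F-ratio and MDS.**  Discriminability is the pooled between-class /
within-class variance ratio; significance by label permutation
(p = (1+#{F_perm ≥ F})/(n+1)).  MDS minimises metric stress by SMACOF from
a classical-scaling initialisation and reports Kruskal stress-1.

## Spatial analysis

Along-gyrus distance is the signed projection of (ML, PA) coordinates onto
their first principal axis, origin at the most medial site, sign chosen so
distance grows medial→lateral; a near-isotropic cloud (eigenvalue ratio
< 1.2) triggers an instability warning.  2-D coordinates are the default
(3-D projection is a trivial extension but display maps are 2-D).  ML is
|distance to midsagittal| minus the cohort minimum.  KNN smoothing (k = 4,
self excluded, distance ties broken by site id) and barycentric
interpolation (masked outside the convex hull) are display-only; every
statistic runs on raw values.  Missing values (e.g. sites without the
sensitivity task) are imputed from the single nearest neighbour for
display only.  BF enters correlations and the joint PCA as log2 Hz —
frequency tuning is log-distributed and a linear-Hz axis would let a few
high-BF sites dominate.  The five feature columns are z-scored before PCA
(they mix Hz, ms and t-units; unscaled PCA would be unit-dominated), and
each component's sign is fixed so its largest-magnitude weight is
positive.  The best spatial direction of a PC projection is the canonical
correlation direction between (ML, PA) and the projection; with a
one-column response this reduces to the regression direction but is
computed through the general CCA form.  The random-Y control repeats the
fit with random projections: on an (approximately isotropic) site cloud
the resulting axial angles are uniform (Rayleigh test on doubled angles).
On a strongly elongated cloud they are provably *not* uniform — random-Y
directions concentrate along the cloud's minor axis because the direction
estimate is Σxx⁻¹Σxy — so the control is meaningful only where site
coverage is roughly two-dimensional, as in the pooled-cohort maps.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed and the
analyses are validated against its planted truth.

* **Stimulus.**  Spectrogram-domain synthesis (no vocoder): phones are
  laid down sequentially with log-normal durations (median ≈ 0.11 s,
  σ = 0.4, clipped to 40–400 ms — alignment-table phone statistics are not
  published for the source stories, so plausible English phone durations
  are used), occasional pauses, utterance-level speaker turns, 2–8 Hz
  syllabic amplitude modulation, harmonic stacks at each speaker's nominal
  pitch (92/104/174/191 Hz for the four default voices), and formant-like
  spectral envelopes.  A phone's spectrum is 75 % instance-specific
  (coarticulatory) variation and 25 % a fixed per-phoneme template.  This
  split matters: if phone identity were exactly recoverable from the
  spectrogram, any label-keyed response code would be linearly predictable
  from the lagged stimulus and would be absorbed into the estimated STRF,
  corrupting BF/latency recovery; with instance-dominated spectra the code
  stays (mostly) outside the linear span, as intended for a nonlinear
  phonetic response.  A −30 dB white spectrogram floor keeps the lagged
  autocorrelation well conditioned and stands in for room noise.
* **Responses.**  Causal convolution with a planted Gabor STRF (spectral
  Gaussian σ = 0.45 oct at the planted BF; temporal cosine at the planted
  rate under a Gaussian envelope centred at the planted latency), optional
  static nonlinearity (rectify / saturating tanh), a multiplicative speech
  gain on speech frames (the post-linear mechanism behind genuine speech
  sensitivity), additive phoneme-evoked code components in the 70–180 ms
  window, and white Gaussian noise calibrated to the requested SNR
  (empirically within ±0.1 dB).  Noise is white in time — the simplest
  model satisfying the estimator's assumptions — and the SNR, nonlinearity
  and code amplitudes are configurable.
* **Phoneme-evoked codes.**  Per site, unit-RMS smoothed random temporal
  kernels keyed by (attribute, value) [speaker-invariant code], by
  (attribute, value, speaker) [speaker-dependent code], and by speaker
  [identity code], mixed as α, 1−α, and speaker_code·(1−α) respectively
  (α = 1 ⇔ fully invariant).  Kernels are centred so the
  inventory-frequency-weighted mean over values is zero: only category
  *contrasts* are planted, not a common onset response that would leak
  into the stimulus-driven filter.  The identity code is off by default —
  a code tied to an audible speaker is itself partly stimulus-predictable
  and biases STRF estimates, exactly as strong speaker-specific responses
  would in vivo — and is enabled (speaker_code = 1) for speaker-decoding
  and discriminability analyses, which do not involve STRFs.  The default
  phonetic-code amplitude (0.8 × acoustic-response SD) keeps responses
  predominantly stimulus-driven while leaving the attributes decodable.
* **Gradient cohorts.**  Sites along a simulated gyrus axis (default 40°
  in the ML–PA plane, 20 mm span, 1.5 mm perpendicular jitter) with
  planted log-BF 4 kHz→300 Hz, latency 40→160 ms, BTM 12→3 Hz, α 0→1 and
  speech gain 1→3 plus jitter.  The joint-map fixture instead scatters
  sites isotropically over a patch with the gradients carried by the
  tuning values along a 45° axis, so the CCA direction is informative and
  the random-Y control is valid.
* **Sound set.**  Exactly 16 speech and 53 nonspeech trials, 1 s gaps, a
  leading silence segment.  Nonspeech trials draw from six families (tone
  complexes, fast AM noise, click/drum trains, sustained musical notes,
  frequency sweeps, drifting noise).  The published task used ≈13.5 s
  trials and 2 min of silence; that remains the default, while tests and
  the acceptance script use 2 s trials and 10 s silence to stay
  desk-scale — the statistic's degrees of freedom depend on trial counts,
  which are preserved, not on trial length.

**What passing tests show — and do not.**  Validation on this generator
establishes estimator correctness (parameter recovery, calibration of
significance machinery, directional effects under planted mechanisms), not
biological truth.  Real high-gamma is non-Gaussian and autocorrelated,
real phone codes are not additive random kernels, real electrode arrays
sample anatomy unevenly across subjects, and real effect sizes are far
smaller: published prediction correlations average ≈0.44 and map
correlations |r| ≈ 0.2–0.5, whereas planted-gradient cohorts reach
|r| > 0.8.  Sign patterns and calibration transfer; magnitudes do not.

## Problem sizes

Deliberate desk-scale choices: 60–180 s stimuli (vs 20–25 min sessions),
48–50-site cohorts (vs 132 electrodes), 2 s sensitivity trials, 100-fit
null calibrations.  The shared-design fitter makes these sizes effectively
free to increase; sizes are set where the validated quantities are already
stable across seeds.

## Known limitations

* The centroid BTM inherits an upward bias at the lowest rates from
  spectral leakage; it is bounded (≤ ~10 % for ≥ 2 Hz gratings) and
  identical across sites, so gradient analyses are unaffected.
* Per-site SI needs hundreds of phone instances; at 3-minute synthetic
  sessions its per-site scatter is ≈0.05–0.1.
* The acoustic front end's filter shapes are a parametric stand-in for a
  full cochlear model; tonotopic band assignment is exact at band centres
  and may be off by one band at band edges.
* No artifact rejection or re-referencing is provided; inputs are assumed
  clean.
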