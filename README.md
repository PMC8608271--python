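# hgmap

Feature-tuning and spatial-map analysis of speech-driven auditory-cortex
recordings, with a ground-truth synthetic data generator.

Human Heschl's gyrus (HG) contains the primary auditory cortex, and
intracranial recordings made while patients listen to natural speech show
graded changes in what individual sites encode along the gyrus: sites tuned
to high acoustic frequencies and fast temporal modulations sit
posteromedially, while anterolateral sites respond later, prefer speech
over other sounds, and represent phonemes in a more speaker-invariant way.
`hgmap` implements the full analysis chain needed to measure and map these
properties, for researchers who work with multichannel neural time series
(iEEG/ECoG) and continuous speech stimuli:

* **Acoustic front end** — a cochlear-style filterbank (128 asymmetric
  log-spaced filters, compressive nonlinearity, lateral inhibition via a
  rectified spectral derivative) pooled to a 16-band auditory spectrogram.
* **Neural front end** — high-gamma (70–150 Hz) envelope extraction:
  resampling to 500 Hz, 1 Hz high-pass, line-noise notches, eight analytic
  sub-band envelopes averaged and z-scored to prestimulus silence.
* **STRF estimation** — the spectrotemporal receptive field `w(lag, band)`
  minimising `||y − Xw||² + λ||w||²` on the lagged spectrogram `X`
  (normalized reverse correlation), with the ridge and sparseness
  parameters picked on 20 held-out contiguous folds, and electrode
  inclusion gated by a Benjamini–Hochberg-corrected t-test on the per-fold
  prediction correlations (p < 0.01, N = 20).
* **Tuning attributes** — best frequency (BF) and response latency as the
  power-weighted centre of the STRF's excitatory region; best temporal
  modulation (BTM) as the power-weighted rate centroid of a 2-D modulation
  (rate × scale) decomposition; speech sensitivity (SS) as the unpaired
  t statistic contrasting silence-normalised mean responses to speech vs
  nonspeech trials; and a speaker-invariance index
  SI = (leave-one-speaker-out phonetic decoding accuracy) / (within-speaker
  accuracy) computed with one-vs-rest regularized least-squares (RLS)
  classifiers.
* **Spatial analysis** — along-gyrus distance by principal-axis projection,
  k-nearest-neighbour display smoothing, piecewise-linear map
  interpolation, feature-vs-distance Pearson correlations, Wilcoxon
  rank-sum hemisphere comparisons, and a joint PCA over the five tuning
  maps whose dominant spatial direction is found by canonical correlation
  analysis (with a random-response control for direction bias).

Because patient recordings cannot be redistributed, the package ships a
first-class synthetic generator (`hgmap.synth`) that emulates every input:
speech-like spectrograms spoken by up to eight "voice actors" with nominal
pitches anchored at 92/104/174/191 Hz, forced-aligner-style phoneme tables
with five phonetic attributes, electrode geometries with planted tuning
gradients, responses driven by known Gabor STRFs with controllable SNR,
nonlinearity, speech gain and speaker-invariance mixing, and a
16-speech/53-nonspeech trial set with 1 s gaps and a silence baseline.
Every analysis is validated against this planted ground truth.

## Worked example

```python
import numpy as np
from hgmap import synth, strf, maps

# 48 sites along a simulated HG axis with planted tuning gradients
cohort = synth.generate_cohort(48, duration_s=120, seed=11,
                               plant_gradients=True)
resp = synth.generate_responses(cohort, snr_db=6.0)

design = strf.LaggedStimulusDesign(cohort.stimulus)
models = [design.fit(y) for y in resp]
flags, p, q = strf.include_electrodes(models)        # FDR-gated inclusion

bf, lat = zip(*(strf.extract_bf_latency(m) for m in models))
btm = [strf.compute_btm(strf.modulation_decompose(m)) for m in models]

fm = maps.FeatureMapSet(
    X=np.column_stack([bf, lat, btm]),
    coords=np.array([s.coords for s in cohort.sites]),
    feature_names=["bf", "latency", "btm"])
print(maps.gradient_report(fm)[["feature", "r", "p"]])
```

prints

```
   feature         r             p
0       bf -0.971705  1.781270e-30
1  latency  0.968641  1.835341e-29
2      btm -0.876616  3.230865e-16
```

i.e. with high- to low-frequency and fast-to-slow modulation gradients and
increasing latencies planted along the array's long axis, the estimated
best frequency and best temporal modulation correlate negatively with
along-axis distance and latency positively — the canonical
posteromedial-to-anterolateral pattern — each at p ≪ 0.01 despite 6 dB
SNR.  Adding the speaker-invariance and speech-sensitivity stages (see
`tests/test_acceptance.py::TestGradientSigns`) completes the five-feature
panel, and `maps.joint_pca` + `maps.cca_best_direction` recover the shared
gradient axis from the joint maps.

A thin CLI wraps the spatial report for exported tables:

```bash
hgmap maps --features tuning.tsv --coords sites.tsv --out report/
```

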