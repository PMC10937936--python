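# Methods

`vowelpap` re-implements, as a tested pipeline, an analysis that links vowel
acoustics to ultrasound-measured upper-airway narrowing in adults at high
risk of obstructive sleep apnea (OSA). Because the original recordings are
not deposited, the package is organised around a synthetic-cohort generator
whose defaults are parameterized by the published group statistics; every
downstream stage (preprocessing, feature extraction, statistics, estimation)
is exercised and validated against that generator's ground truth.

## Study design being emulated

Two groups of adults — 18 controls and 13 participants at high OSA risk,
labelled by the NoSAS score (high risk at ≥ 8 of 17 points) — sustain five
vowels (/i/ "see", /u/ "soo", /a/ "sah", /e/ "set", /o/ "so") while a
sonographer measures the parasagittal anterior–posterior (PAP) diameter of
the upper airway (five replicates, averaged) and a microphone records the
vowel at 15,300 Hz. Frontal vowels (/i/, /u/) widen the airway; back vowels
narrow it. The headline statistic is the per-participant See−Sah PAP delta,
which is markedly smaller in the high-risk group.

## Synthetic cohort generator (`vowelpap.synth`)

**Demographics.** Age, BMI and neck circumference are Gaussian per group
with the published means/SDs; sex and snoring are Bernoulli (sex odds from
the published M/F split; snoring prevalence 0.25 control / 0.75 high-risk —
not published, chosen as realistic). Profiles are rejection-sampled until
the NoSAS label matches the group. Two corrections keep the *accepted*
sample faithful to the published means: (a) age is drawn from a
left-truncated Gaussian (adults ≥ 18) whose location is solved so the
truncated mean equals the published mean; (b) a short deterministic
fixed-point calibration shifts the latent (age, BMI, NC) locations so that
the means *after* NoSAS rejection match the published values (which are
themselves conditional on the group label).

**PAP diameters.** Each participant carries a latent airway-openness
`z ~ N(0, 1)`. The PAP value in cell (group, vowel) is
`mean + sd·(ρ·z + √(1−ρ²)·ε)`, truncated at zero by an exact inverse-CDF
draw of the independent component (equivalent to resampling ε, but defined
for all z). The published /i/ and /a/ cells are used verbatim; /u/, /e/,
/o/ have no published statistics and interpolate between them, preserving
the frontal > back ordering and the group reversal on back vowels.
`ρ = pap_coupling = 0.95`: the published delta SDs (3.9 mm control, 5.3 mm
OSA) together with the cell SDs imply a within-person PAP correlation of
≈ 1.0 (in fact slightly above 1, i.e. the printed numbers are borderline
inconsistent under a Gaussian shared-factor model); 0.95 is the
near-boundary feasible choice and reproduces delta SDs of ≈ 4.3 / 5.7 mm.
Five sonographer replicates (SD 0.5 mm) are averaged per measurement.

**Vowel waveforms.** Source–filter synthesis: a Rosenberg-type glottal
flow pulse train at f0 (cycle-to-cycle jitter 0.5 %), differentiated, then
passed through a cascade of three impulse-invariant second-order resonators
at (F1, F2, F3) with bandwidths (80, 120, 160) Hz, a one-zero spectral-tilt
filter, and additive white noise at 30 dB SNR; peak-normalised to 0.5 full
scale, 0.6 s per vowel at 15,300 Hz. f0 and F2 cells for /i/ and /a/ use
the published group values; F1/F3 come from standard adult vowel tables
(the /u/ F3 default is 2650 Hz, the female-range table value, because the
male-range ≈ 2250 Hz sits in a region an order-8 LPC cannot separate from
the analysis band edge). The latent z enters F2 (correlation `coupling`,
default 0.6) and the spectral tilt, so the feature–PAP association the
statistics and the estimator look for is genuinely present and tunable by
one knob; `coupling = 0` severs it (used for null calibration).

## Preprocessing (`vowelpap.preprocess`, `vowelpap.textgrid`)

Recordings are sliced by PRAAT TextGrid annotations (own reader for the
full and short text formats; labelled intervals sliced half-open, empty
padding intervals skipped), resampled to 10,000 Hz by polyphase rational
resampling, and band-pass filtered 100–3000 Hz with a 5th-order Butterworth
applied forward–backward. Zero-phase filtering preserves segment-internal
timing for framing; only spectral magnitudes are used downstream, where the
doubled effective attenuation is harmless. Segments shorter than 0.2 s are
rejected with a warning (20 ms framing needs ≥ ~10 frames for stable
statistics).

## Feature extraction (`vowelpap.features`)

106 scalars per segment, fixed order (manifest in
`results/feature_manifest.txt`): pitch mean/SD (2); F1–F3 (3); band power,
relative power and spectral centroid in 10 bands (30); MFCC mean/SD for 13
coefficients (26); chroma mean/SD (24); spectral-contrast mean/SD in 7
bands (14); roll-off mean/SD (2); zero-crossing-rate mean/SD (2); spectral
skewness, kurtosis and entropy (3).

- **Pitch**: per 20 ms frame, the normalized cross-correlation function
  over lags spanning 60–400 Hz; candidates are NCCF local maxima ≥ 0.3
  with a mild lag penalty (so the fundamental beats its octave-down copy),
  selected by a Viterbi pass with an octave-jump penalty and an explicit
  unvoiced state; chosen lags refined by parabolic interpolation. Unvoiced
  frames are excluded; < 20 % voiced frames ⇒ NaN sentinel.
- **Formants**: per 20 ms Hamming frame after 0.97 pre-emphasis,
  autocorrelation LPC of order 8 via Levinson–Durbin; polynomial roots give
  (frequency, bandwidth) candidates; those in 90–4000 Hz with bandwidth
  < 400 Hz are kept, sorted ascending, first three taken; segment value is
  the frame median. When fewer than three candidates survive, the frame
  retries at a 700 Hz bandwidth cutoff: LPC-8 systematically inflates the
  F2 bandwidth to 450–650 Hz on close-formant vowels (/u/, low-F2 /i/),
  and without the fallback ~55 % of /u/ segments are lost; with it,
  failure rates are 0–7 % and the F2 median relative error is 0.6–3 %.
  Segments where > 50 % of frames fail yield the NaN sentinel.
- **Welch PSD**: 20 ms Hamming windows zero-padded to 512 FFT points, 90 %
  overlap, one-sided density. Band power integrates the density over bins
  with `lo ≤ f < hi` (so the six disjoint 500 Hz sub-bands partition the
  100–3000 Hz band exactly and their relative powers sum to 1); the dB
  reference is digital full scale (recordings are uncalibrated — only
  relative comparisons are meaningful). "Average power" is read as
  integrated band power rather than mean density; the two differ only by
  the bin-quantized band width, and the partition property holds exactly
  under this reading.
- **MFCC**: 26 HTK-mel triangular filters on the 512-point power spectrum,
  natural log with a 1e-10 floor, orthonormal DCT-II, first 13
  coefficients, aggregated to per-coefficient mean and SD. Validated to
  1 % against an independent straight-from-the-definition implementation.
- **Chroma / contrast / roll-off / ZCR**: pitch-class energy fractions per
  frame; octave-band peak-to-valley contrast (dB, 2 % quantiles); 85 %
  energy roll-off; crossings per sample. Spectral skewness, kurtosis
  (non-excess) and entropy (nats) treat the normalized 100–3000 Hz PSD as
  a distribution over frequency.

Missing values are NaN sentinels and are never imputed during extraction.

## Statistics (`vowelpap.stats`)

Every comparison is gated on Shapiro–Wilk normality at α = 0.05 (paired:
on the differences): parametric branch (paired/independent t) if normal,
rank branch (Wilcoxon signed-rank with Pratt zero handling / Mann–Whitney
U) otherwise; correlations are Pearson/Spearman under the same gate. The
vowel-wise PAP comparison is a one-way ANOVA; the See→Sah delta analysis
is a mixed-design (two-way repeated-measures) ANOVA with group between
subjects and vowel within subjects — its interaction term is the headline
"does the change differ by group" test, and with a balanced two-level
within factor it algebraically equals the squared unpaired t statistic on
per-subject deltas (used as a cross-check). No multiple-testing correction
is applied; raw p-values are reported, matching the original reporting
style. The underlying tests come from scipy and pingouin; this module owns
the gating, pairing, delta and table logic.

## PAP estimation (`vowelpap.estimator`)

Six-fold cross-validation (default `by_observation`: shuffled round-robin
deal, so 150 samples give exactly 125 train / 25 test per fold;
`by_participant` is offered as the leakage-safe alternative since vowels of
one participant are correlated). Step 1 fits four base regressors per
training split, each behind a median-imputation + standardization pipeline
fitted on training folds only:

- ordinary least squares linear regression;
- random forest (500 trees, unlimited depth);
- multilayer perceptron (64, 32 hidden units, ReLU, Adam, early stopping
  on a 10 % inner split, targets standardized);
- a 1-D convolutional network treating the 106-vector as an ordered
  sequence (conv blocks of 16 and 32 channels, kernel 5, max-pool 2, dense
  head of 32; implemented in numpy with Adam and early stopping).

Step 2 trains a random-forest combiner (500 trees, `min_samples_leaf=10`;
a 4-input meta-learner overfits at unlimited depth and can then trail the
best base model) on *out-of-fold* step-1 predictions:
for each fold, the combiner is fitted on the pooled out-of-fold predictions
of the other folds and applied to that fold, so neither step sees its
evaluation fold's targets. The leakage guard (label permutation) verifies
this empirically. Metrics are RMSE (mm) and the Pearson r of pooled
out-of-fold predictions, reported fold-wise (mean ± SD) and overall.

A known limitation: plain OLS does not generalize at 106 features per
~125 training rows (pooled out-of-fold r ≈ 0.4–0.6 on the default cohort,
with occasional large-error folds); it is kept unregularized because the
model family is part of the design, and the stacking combiner down-weights
it.

## What the generator does and does not emulate

It reproduces the group-level distributional structure (PAP cells and
deltas, f0/F2 group differences, a controllable acoustics–PAP coupling)
and realistic waveform properties (harmonic source, formant resonances,
jitter, noise). It does **not** model room acoustics or microphone
response, speaker-specific vocal-tract detail beyond three formants,
breathiness/shimmer, loudness variation, or any non-Gaussian shape of the
real cell distributions. Passing tests therefore demonstrate that the
pipeline is correct and unbiased under the published statistical structure
— not that the clinical effect sizes would replicate in new recordings.

## Numerical and design notes

- All randomness flows from one seed through named `SeedSequence` child
  streams per stage; reruns are byte-identical (neural stages under
  single-threaded execution).
- The NoSAS BMI is rounded to one decimal before banding; all criterion
  thresholds are inclusive.
- Wilcoxon uses the Pratt zero-difference convention; an all-zero
  difference vector short-circuits to p = 1.
- Problem sizes used by the test-suite recovery checks: 60 replicate
  cohorts for the PAP sampler statistics, 20 replicate cohorts of 13
  vowels for the end-to-end pitch/F2 recovery, 200 synthesized vowels for
  the formant-recovery corpus, 1,000 simulations per test for type-I
  calibration, 20 label permutations for the leakage guard, and 100
  replicate cohorts for the interaction power check.
- The estimator's per-fold inner seeds are derived from the run seed, so
  fold assignment, forest, and network initialisations are all
  reproducible.
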