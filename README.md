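# vowelpap

Vowel-acoustics estimation of upper-airway size for obstructive-sleep-apnea
(OSA) screening.

During vowel articulation the tongue reshapes the upper airway: frontal
vowels (/i/ "see", /u/ "soo") widen it, back vowels (/a/ "sah", /e/ "set",
/o/ "so") narrow it. In adults at high OSA risk the airway moves less — the
parasagittal anterior–posterior (PAP) diameter measured by submandibular
ultrasound changes less from "see" to "sah" than in controls — and that
restriction leaves an acoustic signature in the vowels themselves. This
package implements the full analysis pipeline behind that idea, for
researchers in biomedical acoustics and sleep medicine:

1. **`vowelpap.synth`** — a synthetic cohort generator (18 control + 13
   high-risk participants, NoSAS-consistent demographics, per-vowel PAP
   diameters, and source–filter vowel waveforms) parameterized by the
   published group statistics, so every stage is testable without any
   recordings;
2. **`vowelpap.preprocess` / `vowelpap.textgrid`** — WAV + PRAAT-TextGrid
   segment extraction, resampling to 10 kHz, 5th-order Butterworth
   band-pass 100–3000 Hz;
3. **`vowelpap.features`** — the 106-dimensional acoustic feature vector:
   pitch (normalized-cross-correlation tracker), F1–F3 (order-8 LPC), band
   power / relative power / spectral centroid in 10 bands (Welch PSD,
   20 ms Hamming, 512-point FFT, 90 % overlap), 13 MFCCs (mean + SD),
   chroma, spectral contrast, roll-off, zero-crossing rate, and spectral
   shape moments;
4. **`vowelpap.nosas`** — the NoSAS risk score (Neck ≥ 40 cm: 4; BMI
   25–30 / ≥ 30: 3 / 5; Snoring: 2; Age ≥ 55: 4; male Sex: 2; high risk at
   ≥ 8 of 17);
5. **`vowelpap.stats`** — normality-gated group comparisons, one-way
   ANOVA across vowels, the mixed-design repeated-measures ANOVA for the
   See−Sah delta, and the feature-vs-PAP correlation table;
6. **`vowelpap.estimator`** — six-fold cross-validated two-step stacked
   regression of PAP diameter from the 106 features (linear, random
   forest, neural network and 1-D CNN base models; random-forest combiner
   on out-of-fold predictions), evaluated by RMSE (mm) and Pearson *r*.

## Worked example

The analysis is driven by four numbered scripts, each writing its tables
under `results/`:

```bash
python analysis/01_simulate_cohort.py      # cohort tables (add --audio for WAVs)
python analysis/02_extract_features.py     # 106 features per vowel
python analysis/03_group_statistics.py     # deltas, ANOVA, correlations
python analysis/04_estimate_pap.py         # stacked CV estimation
```

A run with the default seeds prints (abridged):

```
cohort: 31 participants (18 control, 13 high-risk), 155 PAP measurements
PAP cells (mm):      control i 27.1±7.3   osa i 21.6±6.5
                     control a  4.4±2.2   osa a  7.0±2.7
pitch recovery: median |rel err| = 0.072%   (155/155 voiced)
F2 recovery:    median |rel err| = 1.561%   (149/155 defined)
See - Sah PAP delta (mm):  control 22.7±5.4   osa 14.6±4.3
group x vowel interaction: F = 20.0, p = 0.00011
F2 vs PAP during 'see': r = 0.81, p = 0.000 (pearson)
        model  overall_rmse  overall_r
       linear         10.50       0.56
random_forest          4.76       0.86
          ann          6.88       0.71
          cnn          7.68       0.62
      stacked          5.29       0.83
```

Reading this: the simulated control group closes its airway by ~23 mm from
"see" to "sah" while the high-risk group moves only ~15 mm, and the
mixed-ANOVA interaction flags that difference at p ≈ 1e-4. The feature
extractor recovers the generator's ground-truth pitch to < 0.1 % and F2 to
~1.6 % median error. Stacking the four base regressors estimates the
ultrasound PAP diameter from acoustics alone with an out-of-fold r of 0.83
and an RMSE of 5.3 mm — the same qualitative conclusion as the original
study (acoustics carry enough information to monitor airway size).

The same machinery runs on real data: point
`vowelpap.pipeline.PipelineConfig` (or `features_from_files`) at a
directory of WAV recordings plus PRAAT TextGrids with a labelled "vowel"
interval tier, and supply `demographics.csv` / `pap.csv` tables.

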