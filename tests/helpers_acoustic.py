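"""Shared independent oracles for acoustic tests.

Kept separate from the package so the checked code path never feeds the
expected values.
"""

import math

import numpy as np

from vowelpap.preprocess import preprocess_segment
from vowelpap.synth import synthesize_vowel
from vowelpap.types import VowelSegment, VowelSpec


def reference_mfcc(x, rate):
    """Straight-from-the-definition MFCC: explicit formulas, no shared
    helpers with the implementation.  Periodic Hamming window, 512-point
    power spectrum, 26 HTK-mel triangles, natural log (1e-10 floor),
    orthonormal DCT-II, 13 coefficients; per-coefficient mean and SD."""
    frame, hop, nfft, n_mels, n_out = 200, 100, 512, 26, 13
    win = np.array([0.54 - 0.46 * math.cos(2 * math.pi * n / frame)
                    for n in range(frame)])
    mel = lambda f: 2595.0 * math.log10(1.0 + f / 700.0)
    imel = lambda m: 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    edges = [imel(mel(0.0) + (mel(rate / 2) - mel(0.0)) * i / (n_mels + 1))
             for i in range(n_mels + 2)]
    bins = [i * rate / nfft for i in range(nfft // 2 + 1)]
    fb = np.zeros((n_mels, len(bins)))
    for m in range(n_mels):
        lo, mid, hi = edges[m], edges[m + 1], edges[m + 2]
        for j, f in enumerate(bins):
            if lo <= f <= mid:
                fb[m, j] = (f - lo) / (mid - lo)
            elif mid < f <= hi:
                fb[m, j] = (hi - f) / (hi - mid)
    ceps = []
    n_frames = 1 + (len(x) - frame) // hop
    for t in range(n_frames):
        fr = x[t * hop:t * hop + frame] * win
        spec = np.abs(np.fft.rfft(fr, nfft)) ** 2
        logmel = np.log(np.maximum(fb @ spec, 1e-10))
        c = np.empty(n_out)
        for k in range(n_out):
            s = sum(logmel[n] * math.cos(math.pi * k * (2 * n + 1) / (2 * n_mels))
                    for n in range(n_mels))
            c[k] = s * math.sqrt((1 if k == 0 else 2) / n_mels)
        ceps.append(c)
    ceps = np.array(ceps)
    return ceps.mean(axis=0), ceps.std(axis=0, ddof=1)


def synthesized_segment(f0=150.0, formants=(300.0, 2100.0, 2900.0), seed=0,
                        vowel="i", **kw):
    """Synthesize one vowel and run it through preprocessing."""
    spec = VowelSpec(vowel=vowel, f0=f0, formants=formants, **kw)
    wave = synthesize_vowel(spec, np.random.default_rng(seed))
    return preprocess_segment(VowelSegment("P", vowel, wave, spec.sample_rate))


def recovery_corpus(n=200, seed=404):
    """200 (segment, truth) pairs spanning the generator's vowel, pitch and
    formant ranges; truth is (f0, F1, F2, F3)."""
    from vowelpap.types import F1_F3_DEFAULTS, CohortParams

    params = CohortParams()
    rng = np.random.default_rng(seed)
    vowels = ["i", "u", "a", "e", "o"]
    groups = ["control", "osa"]
    out = []
    for i in range(n):
        vowel = vowels[i % 5]
        group = groups[(i // 5) % 2]
        f0 = float(np.clip(rng.normal(*params.f0_mean_sd[(group, vowel)]), 60, 400))
        f1d, f3d = F1_F3_DEFAULTS[vowel]
        f1 = float(np.clip(rng.normal(f1d, 40.0), 150, 900))
        f2 = float(np.clip(rng.normal(*params.f2_mean_sd[(group, vowel)]),
                           f1 + 250, 2850))
        f3 = float(np.clip(rng.normal(f3d, 120.0), f2 + 300, 4800))
        tilt = 0.2 + 0.2 * math.tanh(rng.standard_normal())
        seg = synthesized_segment(f0=f0, formants=(f1, f2, f3), vowel=vowel,
                                  seed=1000 + i, spectral_tilt=tilt)
        out.append((seg, (f0, f1, f2, f3)))
    return out
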