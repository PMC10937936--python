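"""The 106-scalar acoustic feature set for one vowel segment.

Inventory (fixed order, 106 scalars):

====================  =====  ==========================================
family                count  description
====================  =====  ==========================================
pitch mean/sd             2  NCCF (RAPT-style) tracker, 60-400 Hz
F1, F2, F3                3  LPC order 8 root formants, frame median
band power               10  integrated Welch power per band, dB re FS
relative power           10  band power / 100-3000 Hz power
spectral centroid        10  power-weighted mean frequency per band
MFCC mean/sd          13+13  13 cepstral coefficients, 26 mel filters
chroma mean/sd        12+12  pitch-class energy fractions
contrast mean/sd        7+7  per-band peak-to-valley spectral contrast, dB
roll-off mean/sd          2  85th-percentile-energy frequency
ZCR mean/sd               2  zero crossings per sample
skew/kurt/entropy         3  moments of the 100-3000 Hz PSD; entropy nats
====================  =====  ==========================================

All frame-based features use 20 ms windows; the Welch PSD uses a 20 ms
Hamming window zero-padded to 512 FFT points with 90 % overlap.  Missing
values (e.g. unvoiced pitch) are NaN sentinels, never imputed here.
"""

from __future__ import annotations

import warnings
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft
from scipy.signal import get_window, welch
from scipy.signal.windows import hamming

from .types import ANALYSIS_RATE, VowelSegment

# --- framing constants (at the 10 kHz analysis rate) ----------------------
FRAME_S = 0.020
HOP_S = 0.010
NFFT = 512
WELCH_OVERLAP = 0.90

# --- pitch tracker ---------------------------------------------------------
PITCH_FMIN = 60.0
PITCH_FMAX = 400.0
NCCF_VOICING_THRESHOLD = 0.30
#: minimum fraction of voiced frames for a defined pitch
MIN_VOICED_FRACTION = 0.20

# --- formants --------------------------------------------------------------
LPC_ORDER = 8
PREEMPHASIS = 0.97
FORMANT_FMIN = 90.0
FORMANT_FMAX = 4000.0
FORMANT_MAX_BW = 400.0
#: fallback cutoff for frames where fewer than three candidates survive the
#: strict bandwidth rule (close-formant vowels like /u/ inflate LPC-8
#: bandwidth estimates well past the true resonator bandwidths)
FORMANT_FALLBACK_BW = 700.0

#: The ten analysis bands: full band first, six disjoint 500 Hz sub-bands,
#: then three 1 kHz sub-bands.
DEFAULT_BANDS: Tuple[Tuple[float, float], ...] = (
    (100.0, 3000.0),
    (100.0, 500.0), (500.0, 1000.0), (1000.0, 1500.0),
    (1500.0, 2000.0), (2000.0, 2500.0), (2500.0, 3000.0),
    (100.0, 1000.0), (1000.0, 2000.0), (2000.0, 3000.0),
)

N_MFCC = 13
N_MELS = 26
N_CHROMA = 12
#: spectral-contrast octave band edges (Hz); 7 bands up to the 5 kHz Nyquist
CONTRAST_EDGES = (0.0, 100.0, 200.0, 400.0, 800.0, 1600.0, 3200.0, 5000.0)
CONTRAST_QUANTILE = 0.02
ROLLOFF_FRACTION = 0.85

_EPS = 1e-12


def _band_names() -> List[str]:
    return [f"{int(lo)}_{int(hi)}" for lo, hi in DEFAULT_BANDS]


FEATURE_NAMES: Tuple[str, ...] = tuple(
    ["pitch_mean", "pitch_sd", "F1", "F2", "F3"]
    + [f"band_power_{b}" for b in _band_names()]
    + [f"relative_power_{b}" for b in _band_names()]
    + [f"spectral_centroid_{b}" for b in _band_names()]
    + [f"mfcc_mean_{i}" for i in range(N_MFCC)]
    + [f"mfcc_sd_{i}" for i in range(N_MFCC)]
    + [f"chroma_mean_{i}" for i in range(N_CHROMA)]
    + [f"chroma_sd_{i}" for i in range(N_CHROMA)]
    + [f"contrast_mean_{i}" for i in range(7)]
    + [f"contrast_sd_{i}" for i in range(7)]
    + ["rolloff_mean", "rolloff_sd", "zcr_mean", "zcr_sd",
       "spectral_skewness", "spectral_kurtosis", "spectral_entropy"]
)
assert len(FEATURE_NAMES) == 106


def _check_segment(seg: VowelSegment) -> np.ndarray:
    x = np.asarray(seg.samples, dtype=np.float64)
    if len(x) / seg.sample_rate < 0.2:
        raise ValueError(
            f"{seg.participant_id}/{seg.vowel}: segment shorter than 0.2 s"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{seg.participant_id}/{seg.vowel}: non-finite samples")
    return x


def _frames(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    """(n_frames, frame) view of x; drops the tail."""
    n = 1 + (len(x) - frame) // hop
    if n < 1:
        return np.empty((0, frame))
    idx = np.arange(frame)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


# ---------------------------------------------------------------------------
# Pitch: normalized cross-correlation tracker with Viterbi continuity
# ---------------------------------------------------------------------------

def _nccf_frame(chunk: np.ndarray, window: int, lags: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of chunk[:window] against shifted copies."""
    base = chunk[:window]
    e0 = float(base @ base)
    out = np.empty(len(lags))
    for i, lag in enumerate(lags):
        shifted = chunk[lag:lag + window]
        e1 = float(shifted @ shifted)
        out[i] = float(base @ shifted) / np.sqrt(e0 * e1 + _EPS)
    return out


def estimate_pitch(seg: VowelSegment) -> Tuple[float, float]:
    """Frame-wise fundamental-frequency estimate, (mean, sd) in Hz.

    Per 20 ms frame the normalized cross-correlation function (NCCF) over
    lags spanning 60-400 Hz is peak-picked into candidates; a Viterbi pass
    with an octave-jump penalty and an explicit unvoiced state selects the
    track; chosen lags are refined by parabolic interpolation.  Unvoiced
    frames are excluded; if fewer than 20 % of frames are voiced the result
    is the (nan, nan) sentinel with a warning.
    """
    x = _check_segment(seg)
    rate = seg.sample_rate
    window = int(round(FRAME_S * rate))
    hop = int(round(HOP_S * rate))
    lag_min = int(np.floor(rate / PITCH_FMAX))
    lag_max = int(np.ceil(rate / PITCH_FMIN))
    chunk_len = window + lag_max + 1
    lags = np.arange(lag_min, lag_max + 1)

    chunks = _frames(x, chunk_len, hop)
    if len(chunks) == 0:
        warnings.warn(f"{seg.participant_id}/{seg.vowel}: too short for pitch")
        return (float("nan"), float("nan"))

    # Candidate generation: local NCCF maxima above the voicing threshold,
    # with a mild lag penalty so the fundamental beats its octave-down copy.
    cands: List[List[Tuple[float, float]]] = []  # per frame: (freq, merit)
    all_nccf = []
    for chunk in chunks:
        nccf = _nccf_frame(chunk, window, lags)
        all_nccf.append(nccf)
        peaks = np.flatnonzero(
            (nccf[1:-1] > nccf[:-2]) & (nccf[1:-1] >= nccf[2:])
            & (nccf[1:-1] >= NCCF_VOICING_THRESHOLD)
        ) + 1
        frame_cands = []
        for p in peaks:
            # parabolic refinement of the peak lag
            y0, y1, y2 = nccf[p - 1], nccf[p], nccf[p + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > _EPS else 0.0
            lag = lags[p] + float(np.clip(delta, -1, 1))
            merit = y1 - 0.10 * np.log2(lag / lag_min)
            frame_cands.append((rate / lag, float(merit)))
        frame_cands.sort(key=lambda fm: -fm[1])
        cands.append(frame_cands[:5])

    # Viterbi over candidates plus an unvoiced state.
    UNVOICED_COST = 0.65
    TRANS_VU = 0.20
    OCTAVE_W = 0.40
    n = len(cands)
    paths: List[List[Tuple[float, int]]] = []  # per frame: (cost, backpointer)
    states: List[List[float]] = []             # per frame: freq (nan=unvoiced)
    for t in range(n):
        freqs = [f for f, _ in cands[t]] + [float("nan")]
        local = [1.0 - m for _, m in cands[t]] + [UNVOICED_COST]
        if t == 0:
            paths.append([(lc, -1) for lc in local])
        else:
            row = []
            for j, fj in enumerate(freqs):
                best, arg = np.inf, -1
                for i, fi in enumerate(states[t - 1]):
                    prev = paths[t - 1][i][0]
                    if np.isnan(fi) and np.isnan(fj):
                        trans = 0.0
                    elif np.isnan(fi) or np.isnan(fj):
                        trans = TRANS_VU
                    else:
                        trans = OCTAVE_W * abs(np.log2(fj / fi))
                    cost = prev + trans
                    if cost < best:
                        best, arg = cost, i
                row.append((best + local[j], arg))
            paths.append(row)
        states.append(freqs)

    j = int(np.argmin([c for c, _ in paths[-1]]))
    track = []
    for t in range(n - 1, -1, -1):
        track.append(states[t][j])
        j = paths[t][j][1]
    track = np.array(track[::-1])

    voiced = track[~np.isnan(track)]
    if len(voiced) < MIN_VOICED_FRACTION * n:
        warnings.warn(
            f"{seg.participant_id}/{seg.vowel}: segment is unvoiced; "
            "pitch reported as NaN"
        )
        return (float("nan"), float("nan"))
    return (float(np.mean(voiced)), float(np.std(voiced, ddof=1)) if len(voiced) > 1 else 0.0)


# ---------------------------------------------------------------------------
# Formants: LPC-8 root solving per frame, median aggregation
# ---------------------------------------------------------------------------

def _levinson(r: np.ndarray, order: int) -> np.ndarray:
    """Levinson-Durbin recursion; returns LPC polynomial a (a[0] = 1)."""
    a = np.zeros(order + 1)
    a[0] = 1.0
    err = r[0]
    if err <= 0:
        raise np.linalg.LinAlgError("zero-energy frame")
    for i in range(1, order + 1):
        acc = r[i] + a[1:i] @ r[1:i][::-1]
        k = -acc / err
        a[1:i + 1] = np.concatenate([a[1:i] + k * a[1:i][::-1], [k]])
        err *= (1.0 - k * k)
        if err <= 0:
            raise np.linalg.LinAlgError("unstable recursion")
    return a


def _frame_formants(frame: np.ndarray, rate: int) -> List[float]:
    r = np.correlate(frame, frame, mode="full")[len(frame) - 1:len(frame) + LPC_ORDER]
    try:
        a = _levinson(r, LPC_ORDER)
    except np.linalg.LinAlgError:
        return []
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * rate / (2 * np.pi)
    bws = -np.log(np.abs(roots) + _EPS) * rate / np.pi
    in_range = (freqs > FORMANT_FMIN) & (freqs < FORMANT_FMAX)
    keep = in_range & (bws < FORMANT_MAX_BW)
    if keep.sum() < 3:
        keep = in_range & (bws < FORMANT_FALLBACK_BW)
    return sorted(freqs[keep])


def estimate_formants(seg: VowelSegment) -> Tuple[float, float, float]:
    """First three formant frequencies (Hz) via 8th-order LPC.

    Per 20 ms Hamming frame: pre-emphasis, autocorrelation LPC through
    Levinson-Durbin, polynomial roots -> candidate (frequency, bandwidth)
    pairs; candidates inside 90-4000 Hz with bandwidth < 400 Hz are kept,
    sorted ascending, and the first three taken.  The segment value is the
    per-formant median over frames; if more than half the frames yield fewer
    than three candidates the sentinel (nan, nan, nan) is returned.
    """
    x = _check_segment(seg)
    rate = seg.sample_rate
    x = np.append(x[0], x[1:] - PREEMPHASIS * x[:-1])
    frame = int(round(FRAME_S * rate))
    hop = int(round(HOP_S * rate))
    win = hamming(frame, sym=False)
    triples = []
    frames = _frames(x, frame, hop)
    for fr in frames:
        f = _frame_formants(fr * win, rate)
        if len(f) >= 3:
            triples.append(f[:3])
    if len(triples) <= 0.5 * len(frames) or not triples:
        warnings.warn(
            f"{seg.participant_id}/{seg.vowel}: formants undefined "
            f"({len(triples)}/{len(frames)} usable frames)"
        )
        return (float("nan"),) * 3
    med = np.median(np.array(triples), axis=0)
    return (float(med[0]), float(med[1]), float(med[2]))


# ---------------------------------------------------------------------------
# Welch PSD and band features
# ---------------------------------------------------------------------------

def welch_psd(seg: VowelSegment) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD: 20 ms Hamming windows zero-padded to 512 FFT
    points, 90 % overlap.  Returns (frequencies Hz, density 1/Hz)."""
    x = _check_segment(seg)
    nperseg = int(round(FRAME_S * seg.sample_rate))
    noverlap = int(round(WELCH_OVERLAP * nperseg))
    freqs, psd = welch(
        x, fs=seg.sample_rate, window=get_window("hamming", nperseg),
        nperseg=nperseg, noverlap=noverlap, nfft=NFFT,
        detrend=False, scaling="density",
    )
    return freqs, psd


def band_features(
    freqs: np.ndarray,
    psd: np.ndarray,
    bands: Sequence[Tuple[float, float]] = DEFAULT_BANDS,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-band (power dB, relative power, spectral centroid Hz).

    Band power integrates the density over the bins with lo <= f < hi
    (so the six disjoint sub-bands partition the full band exactly and
    their relative powers sum to 1); the dB reference is digital full
    scale.  Relative power divides by the 100-3000 Hz power; the centroid
    is the power-weighted mean frequency of the in-band bins.
    """
    full_lo, full_hi = DEFAULT_BANDS[0]
    if freqs[0] > full_lo or freqs[-1] < full_hi:
        raise ValueError("PSD grid does not cover 100-3000 Hz")
    df = freqs[1] - freqs[0]
    full_mask = (freqs >= full_lo) & (freqs < full_hi)
    total = float(np.sum(psd[full_mask]) * df)
    if total <= 0:
        raise ValueError("zero power in 100-3000 Hz")
    powers, rels, cents = [], [], []
    for lo, hi in bands:
        mask = (freqs >= lo) & (freqs < hi)
        p = float(np.sum(psd[mask]) * df)
        powers.append(10 * np.log10(p + _EPS))
        rels.append(p / total)
        w = psd[mask]
        s = float(np.sum(w))
        cents.append(float(np.sum(freqs[mask] * w) / s) if s > 0 else float("nan"))
    return np.array(powers), np.array(rels), np.array(cents)


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------

def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, nfft: int, rate: int,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular mel filterbank (HTK mel scale, unit-peak triangles) on the
    one-sided FFT grid; shape (n_mels, nfft//2 + 1)."""
    fmax = fmax if fmax is not None else rate / 2
    mels = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz = mel_to_hz(mels)
    bins = np.fft.rfftfreq(nfft, d=1.0 / rate)
    fb = np.zeros((n_mels, len(bins)))
    for m in range(1, n_mels + 1):
        lo, mid, hi = hz[m - 1], hz[m], hz[m + 1]
        up = (bins - lo) / (mid - lo + _EPS)
        down = (hi - bins) / (hi - mid + _EPS)
        fb[m - 1] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _power_frames(x: np.ndarray, rate: int) -> np.ndarray:
    frame = int(round(FRAME_S * rate))
    hop = int(round(HOP_S * rate))
    win = hamming(frame, sym=False)
    fr = _frames(x, frame, hop) * win
    return np.abs(rfft(fr, n=NFFT, axis=1)) ** 2


def mfcc_features(seg: VowelSegment) -> Tuple[np.ndarray, np.ndarray]:
    """Frame-wise 13-coefficient MFCCs aggregated to (mean[13], sd[13]).

    Pipeline per 20 ms Hamming frame: 512-point power spectrum, 26-filter
    triangular mel filterbank (HTK scale), natural log with floor,
    orthonormal DCT-II, first 13 coefficients.
    """
    x = _check_segment(seg)
    spec = _power_frames(x, seg.sample_rate)
    fb = mel_filterbank(N_MELS, NFFT, seg.sample_rate)
    mel_energy = spec @ fb.T
    log_mel = np.log(np.maximum(mel_energy, 1e-10))
    cep = dct(log_mel, type=2, norm="ortho", axis=1)[:, :N_MFCC]
    sd = cep.std(axis=0, ddof=1) if cep.shape[0] > 1 else np.zeros(N_MFCC)
    return cep.mean(axis=0), sd


# ---------------------------------------------------------------------------
# Chroma, contrast, roll-off, ZCR, spectral moments
# ---------------------------------------------------------------------------

def _chroma_map(nfft: int, rate: int) -> np.ndarray:
    """Pitch class (0-11, C = 0) of each positive FFT bin; -1 outside 100 Hz-Nyquist."""
    bins = np.fft.rfftfreq(nfft, d=1.0 / rate)
    pc = np.full(len(bins), -1)
    valid = bins >= 100.0
    midi = np.round(69.0 + 12.0 * np.log2(bins[valid] / 440.0)).astype(int)
    pc[valid] = midi % 12
    return pc


def misc_features(seg: VowelSegment, psd: Tuple[np.ndarray, np.ndarray] | None = None):
    """Chroma, spectral contrast, roll-off, ZCR, and PSD shape moments.

    Returns a dict of arrays/scalars: chroma mean/sd[12] (per-frame energy
    fractions over pitch classes), contrast mean/sd[7] (peak-to-valley dB in
    octave bands), rolloff mean/sd (85th-percentile-energy frequency, Hz),
    zcr mean/sd (crossings/sample), and spectral skewness / kurtosis /
    entropy (nats) of the normalized 100-3000 Hz Welch PSD treated as a
    probability distribution over frequency.
    """
    x = _check_segment(seg)
    rate = seg.sample_rate
    spec = _power_frames(x, rate)
    bins = np.fft.rfftfreq(NFFT, d=1.0 / rate)

    # chroma: energy fraction per pitch class, per frame
    pc = _chroma_map(NFFT, rate)
    chroma = np.zeros((spec.shape[0], N_CHROMA))
    for k in range(N_CHROMA):
        chroma[:, k] = spec[:, pc == k].sum(axis=1)
    chroma /= chroma.sum(axis=1, keepdims=True) + _EPS

    # spectral contrast: peak minus valley (dB) in octave-ish bands
    n_bands = len(CONTRAST_EDGES) - 1
    contrast = np.zeros((spec.shape[0], n_bands))
    for b in range(n_bands):
        mask = (bins >= CONTRAST_EDGES[b]) & (bins < CONTRAST_EDGES[b + 1])
        sub = np.sort(spec[:, mask], axis=1)
        k = max(1, int(np.ceil(CONTRAST_QUANTILE * sub.shape[1])))
        valley = sub[:, :k].mean(axis=1)
        peak = sub[:, -k:].mean(axis=1)
        contrast[:, b] = 10 * (np.log10(peak + _EPS) - np.log10(valley + _EPS))

    # roll-off: lowest frequency containing 85 % of frame energy
    cum = np.cumsum(spec, axis=1)
    total = cum[:, -1:]
    roll_idx = np.argmax(cum >= ROLLOFF_FRACTION * total, axis=1)
    rolloff = bins[roll_idx]

    # zero-crossing rate per frame (crossings/sample)
    frame = int(round(FRAME_S * rate))
    hop = int(round(HOP_S * rate))
    fr = _frames(x, frame, hop)
    signs = np.sign(fr)
    signs[signs == 0] = 1
    zcr = 0.5 * np.abs(np.diff(signs, axis=1)).mean(axis=1)

    # spectral shape of the whole-segment PSD restricted to 100-3000 Hz
    freqs, density = psd if psd is not None else welch_psd(seg)
    mask = (freqs >= 100.0) & (freqs < 3000.0)
    f, p = freqs[mask], density[mask]
    p = p / (p.sum() + _EPS)
    mu = float(np.sum(f * p))
    var = float(np.sum(p * (f - mu) ** 2))
    sigma = np.sqrt(var) + _EPS
    skew = float(np.sum(p * (f - mu) ** 3) / sigma**3)
    kurt = float(np.sum(p * (f - mu) ** 4) / sigma**4)
    entropy = float(-np.sum(p * np.log(p + _EPS)))

    def ms(a: np.ndarray):
        if a.shape[0] > 1:
            return a.mean(axis=0), a.std(axis=0, ddof=1)
        return a.mean(axis=0), np.zeros(a.shape[1]) if a.ndim > 1 else 0.0

    chroma_mean, chroma_sd = ms(chroma)
    contrast_mean, contrast_sd = ms(contrast)
    return {
        "chroma_mean": chroma_mean, "chroma_sd": chroma_sd,
        "contrast_mean": contrast_mean, "contrast_sd": contrast_sd,
        "rolloff_mean": float(rolloff.mean()),
        "rolloff_sd": float(rolloff.std(ddof=1)) if len(rolloff) > 1 else 0.0,
        "zcr_mean": float(zcr.mean()),
        "zcr_sd": float(zcr.std(ddof=1)) if len(zcr) > 1 else 0.0,
        "spectral_skewness": skew,
        "spectral_kurtosis": kurt,
        "spectral_entropy": entropy,
    }


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def extract_all(seg: VowelSegment) -> np.ndarray:
    """The full ordered 106-scalar feature vector for one segment.

    Missing-value sentinels (NaN) from constituent extractors propagate;
    they are never imputed at this stage.
    """
    try:
        pitch_mean, pitch_sd = estimate_pitch(seg)
        f1, f2, f3 = estimate_formants(seg)
        freqs, psd = welch_psd(seg)
        power, rel, cent = band_features(freqs, psd)
        mfcc_mean, mfcc_sd = mfcc_features(seg)
        misc = misc_features(seg, psd=(freqs, psd))
    except ValueError as exc:
        raise ValueError(f"{seg.participant_id}/{seg.vowel}: {exc}") from exc
    vec = np.concatenate([
        [pitch_mean, pitch_sd, f1, f2, f3],
        power, rel, cent,
        mfcc_mean, mfcc_sd,
        misc["chroma_mean"], misc["chroma_sd"],
        misc["contrast_mean"], misc["contrast_sd"],
        [misc["rolloff_mean"], misc["rolloff_sd"],
         misc["zcr_mean"], misc["zcr_sd"],
         misc["spectral_skewness"], misc["spectral_kurtosis"],
         misc["spectral_entropy"]],
    ])
    assert vec.shape == (106,)
    return vec


def extract_table(segments, groups: dict | None = None) -> pd.DataFrame:
    """Feature table: one row per segment, columns id/group/vowel + the 106
    features in fixed order."""
    rows = []
    for seg in segments:
        rec = {"participant_id": seg.participant_id,
               "group": (groups or {}).get(seg.participant_id, ""),
               "vowel": seg.vowel}
        rec.update(dict(zip(FEATURE_NAMES, extract_all(seg))))
        rows.append(rec)
    return pd.DataFrame(rows, columns=["participant_id", "group", "vowel", *FEATURE_NAMES])
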