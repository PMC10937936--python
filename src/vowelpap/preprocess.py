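"""Segment extraction and signal conditioning.

Raw recordings (any rate >= 6 kHz) are sliced by their TextGrid vowel
annotations, resampled to the 10 kHz analysis rate, and band-pass filtered
100-3000 Hz with a 5th-order Butterworth applied forward-backward, so only
in-band structure reaches the feature extractor.
"""

from __future__ import annotations

import logging
import warnings
from fractions import Fraction
from pathlib import Path
from typing import List, Optional

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, resample_poly, sosfiltfilt

from .textgrid import read_textgrid
from .types import ANALYSIS_RATE, VOWELS, VowelSegment

logger = logging.getLogger(__name__)

MIN_DURATION_S = 0.2
BAND_HZ = (100.0, 3000.0)
FILTER_ORDER = 5


def read_wav(path: str | Path) -> tuple[int, np.ndarray]:
    """Read a WAV file as (rate, mono float in [-1, 1])."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return int(rate), data


def read_segments(
    audio: str | Path,
    annotations: str | Path,
    tier: str = "vowel",
    participant_id: Optional[str] = None,
) -> List[VowelSegment]:
    """Slice one recording into raw vowel segments by its TextGrid.

    Labelled intervals on the given tier are sliced half-open
    [start, end); PRAAT's empty-text padding intervals are skipped.  The
    participant id defaults to the WAV stem up to the last ``_`` (the
    ``<pid>_<vowel>.wav`` naming convention) or the full stem.
    """
    audio = Path(audio)
    rate, data = read_wav(audio)
    tiers = {t.name: t for t in read_textgrid(annotations)}
    if tier not in tiers:
        raise ValueError(f"{annotations}: no interval tier named {tier!r}")
    if participant_id is None:
        stem = audio.stem
        participant_id = stem.rsplit("_", 1)[0] if "_" in stem else stem

    labelled = [(lo, hi, txt) for lo, hi, txt in tiers[tier].intervals if txt.strip()]
    if not labelled:
        warnings.warn(f"{annotations}: tier {tier!r} has no labelled intervals")
        return []
    for (lo1, hi1, t1), (lo2, hi2, t2) in zip(labelled, labelled[1:]):
        if lo2 < hi1 - 1e-9:
            raise ValueError(
                f"{annotations}: intervals [{lo1}, {hi1}] {t1!r} and "
                f"[{lo2}, {hi2}] {t2!r} overlap"
            )

    segments: List[VowelSegment] = []
    total = len(data) / rate
    for lo, hi, label in labelled:
        label = label.strip()
        if label not in VOWELS:
            raise ValueError(
                f"{annotations}: interval [{lo}, {hi}] has unknown vowel "
                f"label {label!r} (expected one of {VOWELS})"
            )
        if hi > total + 1e-9:
            raise ValueError(
                f"{annotations}: interval [{lo}, {hi}] {label!r} extends past "
                f"audio end ({total:.3f} s)"
            )
        i0 = int(round(lo * rate))
        i1 = int(round(hi * rate))
        segments.append(
            VowelSegment(
                participant_id=participant_id, vowel=label,
                samples=data[i0:i1], sample_rate=rate, source_span=(lo, hi),
            )
        )
    return segments


def bandpass_sos(rate: int = ANALYSIS_RATE):
    return butter(FILTER_ORDER, BAND_HZ, btype="bandpass", output="sos", fs=rate)


def preprocess_segment(seg: VowelSegment) -> VowelSegment:
    """Resample a raw segment to 10 kHz and band-pass 100-3000 Hz.

    The Butterworth filter is applied forward-backward (zero-phase) so
    segment-internal timing is preserved for framing; only spectral
    magnitudes are used downstream, where the doubled effective attenuation
    is harmless.  Raises on input rates below 6 kHz (Nyquist below the upper
    band edge) and on segments shorter than 0.2 s.
    """
    if seg.sample_rate < 6000:
        raise ValueError(
            f"sample rate {seg.sample_rate} Hz too low: need >= 6000 Hz"
        )
    x = np.asarray(seg.samples, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{seg.participant_id}/{seg.vowel}: non-finite samples")
    if seg.sample_rate != ANALYSIS_RATE:
        frac = Fraction(ANALYSIS_RATE, seg.sample_rate)
        x = resample_poly(x, frac.numerator, frac.denominator)
    if len(x) / ANALYSIS_RATE < MIN_DURATION_S:
        raise ValueError(
            f"{seg.participant_id}/{seg.vowel}: segment shorter than "
            f"{MIN_DURATION_S} s after resampling"
        )
    x = sosfiltfilt(bandpass_sos(), x)
    return VowelSegment(
        participant_id=seg.participant_id, vowel=seg.vowel,
        samples=x, sample_rate=ANALYSIS_RATE, source_span=seg.source_span,
    )


def preprocess_all(segments: List[VowelSegment]) -> List[VowelSegment]:
    """Preprocess a batch, dropping too-short segments with a logged warning."""
    out = []
    for seg in segments:
        try:
            out.append(preprocess_segment(seg))
        except ValueError as exc:
            if "shorter than" in str(exc):
                logger.warning("dropping segment: %s", exc)
            else:
                raise
    return out
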