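"""Synthetic cohort generator.

Emulates the study conditions end to end so the whole pipeline is testable
without recordings: group-specific demographics consistent with the NoSAS
labels, per-participant-per-vowel PAP airway diameters, and source-filter
vowel waveforms whose ground-truth parameters (f0, formants) are drawn from
the published group statistics.

A per-participant latent "airway openness" z ~ N(0, 1) is shared between the
PAP sampler and the acoustic sampler, so the feature-PAP association the
downstream statistics and estimator look for is actually present in the
synthetic data and its strength is controlled by a single coupling knob.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import lfilter

from .nosas import nosas_score
from .textgrid import write_textgrid
from .types import (
    F1_F3_DEFAULTS,
    F1_SD,
    F3_SD,
    VOWELS,
    CohortParams,
    ParticipantProfile,
    PapMeasurement,
    VowelSpec,
)

# Group demographic distributions (means +- SD) matching the study cohort:
# age in years, BMI in kg/m2, neck circumference in cm; sex as P(male) from
# the reported M/F split; snoring prevalence chosen as a realistic default
# (not reported per group).
DEMOGRAPHICS = {
    "control": {
        "age": (35.11, 11.97),
        "bmi": (24.73, 3.74),
        "nc": (33.59, 5.64),
        "p_male": 5 / 18,
        "p_snoring": 0.25,
    },
    "osa": {
        "age": (54.54, 11.59),
        "bmi": (33.29, 5.77),
        "nc": (34.21, 3.30),
        "p_male": 7 / 13,
        "p_snoring": 0.75,
    },
}

_MAX_REJECTION_ATTEMPTS = 10_000


class RejectionError(RuntimeError):
    """Raised when rejection sampling cannot satisfy a constraint."""


@lru_cache(maxsize=None)
def _mean_preserving_mu(target_mean: float, sd: float, lo: float) -> float:
    """Location of a left-truncated Gaussian whose truncated mean equals
    ``target_mean``.  The adult-age floor (>= 18 y) would otherwise inflate
    the accepted-sample mean above the configured group mean."""
    from scipy.optimize import brentq
    from scipy.stats import norm

    def truncated_mean(mu):
        a = (lo - mu) / sd
        return mu + sd * norm.pdf(a) / norm.sf(a)

    if truncated_mean(target_mean) - target_mean < 1e-6:
        return target_mean
    return float(brentq(lambda mu: truncated_mean(mu) - target_mean,
                        target_mean - 6 * sd, target_mean))


def _draw_profile(group: str, locs, rng: np.random.Generator,
                  participant_id: str) -> ParticipantProfile:
    """One rejection-sampled profile using the given (age, bmi, nc) latent
    locations."""
    d = DEMOGRAPHICS[group]
    age_loc, bmi_loc, nc_loc = locs
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        age = int(round(rng.normal(age_loc, d["age"][1])))
        bmi = rng.normal(bmi_loc, d["bmi"][1])
        nc = rng.normal(nc_loc, d["nc"][1])
        sex = "M" if rng.random() < d["p_male"] else "F"
        snoring = bool(rng.random() < d["p_snoring"])
        if age < 18 or bmi <= 10 or nc <= 20:
            continue
        profile = ParticipantProfile(
            participant_id=participant_id, group=group, sex=sex,
            age=age, bmi=bmi, neck_circumference=nc, snoring=snoring,
        )
        if nosas_score(profile).high_risk == (group == "osa"):
            return profile
    raise RejectionError(
        f"could not draw a NoSAS-consistent {group!r} profile in "
        f"{_MAX_REJECTION_ATTEMPTS} attempts; demographic parameterization "
        "is inconsistent with the group label"
    )


@lru_cache(maxsize=None)
def _calibrated_locs(group: str) -> Tuple[float, float, float]:
    """Latent (age, bmi, nc) locations such that the *accepted* sample means
    match the published group means.

    The published demographics describe participants conditional on their
    NoSAS classification, so the rejection step shifts naive Gaussian
    means (e.g. accepted controls skew younger).  A short deterministic
    fixed-point iteration absorbs that shift.
    """
    d = DEMOGRAPHICS[group]
    targets = np.array([d["age"][0], d["bmi"][0], d["nc"][0]])
    locs = np.array([
        _mean_preserving_mu(d["age"][0], d["age"][1], 17.5),
        d["bmi"][0], d["nc"][0],
    ])
    rng = np.random.default_rng(1_234_567)  # calibration is deterministic
    for _ in range(3):
        draws = np.array([
            [
                (p := _draw_profile(group, tuple(locs), rng, "CAL")).age,
                p.bmi, p.neck_circumference,
            ]
            for _ in range(6000)
        ])
        locs = locs + (targets - draws.mean(axis=0))
    return tuple(float(v) for v in locs)


def generate_participant(
    group: str,
    rng: np.random.Generator,
    participant_id: str = "P000",
) -> ParticipantProfile:
    """Draw one participant whose NoSAS classification matches ``group``.

    Demographics are sampled from calibrated group-specific Gaussians /
    Bernoullis and rejection-sampled until the NoSAS constraint holds: a
    control profile must score < 8, a high-risk profile >= 8.
    """
    if group not in DEMOGRAPHICS:
        raise ValueError(f"unknown group {group!r}")
    return _draw_profile(group, _calibrated_locs(group), rng, participant_id)


def sample_pap(
    group: str,
    vowel: str,
    params: CohortParams,
    rng: np.random.Generator,
    participant_id: str = "P000",
    latent_z: float = 0.0,
) -> PapMeasurement:
    """Draw one averaged PAP measurement for a (group, vowel) cell.

    The participant's true diameter is Gaussian in the cell with correlation
    ``params.pap_coupling`` to the latent openness z, truncated at zero by
    resampling the independent component.  Five sonographer replicates are
    drawn around the true value and averaged, mirroring the measurement
    protocol.
    """
    key = (group, vowel)
    if key not in params.pap_mean_sd:
        raise KeyError(f"no PAP parameterization for cell {key}")
    mean, sd = params.pap_mean_sd[key]
    rho = params.pap_coupling if sd > 0 else 0.0
    mu = mean + sd * rho * latent_z
    sigma = sd * math.sqrt(1.0 - rho**2)
    if sigma == 0:
        if mu <= 0:
            raise RejectionError(f"PAP cell {key} collapses to {mu} mm (> 0 required)")
        value = mu
    else:
        # exact inverse-CDF draw from N(mu, sigma) truncated at zero
        # (equivalent to resampling the independent component until > 0)
        from scipy.stats import norm

        u = rng.random()
        # eps | eps > a with a = -mu/sigma:  eps = isf((1-u) * sf(a))
        value = mu + sigma * float(norm.isf((1.0 - u) * norm.sf(-mu / sigma)))
        if not np.isfinite(value) or value <= 0:
            value = max(mu, 0.0) + 1e-9
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        reps = value + params.replicate_noise_mm * rng.standard_normal(5)
        if reps.mean() > 0:
            break
    return PapMeasurement(
        participant_id=participant_id, vowel=vowel,
        pap_mm=float(reps.mean()), replicate_values=tuple(float(r) for r in reps),
    )


# ---------------------------------------------------------------------------
# Source-filter vowel synthesis
# ---------------------------------------------------------------------------

def _rosenberg_pulse(n: int, open_frac: float = 0.4, close_frac: float = 0.16) -> np.ndarray:
    """One Rosenberg-type glottal flow cycle of ``n`` samples."""
    n_open = max(1, int(round(open_frac * n)))
    n_close = max(1, int(round(close_frac * n)))
    pulse = np.zeros(n)
    t1 = np.arange(n_open) / n_open
    pulse[:n_open] = 0.5 * (1 - np.cos(np.pi * t1))
    t2 = np.arange(n_close) / n_close
    stop = min(n, n_open + n_close)
    pulse[n_open:stop] = np.cos(0.5 * np.pi * t2)[: stop - n_open]
    return pulse


def _resonator_coeffs(freq: float, bandwidth: float, rate: float) -> Tuple[np.ndarray, np.ndarray]:
    """Impulse-invariant two-pole resonator with unity DC gain."""
    r = math.exp(-math.pi * bandwidth / rate)
    theta = 2 * math.pi * freq / rate
    b1 = 2 * r * math.cos(theta)
    b2 = -(r**2)
    a0 = 1 - b1 - b2
    return np.array([a0]), np.array([1.0, -b1, -b2])


def synthesize_vowel(spec: VowelSpec, rng: np.random.Generator) -> np.ndarray:
    """Render one sustained vowel as a mono float waveform.

    A Rosenberg glottal pulse train at ``spec.f0`` (with small cycle-to-cycle
    jitter) is differentiated and passed through a cascade of three
    second-order resonators at the requested formants; white Gaussian noise is
    added at ``spec.noise_snr`` dB.  The peak amplitude is normalised to 0.5
    full scale.  Deterministic for a fixed rng state.
    """
    rate = spec.sample_rate
    if max(spec.formants) >= rate / 2:
        raise ValueError("formant at or above Nyquist")
    n_target = int(round(spec.duration * rate))
    source = np.zeros(n_target)
    pos = 0
    while pos < n_target:
        period = rate / spec.f0
        if spec.jitter > 0:
            period *= 1.0 + spec.jitter * (2 * rng.random() - 1)
        n = max(4, int(round(period)))
        cycle = _rosenberg_pulse(n)
        end = min(pos + n, n_target)
        source[pos:end] = cycle[: end - pos]
        pos += n
    # Differentiate the flow: the radiating source is closer to dU/dt.
    source = np.diff(source, prepend=0.0)

    out = source
    for freq, bw in zip(spec.formants, spec.formant_bandwidths):
        b, a = _resonator_coeffs(freq, bw, rate)
        out = lfilter(b, a, out)
    if spec.spectral_tilt != 0.0:
        out = lfilter(np.array([1.0, -spec.spectral_tilt]), np.array([1.0]), out)

    if np.isfinite(spec.noise_snr):
        sig_power = float(np.mean(out**2))
        noise_power = sig_power / 10 ** (spec.noise_snr / 10)
        out = out + rng.standard_normal(len(out)) * math.sqrt(noise_power)

    peak = float(np.max(np.abs(out)))
    if peak > 0:
        out = out * (0.5 / peak)
    return out


# ---------------------------------------------------------------------------
# Whole-cohort generation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """In-memory synthetic cohort with ground-truth sidecar."""

    params: CohortParams
    profiles: List[ParticipantProfile]
    measurements: List[PapMeasurement]
    specs: Dict[Tuple[str, str], VowelSpec]
    waveforms: Dict[Tuple[str, str], np.ndarray]
    latent: Dict[str, float] = field(default_factory=dict)

    def demographics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [p.participant_id for p in self.profiles],
                "group": [p.group for p in self.profiles],
                "sex": [p.sex for p in self.profiles],
                "age": [p.age for p in self.profiles],
                "bmi": [p.bmi for p in self.profiles],
                "neck_circumference": [p.neck_circumference for p in self.profiles],
                "snoring": [p.snoring for p in self.profiles],
            }
        )

    def pap_frame(self) -> pd.DataFrame:
        group = {p.participant_id: p.group for p in self.profiles}
        return pd.DataFrame(
            {
                "participant_id": [m.participant_id for m in self.measurements],
                "group": [group[m.participant_id] for m in self.measurements],
                "vowel": [m.vowel for m in self.measurements],
                "pap_mm": [m.pap_mm for m in self.measurements],
            }
        )

    def sidecar_frame(self) -> pd.DataFrame:
        """Ground truth: latent z and every synthesis parameter."""
        pap = {(m.participant_id, m.vowel): m.pap_mm for m in self.measurements}
        rows = []
        for (pid, vowel), spec in self.specs.items():
            rows.append(
                {
                    "participant_id": pid,
                    "vowel": vowel,
                    "z": self.latent[pid],
                    "f0": spec.f0,
                    "F1": spec.formants[0],
                    "F2": spec.formants[1],
                    "F3": spec.formants[2],
                    "spectral_tilt": spec.spectral_tilt,
                    "pap_mm": pap[(pid, vowel)],
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> Path:
        """Write WAVs (16-bit PCM), TextGrids, CSV tables and the config."""
        outdir = Path(outdir)
        audio_dir = outdir / "audio"
        tg_dir = outdir / "textgrid"
        audio_dir.mkdir(parents=True, exist_ok=True)
        tg_dir.mkdir(parents=True, exist_ok=True)
        pad = int(round(0.1 * self.params.sample_rate))
        for (pid, vowel), wave in self.waveforms.items():
            padded = np.concatenate([np.zeros(pad), wave, np.zeros(pad)])
            pcm = np.clip(padded * 32767.0, -32768, 32767).astype(np.int16)
            wavfile.write(audio_dir / f"{pid}_{vowel}.wav", self.params.sample_rate, pcm)
            total = len(padded) / self.params.sample_rate
            start = pad / self.params.sample_rate
            end = start + len(wave) / self.params.sample_rate
            write_textgrid(
                tg_dir / f"{pid}_{vowel}.TextGrid",
                tier_name="vowel",
                intervals=[(start, end, vowel)],
                xmax=total,
            )
        self.demographics_frame().to_csv(outdir / "demographics.csv", index=False)
        self.pap_frame().to_csv(outdir / "pap.csv", index=False)
        self.sidecar_frame().to_csv(outdir / "ground_truth.csv", index=False)
        with open(outdir / "cohort_config.txt", "w") as fh:
            for k in ("n_control", "n_osa", "coupling", "pap_coupling",
                      "replicate_noise_mm", "duration", "noise_snr",
                      "sample_rate", "seed"):
                fh.write(f"{k} = {getattr(self.params, k)}\n")
        return outdir


def _truncated_normal(mean: float, sd: float, lo: float, hi: float,
                      rng: np.random.Generator) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RejectionError(f"N({mean}, {sd}) never hit [{lo}, {hi}]")


def generate_cohort(params: CohortParams | None = None,
                    with_audio: bool = True) -> Cohort:
    """Generate the full synthetic cohort: profiles, PAPs, waveforms, sidecar.

    Fully reproducible from ``params.seed``; every stage draws from a named
    child stream so adding participants does not perturb earlier ones.
    ``with_audio=False`` skips waveform synthesis (identical profiles, PAPs
    and specs, empty waveform dict) for sampling-only studies.
    """
    params = params or CohortParams()
    root = np.random.SeedSequence(params.seed)
    demo_ss, latent_ss, pap_ss, acoustic_ss, audio_ss = root.spawn(5)
    demo_rng = np.random.default_rng(demo_ss)
    latent_rng = np.random.default_rng(latent_ss)
    pap_rng = np.random.default_rng(pap_ss)
    ac_rng = np.random.default_rng(acoustic_ss)
    audio_rng = np.random.default_rng(audio_ss)

    profiles: List[ParticipantProfile] = []
    measurements: List[PapMeasurement] = []
    specs: Dict[Tuple[str, str], VowelSpec] = {}
    waveforms: Dict[Tuple[str, str], np.ndarray] = {}
    latent: Dict[str, float] = {}

    groups = ["control"] * params.n_control + ["osa"] * params.n_osa
    c = params.coupling
    for idx, group in enumerate(groups):
        pid = f"P{idx:03d}"
        profiles.append(generate_participant(group, demo_rng, pid))
        z = float(latent_rng.standard_normal())
        latent[pid] = z
        for vowel in VOWELS:
            measurements.append(
                sample_pap(group, vowel, params, pap_rng, pid, latent_z=z)
            )
            f0_mean, f0_sd = params.f0_mean_sd[(group, vowel)]
            f0 = _truncated_normal(f0_mean, f0_sd, 60.0, 400.0, ac_rng)
            f1_mean, f3_mean = F1_F3_DEFAULTS[vowel]
            f1 = _truncated_normal(f1_mean, F1_SD, 150.0, 900.0, ac_rng)
            # F2 keeps the coupled latent term; only the independent part is
            # resampled to respect F1 < F2 < F3 ordering.
            f2_mean, f2_sd = params.f2_mean_sd[(group, vowel)]
            f2 = -1.0
            for _ in range(_MAX_REJECTION_ATTEMPTS):
                eps = ac_rng.standard_normal()
                f2 = f2_mean + f2_sd * (c * z + math.sqrt(1 - c**2) * eps)
                if f1 + 250.0 <= f2 <= 2850.0:
                    break
            if not (f1 + 250.0 <= f2 <= 2850.0):
                raise RejectionError(f"F2 cell {(group, vowel)} incompatible with F1={f1:.0f}")
            f3 = _truncated_normal(f3_mean, F3_SD, f2 + 300.0, 0.48 * params.sample_rate, ac_rng)
            tilt = 0.2 + 0.2 * math.tanh(c * z)
            spec = VowelSpec(
                vowel=vowel, f0=f0, formants=(f1, f2, f3),
                duration=params.duration, noise_snr=params.noise_snr,
                sample_rate=params.sample_rate, spectral_tilt=tilt,
            )
            specs[(pid, vowel)] = spec
            if with_audio:
                waveforms[(pid, vowel)] = synthesize_vowel(spec, audio_rng)

    return Cohort(params=params, profiles=profiles, measurements=measurements,
                  specs=specs, waveforms=waveforms, latent=latent)
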