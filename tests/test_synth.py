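"""Synthetic-cohort generator tests: distributional recovery, NoSAS
consistency, waveform structure, determinism."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps
from scipy.signal import welch

from vowelpap import synth
from vowelpap.nosas import nosas_score
from vowelpap.synth import (
    RejectionError,
    generate_cohort,
    generate_participant,
    sample_pap,
    synthesize_vowel,
)
from vowelpap.types import VOWELS, CohortParams, VowelSpec


class TestGenerateParticipant:
    def test_nosas_consistency_by_construction(self, rng):
        for group, expect_high in (("control", False), ("osa", True)):
            for _ in range(200):
                p = generate_participant(group, rng)
                assert nosas_score(p).high_risk is expect_high
                assert p.age >= 18

    def test_repeatable_under_same_stream(self):
        p1 = generate_participant("osa", np.random.default_rng(5))
        p2 = generate_participant("osa", np.random.default_rng(5))
        assert p1 == p2

    def test_control_age_distribution_recovered(self):
        """Mean age of 10,000 accepted control draws stays within 3 SE of
        the configured 35.11 y (NoSAS rejection sampling introduces a small
        systematic shift, so the looser distributional-recovery bound
        applies)."""
        rng = np.random.default_rng(99)
        ages = np.array([generate_participant("control", rng).age
                         for _ in range(10_000)], dtype=float)
        se = ages.std(ddof=1) / np.sqrt(len(ages))
        assert abs(ages.mean() - 35.11) <= 3 * se

    def test_infeasible_parameterization_raises(self, rng, monkeypatch):
        bad = dict(synth.DEMOGRAPHICS)
        bad["control"] = {
            "age": (80.0, 0.1), "bmi": (45.0, 0.1), "nc": (55.0, 0.1),
            "p_male": 1.0, "p_snoring": 1.0,
        }  # always scores 17 -> can never be a control
        monkeypatch.setattr(synth, "DEMOGRAPHICS", bad)
        synth._calibrated_locs.cache_clear()
        try:
            with pytest.raises(RejectionError, match="control"):
                generate_participant("control", rng)
        finally:
            synth._calibrated_locs.cache_clear()


class TestSamplePap:
    def _analytic_mean(self, mean, sd, rho, n_grid=4001):
        """Independent oracle: E[pap] under the scheme 'draw z ~ N(0,1),
        then resample the independent component until the value is
        positive', by numerical integration over z."""
        z = np.linspace(-8, 8, n_grid)
        mu_z = mean + sd * rho * z
        sig = sd * np.sqrt(1 - rho**2)
        a = mu_z / sig
        cond_mean = mu_z + sig * sps.norm.pdf(a) / sps.norm.cdf(a)
        return float(np.trapezoid(cond_mean * sps.norm.pdf(z), z))

    def test_control_see_mean_recovered(self, rng):
        params = CohortParams()
        draws = np.array([
            sample_pap("control", "i", params, rng,
                       latent_z=float(rng.standard_normal())).pap_mm
            for _ in range(10_000)
        ])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 26.9) <= 2 * se

    def test_osa_sah_mean_matches_truncation_oracle(self, rng):
        """For the low-mean OSA 'sah' cell the zero-truncation shifts the
        sampler mean by ~0.04 mm; the empirical mean must match the
        integral oracle, and the oracle must stay within 0.1 mm of the
        configured 6.3 mm (mean-preserving resampling, approximately)."""
        params = CohortParams()
        oracle = self._analytic_mean(6.3, 2.5, params.pap_coupling)
        assert abs(oracle - 6.3) < 0.1
        draws = np.array([
            sample_pap("osa", "a", params, rng,
                       latent_z=float(rng.standard_normal())).pap_mm
            for _ in range(10_000)
        ])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - oracle) <= 3 * se

    def test_zero_sd_is_degenerate(self, rng):
        params = CohortParams()
        params.pap_mean_sd[("control", "i")] = (26.9, 0.0)
        for _ in range(5):
            m = sample_pap("control", "i",
                           dataclasses.replace(params, replicate_noise_mm=0.0),
                           rng, latent_z=2.0)
            assert m.pap_mm == pytest.approx(26.9, abs=1e-12)

    def test_replicates_average_to_value(self, rng):
        m = sample_pap("control", "i", CohortParams(), rng)
        assert np.mean(m.replicate_values) == pytest.approx(m.pap_mm, rel=1e-12)
        assert len(m.replicate_values) == 5

    def test_missing_cell_is_error(self, rng):
        params = CohortParams(pap_mean_sd={("control", "i"): (26.9, 6.0)})
        with pytest.raises(KeyError, match="osa"):
            sample_pap("osa", "a", params, rng)


class TestSynthesizeVowel:
    def test_periodicity_matches_f0(self, rng):
        spec = VowelSpec(vowel="a", f0=200.0, formants=(700.0, 1200.0, 2500.0),
                         noise_snr=np.inf, jitter=0.0)
        w = synthesize_vowel(spec, rng)
        # autocorrelation-based period estimate
        ac = np.correlate(w, w, mode="full")[len(w) - 1:]
        lo, hi = int(spec.sample_rate / 400), int(spec.sample_rate / 100)
        lag = lo + int(np.argmax(ac[lo:hi]))
        assert abs(lag - spec.sample_rate / 200.0) <= 1.0

    def test_spectrum_peaks_near_formants(self, rng):
        formants = (300.0, 2100.0, 2900.0)
        spec = VowelSpec(vowel="i", f0=130.0, formants=formants,
                         noise_snr=np.inf, duration=1.0)
        w = synthesize_vowel(spec, rng)
        f, p = welch(w, fs=spec.sample_rate, nperseg=8192)
        for target in formants:
            sel = (f > target - 150) & (f < target + 150)
            peak = f[sel][np.argmax(p[sel])]
            assert abs(peak - target) <= 50.0

    def test_amplitude_and_duration_contract(self, rng):
        spec = VowelSpec(vowel="o", f0=150.0, formants=(500.0, 1000.0, 2400.0))
        w = synthesize_vowel(spec, rng)
        assert np.max(np.abs(w)) == pytest.approx(0.5, rel=1e-9)
        assert abs(len(w) / spec.sample_rate - spec.duration) \
            <= 1.0 / spec.f0 + 1.0 / spec.sample_rate

    def test_deterministic_under_seed(self):
        spec = VowelSpec(vowel="e", f0=180.0, formants=(550.0, 1750.0, 2500.0))
        w1 = synthesize_vowel(spec, np.random.default_rng(3))
        w2 = synthesize_vowel(spec, np.random.default_rng(3))
        assert np.array_equal(w1, w2)

    def test_formant_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            VowelSpec(vowel="i", f0=120.0, formants=(300.0, 2100.0, 2600.0),
                      sample_rate=5000)


class TestGenerateCohort:
    def test_default_cohort_shape(self, default_cohort):
        assert len(default_cohort.profiles) == 31
        assert len(default_cohort.waveforms) == 155
        assert len(default_cohort.measurements) == 155
        assert default_cohort.sidecar_frame().shape[0] == 155

    def test_all_profiles_nosas_consistent(self, default_cohort):
        for p in default_cohort.profiles:
            assert nosas_score(p).high_risk is (p.group == "osa")

    def test_single_participant_cohort(self):
        cohort = generate_cohort(CohortParams(n_control=1, n_osa=0, seed=2))
        assert len(cohort.waveforms) == 5
        assert sorted(v for _, v in cohort.waveforms) == sorted(VOWELS)

    def test_zero_coupling_decouples_f2_from_pap(self):
        """With coupling = 0, ground-truth F2 carries no information about
        PAP: a permutation test on the pooled cells is non-significant."""
        cohort = generate_cohort(CohortParams(coupling=0.0, seed=21),
                                 with_audio=False)
        side = cohort.sidecar_frame()
        # within-cell z-scores so vowel/group structure cannot correlate
        f2 = side.groupby(["vowel"])["F2"].transform(lambda s: (s - s.mean()) / s.std())
        pap = side.groupby(["vowel"])["pap_mm"].transform(lambda s: (s - s.mean()) / s.std())
        obs = np.corrcoef(f2, pap)[0, 1]
        rng = np.random.default_rng(0)
        perm = np.array([
            np.corrcoef(rng.permutation(f2), pap)[0, 1] for _ in range(2000)
        ])
        p_value = np.mean(np.abs(perm) >= abs(obs))
        assert p_value > 0.01

    def test_determinism_byte_identical(self):
        params = CohortParams(n_control=2, n_osa=2, seed=33)
        c1 = generate_cohort(params)
        c2 = generate_cohort(CohortParams(n_control=2, n_osa=2, seed=33))
        assert c1.sidecar_frame().equals(c2.sidecar_frame())
        for key in c1.waveforms:
            assert np.array_equal(c1.waveforms[key], c2.waveforms[key])

    def test_write_outputs(self, small_cohort, tmp_path):
        out = small_cohort.write(tmp_path / "cohort")
        wavs = sorted((out / "audio").glob("*.wav"))
        tgs = sorted((out / "textgrid").glob("*.TextGrid"))
        assert len(wavs) == len(tgs) == 35
        for name in ("demographics.csv", "pap.csv", "ground_truth.csv",
                     "cohort_config.txt"):
            assert (out / name).exists()
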