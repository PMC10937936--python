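"""End-to-end pipeline: synthesize -> extract -> score -> compare -> estimate.

Ties the stages together with file I/O and a single global seed fanned out
to named child streams, so a rerun with an identical configuration
reproduces every CSV byte for byte (the neural stages under single-threaded
execution).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .estimator import stacked_cv
from .features import FEATURE_NAMES, extract_table
from .nosas import score_table
from .preprocess import preprocess_all, read_segments
from .stats import (
    anova_one_way,
    anova_two_way_rm,
    correlate_features,
    delta_table,
    select_test,
)
from .synth import Cohort, generate_cohort
from .types import VOWELS, CohortParams

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run depends on.

    ``audio_dir``/``textgrid_dir`` point at real recordings; when they are
    None a synthetic cohort with ``cohort`` parameters is generated instead.
    """

    out_dir: str = "results/pipeline"
    audio_dir: Optional[str] = None
    textgrid_dir: Optional[str] = None
    cohort: CohortParams = field(default_factory=CohortParams)
    fold_mode: str = "by_observation"
    n_folds: int = 6
    seed: int = 0
    write_audio: bool = False

    def config_hash(self) -> str:
        blob = repr(dataclasses.asdict(self))  # insertion order is stable
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def features_from_cohort(cohort: Cohort) -> pd.DataFrame:
    """Run preprocessing + feature extraction on every cohort waveform."""
    from .types import VowelSegment

    groups = {p.participant_id: p.group for p in cohort.profiles}
    segments = [
        VowelSegment(participant_id=pid, vowel=vowel, samples=wave,
                     sample_rate=cohort.params.sample_rate)
        for (pid, vowel), wave in cohort.waveforms.items()
    ]
    return extract_table(preprocess_all(segments), groups=groups)


def features_from_files(audio_dir: str | Path, textgrid_dir: str | Path) -> pd.DataFrame:
    """Extract features from on-disk WAV + TextGrid pairs."""
    audio_dir, textgrid_dir = Path(audio_dir), Path(textgrid_dir)
    segments = []
    for wav in sorted(audio_dir.glob("*.wav")):
        tg = textgrid_dir / (wav.stem + ".TextGrid")
        if not tg.exists():
            raise FileNotFoundError(f"no TextGrid for {wav.name}: expected {tg}")
        segments.extend(read_segments(wav, tg))
    return extract_table(preprocess_all(segments))


def comparison_tables(features: pd.DataFrame, pap: pd.DataFrame):
    """The group-statistics stage: vowel-wise ANOVA, See/Sah group
    comparisons, See-Sah delta mixed ANOVA, and the correlation cells."""
    comparisons = []

    by_vowel = {v: g["pap_mm"].to_numpy() for v, g in pap.groupby("vowel")}
    res = anova_one_way(by_vowel)
    comparisons.append({"comparison": "pap_across_vowels", "test": res.test_used,
                        "statistic": res.statistic, "p": res.p})

    for vowel in ("i", "a"):
        sub = pap[pap["vowel"] == vowel]
        ctrl = sub[sub["group"] == "control"]["pap_mm"].to_numpy()
        osa = sub[sub["group"] == "osa"]["pap_mm"].to_numpy()
        res = select_test(ctrl, osa, paired=False)
        comparisons.append({"comparison": f"pap_{vowel}_control_vs_osa",
                            "test": res.test_used, "statistic": res.statistic,
                            "p": res.p})

    deltas = delta_table(pap)
    long = pap[pap["vowel"].isin(["i", "a"])]
    mixed = anova_two_way_rm(long, dv="pap_mm")
    comparisons.append({"comparison": "pap_delta_group_x_vowel_interaction",
                        "test": "mixed_anova",
                        "statistic": mixed.interaction.statistic,
                        "p": mixed.interaction.p})

    cells = correlate_features(features, pap, feature_columns=list(FEATURE_NAMES))
    corr = pd.DataFrame([dataclasses.asdict(c) for c in cells])
    return pd.DataFrame(comparisons), deltas, corr


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the output directory.

    Outputs: features.csv, nosas.csv, pap.csv, comparisons.csv, deltas.csv,
    correlation_matrix.csv, estimation.csv, metrics.csv and a JSON run
    manifest (config hash, seed, package version).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    est_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)

    if config.audio_dir is not None:
        features = features_from_files(config.audio_dir, config.textgrid_dir)
        pap = pd.read_csv(Path(config.audio_dir).parent / "pap.csv")
        demographics = pd.read_csv(Path(config.audio_dir).parent / "demographics.csv")
    else:
        cohort_params = dataclasses.replace(config.cohort, seed=config.seed)
        logger.info("generating synthetic cohort (seed=%d)", config.seed)
        cohort = generate_cohort(cohort_params)
        if config.write_audio:
            cohort.write(out / "cohort")
        features = features_from_cohort(cohort)
        pap = cohort.pap_frame()
        demographics = cohort.demographics_frame()

    nosas = score_table(demographics)
    comparisons, deltas, corr = comparison_tables(features, pap)

    merged = features.merge(pap[["participant_id", "vowel", "pap_mm"]],
                            on=["participant_id", "vowel"])
    X = merged[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = merged["pap_mm"].to_numpy(dtype=float)
    result = stacked_cv(X, y, seed=est_seed, mode=config.fold_mode,
                        groups=merged["participant_id"].to_numpy())
    estimation = merged[["participant_id", "vowel", "pap_mm"]].copy()
    for name, pred in result.predictions.items():
        estimation[f"pred_{name}"] = pred
    estimation["fold"] = result.fold_plan.assignment + 1

    features.to_csv(out / "features.csv", index=False)
    nosas.to_csv(out / "nosas.csv", index=False)
    pap.to_csv(out / "pap.csv", index=False)
    comparisons.to_csv(out / "comparisons.csv", index=False)
    deltas.to_csv(out / "deltas.csv", index=False)
    corr.to_csv(out / "correlation_matrix.csv", index=False)
    estimation.to_csv(out / "estimation.csv", index=False)
    result.metrics_table().to_csv(out / "metrics.csv", index=False)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_feature_rows": int(len(features)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
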