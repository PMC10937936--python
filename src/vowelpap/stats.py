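"""Group-comparison statistics and feature-PAP correlations.

Every comparison is gated on normality (Shapiro-Wilk at alpha = 0.05):
normal data get the parametric test (paired/independent t), non-normal
data the rank test (Wilcoxon signed-rank with Pratt zero handling /
Mann-Whitney U).  Correlations are Pearson when both variables pass the
gate, Spearman otherwise.  All p-values are two-tailed; no multiple-testing
correction is applied (raw p-values are reported, matching the original
analysis style).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    statistic_name: str         # "t" | "W" | "U" | "F"
    statistic: float
    p: float
    test_used: str
    n: tuple
    direction: int              # sign of (mean(x) - mean(y)), 0 for ANOVA


def _is_normal(x: np.ndarray) -> bool:
    if np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue >= SHAPIRO_ALPHA


def select_test(x: Sequence[float], y: Sequence[float], paired: bool) -> ComparisonResult:
    """Two-sample comparison with a normality-gated choice of test.

    Paired data: Shapiro-Wilk on the differences; paired t-test if normal,
    else Wilcoxon signed-rank (Pratt zero-difference handling).  Unpaired:
    Shapiro-Wilk on each sample; independent t-test if both pass, else
    Mann-Whitney U.  All-zero paired differences short-circuit to p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per sample")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        raise ValueError("both samples are identical constants; nothing to test")
    direction = int(np.sign(np.mean(x) - np.mean(y)))
    if paired:
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        d = x - y
        if np.all(d == 0):
            return ComparisonResult("W", 0.0, 1.0, "wilcoxon", (len(x), len(y)), 0)
        if _is_normal(d):
            res = sps.ttest_rel(x, y)
            return ComparisonResult("t", float(res.statistic), float(res.pvalue),
                                    "paired_t", (len(x), len(y)), direction)
        res = sps.wilcoxon(x, y, zero_method="pratt", alternative="two-sided")
        return ComparisonResult("W", float(res.statistic), float(res.pvalue),
                                "wilcoxon", (len(x), len(y)), direction)
    if _is_normal(x) and _is_normal(y):
        res = sps.ttest_ind(x, y)
        return ComparisonResult("t", float(res.statistic), float(res.pvalue),
                                "independent_t", (len(x), len(y)), direction)
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return ComparisonResult("U", float(res.statistic), float(res.pvalue),
                            "mann_whitney", (len(x), len(y)), direction)


def anova_one_way(groups: Dict[str, Sequence[float]]) -> ComparisonResult:
    """One-way ANOVA across vowels (or any keyed cells)."""
    if len(groups) < 2:
        raise ValueError("need at least two cells")
    arrays = []
    for key, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 2:
            raise ValueError(f"cell {key!r} has fewer than 2 values")
        arrays.append(vals)
    if np.ptp(np.concatenate(arrays)) == 0:
        return ComparisonResult("F", 0.0, 1.0, "anova_one_way",
                                tuple(len(a) for a in arrays), 0)
    res = sps.f_oneway(*arrays)
    f = float(res.statistic)
    if not np.isfinite(f):  # zero within-cell variance, equal means
        f = 0.0
    return ComparisonResult("F", f, float(res.pvalue) if np.isfinite(res.pvalue) else 1.0,
                            "anova_one_way", tuple(len(a) for a in arrays), 0)


@dataclass(frozen=True)
class MixedAnovaResult:
    group: ComparisonResult
    vowel: ComparisonResult
    interaction: ComparisonResult


def anova_two_way_rm(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "vowel",
    between: str = "group",
    subject: str = "participant_id",
) -> MixedAnovaResult:
    """Mixed-design (two-way repeated-measures) ANOVA.

    ``between`` is the between-subjects factor (group), ``within`` the
    within-subjects factor (vowel condition); subjects missing any within
    level are excluded listwise with a warning.  The interaction term is
    the headline "does the See->Sah change differ by group" test.
    """
    df = data[[subject, between, within, dv]].dropna()
    n_levels = df[within].nunique()
    counts = df.groupby(subject)[within].nunique()
    complete = counts[counts == n_levels].index
    dropped = set(df[subject]) - set(complete)
    if dropped:
        warnings.warn(f"excluding subjects missing a condition: {sorted(dropped)}")
        df = df[df[subject].isin(complete)]
    aov = pg.mixed_anova(data=df, dv=dv, within=within, between=between,
                         subject=subject)
    aov = aov.set_index("Source")
    n_between = df.groupby(between)[subject].nunique()

    def row(source: str) -> ComparisonResult:
        r = aov.loc[source]
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        return ComparisonResult("F", float(r["F"]), float(r[p_col]),
                                "mixed_anova", tuple(int(v) for v in n_between), 0)

    return MixedAnovaResult(
        group=row(between), vowel=row(within), interaction=row("Interaction"),
    )


@dataclass(frozen=True)
class CorrelationCell:
    feature: str
    vowel: str
    r: float
    p: float
    method: str
    n: int


def correlate_features(
    features: pd.DataFrame,
    pap: pd.DataFrame,
    feature_columns: Optional[Sequence[str]] = None,
) -> List[CorrelationCell]:
    """Feature-vs-PAP correlation, one cell per feature x vowel.

    Tables join on (participant_id, vowel).  Pearson when both variables
    pass the Shapiro-Wilk gate, Spearman otherwise.  Constant or
    insufficient features yield NaN cells with a warning.
    """
    merged = features.merge(
        pap[["participant_id", "vowel", "pap_mm"]],
        on=["participant_id", "vowel"], how="inner",
    )
    if feature_columns is None:
        skip = {"participant_id", "group", "vowel", "pap_mm"}
        feature_columns = [c for c in features.columns if c not in skip]
    cells: List[CorrelationCell] = []
    for vowel, sub in merged.groupby("vowel"):
        target = sub["pap_mm"].to_numpy(dtype=float)
        for col in feature_columns:
            vals = sub[col].to_numpy(dtype=float)
            ok = np.isfinite(vals) & np.isfinite(target)
            v, t = vals[ok], target[ok]
            if len(v) < 3 or np.ptp(v) == 0 or np.ptp(t) == 0:
                warnings.warn(f"feature {col!r} / vowel {vowel!r}: constant or "
                              "insufficient data; correlation undefined")
                cells.append(CorrelationCell(col, vowel, float("nan"),
                                             float("nan"), "none", len(v)))
                continue
            if _is_normal(v) and _is_normal(t):
                r, p = sps.pearsonr(v, t)
                method = "pearson"
            else:
                r, p = sps.spearmanr(v, t)
                method = "spearman"
            cells.append(CorrelationCell(col, vowel, float(r), float(p), method, len(v)))
    return cells


def correlation_matrix(cells: List[CorrelationCell]) -> pd.DataFrame:
    """Pivot correlation cells to a feature x vowel matrix of r values."""
    df = pd.DataFrame([{"feature": c.feature, "vowel": c.vowel, "r": c.r}
                       for c in cells])
    return df.pivot(index="feature", columns="vowel", values="r")


def delta_table(values: pd.DataFrame, value_col: str = "pap_mm",
                see: str = "i", sah: str = "a") -> pd.DataFrame:
    """Per-participant See-minus-Sah deltas of one quantity.

    Input is long (participant_id, group, vowel, value); output has one row
    per participant with value_see, value_sah and delta = see - sah.
    """
    wide = values.pivot_table(index=["participant_id", "group"],
                              columns="vowel", values=value_col).reset_index()
    if see not in wide.columns or sah not in wide.columns:
        raise ValueError(f"need both {see!r} and {sah!r} conditions")
    out = wide[["participant_id", "group"]].copy()
    out["value_see"] = wide[see]
    out["value_sah"] = wide[sah]
    out["delta"] = out["value_see"] - out["value_sah"]
    return out.dropna(subset=["delta"]).reset_index(drop=True)
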