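"""NoSAS score for obstructive-sleep-apnea risk.

NoSAS (Neck circumference, obesity, Snoring, Age, Sex) is an additive
screening score: 4 points for neck circumference >= 40 cm, 3 points for
25 <= BMI < 30 kg/m2 or 5 points for BMI >= 30 kg/m2, 2 points for reported
snoring, 4 points for age >= 55 years, and 2 points for male sex.  The score
ranges 0-17; a score >= 8 flags a high probability of OSA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import pandas as pd

from .types import ParticipantProfile

HIGH_RISK_THRESHOLD = 8
MAX_SCORE = 17


@dataclass(frozen=True)
class NosasResult:
    score: int
    high_risk: bool
    components: Dict[str, int]


def nosas_points(
    *,
    neck_circumference: float,
    bmi: Optional[float] = None,
    snoring: bool,
    age: float,
    sex: str,
    height_m: Optional[float] = None,
    weight_kg: Optional[float] = None,
) -> NosasResult:
    """Score the five NoSAS criteria.

    BMI may be given directly or computed from height and weight; it is
    rounded to one decimal before banding so that band-edge ties are
    resolved on the rounded value (clinical convention).  All thresholds
    are inclusive: NC >= 40, BMI bands [25, 30) and [30, inf), age >= 55.
    """
    for name, value in (("neck_circumference", neck_circumference),
                        ("snoring", snoring), ("age", age), ("sex", sex)):
        if value is None:
            raise ValueError(f"missing NoSAS input: {name}")
    if bmi is None:
        if height_m is None or weight_kg is None:
            raise ValueError("missing NoSAS input: bmi (or height_m and weight_kg)")
        bmi = weight_kg / height_m**2
    if bmi <= 0 or neck_circumference <= 0:
        raise ValueError("bmi and neck_circumference must be positive")
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")

    bmi = round(float(bmi), 1)
    components = {
        "nc": 4 if neck_circumference >= 40.0 else 0,
        "bmi": 5 if bmi >= 30.0 else (3 if bmi >= 25.0 else 0),
        "snoring": 2 if snoring else 0,
        "age": 4 if age >= 55 else 0,
        "sex": 2 if sex == "M" else 0,
    }
    score = sum(components.values())
    return NosasResult(score=score, high_risk=score >= HIGH_RISK_THRESHOLD,
                       components=components)


def nosas_score(profile: ParticipantProfile) -> NosasResult:
    """Score a :class:`ParticipantProfile`."""
    return nosas_points(
        neck_circumference=profile.neck_circumference,
        bmi=profile.bmi,
        snoring=profile.snoring,
        age=profile.age,
        sex=profile.sex,
    )


def score_table(demographics: pd.DataFrame) -> pd.DataFrame:
    """Score a demographics table (columns: participant_id, sex, age, bmi,
    neck_circumference, snoring) and return it with `nosas` and `high_risk`
    columns appended."""
    out = demographics.copy()
    results = [
        nosas_points(
            neck_circumference=row.neck_circumference,
            bmi=row.bmi,
            snoring=bool(row.snoring),
            age=row.age,
            sex=row.sex,
        )
        for row in out.itertuples()
    ]
    out["nosas"] = [r.score for r in results]
    out["high_risk"] = [r.high_risk for r in results]
    return out
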