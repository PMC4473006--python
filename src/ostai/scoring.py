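"""The OSTAi index, its risk categories, and the NOF 2013 referral rule.

OSTAi is an OSTA-style self-assessment index for Taiwanese postmenopausal
women: raw = 0.2 * (weight in kg - age in years), rounded to an integer.
Risk categories: low (value >= -1), medium (-4 < value < -1), high
(value <= -4). A woman screens positive for DXA referral when her integer
value is strictly below the cutoff (default -1), so the at-cutoff value is
negative and the low-risk band is exactly the non-referral side.

The NOF 2013 comparator refers every woman aged 65+, and younger
postmenopausal women with any of: BMI < 18.5 kg/m^2, prior fragility
fracture, high-risk medication (glucocorticoids), or a condition associated
with bone loss (rheumatoid arthritis, secondary osteoporosis). Missing
questionnaire answers never fire a criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from .cohort import Participant
from .errors import DomainError

#: Risk factors that qualify a woman under 65 for referral under NOF 2013.
#: Smoking and alcohol are FRAX factors but not NOF referral triggers.
NOF_RISK_FACTORS = (
    "previous_fracture",
    "glucocorticoids",
    "rheumatoid_arthritis",
    "secondary_osteoporosis",
)

NOF_BMI_THRESHOLD = 18.5
NOF_AGE_THRESHOLD = 65.0
DEFAULT_CUTOFF = -1


def round_half_away(x):
    """Round to the nearest integer, ties away from zero (-1.5 -> -2).

    Inputs are pre-rounded to 9 decimals so that exact .5 ties survive the
    float summation order (index scores are multiples of 0.02 in exact
    arithmetic, far coarser than the guard).
    """
    x = np.round(np.asarray(x, dtype=float), 9)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out if out.ndim else float(out)


def _to_integer(raw, rounding: str):
    if rounding == "nearest":
        return round_half_away(raw)
    if rounding == "truncate":  # original OSTA convention
        raw = np.asarray(raw, dtype=float)
        out = np.trunc(raw)
        return out if out.ndim else float(out)
    raise DomainError(f"unknown rounding mode {rounding!r}")


def categorize(value) -> Union[str, np.ndarray]:
    """Risk category for an integer index value; exhaustive and exclusive."""
    v = np.asarray(value)
    cat = np.where(v >= -1, "low", np.where(v <= -4, "high", "medium"))
    return cat if cat.ndim else str(cat)


@dataclass
class OstaiScore:
    """raw = 0.2*(weight - age); value = rounded integer; category per the
    -1 / -4 cutpoints."""

    raw: float
    value: int
    category: str


@dataclass
class ScreeningDecision:
    """Outcome of one screening rule for one participant."""

    rule: str
    positive: bool
    triggers: tuple = ()
    not_evaluable: tuple = field(default_factory=tuple)


def ostai_score(age: float, weight: float, rounding: str = "nearest") -> OstaiScore:
    """Compute the OSTAi index from age (years) and body weight (kg)."""
    if age is None or weight is None or not (age > 0 and weight > 0):
        raise DomainError(f"age and weight must be positive, got age={age}, weight={weight}")
    raw = 0.2 * (weight - age)
    value = int(_to_integer(raw, rounding))
    return OstaiScore(raw=raw, value=value, category=categorize(value))


def ostai_decision(score: OstaiScore, cutoff: int = DEFAULT_CUTOFF) -> ScreeningDecision:
    """Positive (refer for DXA) iff the integer value is strictly below the cutoff."""
    if int(cutoff) != cutoff:
        raise DomainError(f"cutoff must be an integer, got {cutoff!r}")
    return ScreeningDecision(rule="ostai", positive=score.value < cutoff)


def classify_nof2013(p: Participant) -> ScreeningDecision:
    """NOF 2013 referral decision with the list of criteria that fired.

    Age >= 65 is sufficient. Under 65, any qualifying risk factor refers;
    if BMI cannot be computed the BMI criterion is recorded as not
    evaluable and the remaining criteria are still checked.
    """
    if p.age is None:
        raise DomainError(f"participant {p.id}: age required for NOF 2013")
    triggers = []
    not_evaluable = []
    if p.age >= NOF_AGE_THRESHOLD:
        triggers.append("age_ge_65")
    else:
        bmi = p.bmi
        if bmi is None:
            not_evaluable.append("low_bmi")
        elif bmi < NOF_BMI_THRESHOLD:
            triggers.append("low_bmi")
        for rf in NOF_RISK_FACTORS:
            if getattr(p, rf) is True:
                triggers.append(rf)
    return ScreeningDecision(
        rule="nof2013",
        positive=bool(triggers),
        triggers=tuple(triggers),
        not_evaluable=tuple(not_evaluable),
    )


# ---------------------------------------------------------------------------
# Vectorised cohort-frame versions


def ostai_frame(df: pd.DataFrame, cutoff: int = DEFAULT_CUTOFF, rounding: str = "nearest") -> pd.DataFrame:
    """Score every row of a cohort frame.

    Returns columns ostai_raw, ostai_value, ostai_category, ostai_positive
    aligned with ``df``. Rows with a non-positive or missing age/weight get
    NaN scores rather than raising.
    """
    age = df["age"].astype(float)
    weight = df["weight_kg"].astype(float)
    ok = (age > 0) & (weight > 0)
    raw = pd.Series(np.where(ok, 0.2 * (weight - age), np.nan), index=df.index)
    value = pd.Series(np.where(ok, _to_integer(raw.fillna(0.0), rounding), np.nan), index=df.index)
    out = pd.DataFrame(index=df.index)
    out["ostai_raw"] = raw
    out["ostai_value"] = value
    out["ostai_category"] = pd.Series(categorize(value.fillna(0)), index=df.index).where(ok)
    out["ostai_positive"] = (value < cutoff).where(ok)
    return out


def nof2013_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised NOF 2013 decisions: columns nof2013_positive, nof2013_triggers."""
    age = df["age"].astype(float)
    if age.isna().any():
        bad = df.loc[age.isna(), "id"].tolist()
        raise DomainError(f"age required for NOF 2013; missing for ids {bad[:5]}")
    height = df["height_cm"].astype(float)
    weight = df["weight_kg"].astype(float)
    bmi = weight / (height / 100.0) ** 2
    aged = age >= NOF_AGE_THRESHOLD
    low_bmi = (bmi < NOF_BMI_THRESHOLD).fillna(False) & ~aged
    rf_fires = {
        rf: (df[rf].astype(float) == 1.0).fillna(False) & ~aged for rf in NOF_RISK_FACTORS
    }
    positive = aged | low_bmi
    for fires in rf_fires.values():
        positive |= fires
    triggers = []
    for i in df.index:
        t = []
        if aged.loc[i]:
            t.append("age_ge_65")
        else:
            if low_bmi.loc[i]:
                t.append("low_bmi")
            for rf in NOF_RISK_FACTORS:
                if rf_fires[rf].loc[i]:
                    t.append(rf)
        triggers.append(",".join(t))
    out = pd.DataFrame(index=df.index)
    out["nof2013_positive"] = positive
    out["nof2013_triggers"] = triggers
    return out
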