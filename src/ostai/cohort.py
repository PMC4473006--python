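"""Cohort domain model: participants, QC exclusions, and the osteoporosis case definition.

A cohort is one row per woman: demographics, FRAX-style binary risk factors
(tri-state: yes / no / missing), and DXA T-scores at the lumbar spine,
femoral neck, and total hip. Osteoporosis follows the WHO rule: the T-score
at any of the three sites is at or below -2.5.

The canonical in-memory container is a :class:`pandas.DataFrame` using the
column names in :data:`SCHEMA_COLUMNS`; :class:`Cohort` wraps it together
with a QC log of exclusions. :class:`Participant` is the single-row view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .errors import DomainError

#: Skeletal sites, in canonical order.
SITES = ("lumbar_spine", "femoral_neck", "total_hip")

#: DataFrame/CSV column per site.
T_COLUMNS = {
    "lumbar_spine": "t_lumbar",
    "femoral_neck": "t_femoral_neck",
    "total_hip": "t_total_hip",
}

#: Tri-state questionnaire risk factors (FRAX candidates), canonical order.
RISK_FACTORS = (
    "previous_fracture",
    "parent_hip_fracture",
    "current_smoking",
    "glucocorticoids",
    "rheumatoid_arthritis",
    "secondary_osteoporosis",
    "alcohol_3plus_units",
)

#: Continuous variables subject to the extreme-value (3 SD) screen.
EXTREME_VALUE_COLUMNS = ("age", "height_cm", "weight_kg", "menopause_age")

#: Mandatory cohort CSV schema, in order.
SCHEMA_COLUMNS = (
    "id",
    "sex",
    "menopausal",
    "age",
    "height_cm",
    "weight_kg",
    "menopause_age",
    "t_lumbar",
    "t_femoral_neck",
    "t_total_hip",
) + RISK_FACTORS

#: WHO osteoporosis threshold in T-score SD units.
T_THRESHOLD = -2.5


@dataclass
class Participant:
    """One woman's demographics, risk factors, and per-site T-scores.

    Risk factors are ``True`` (yes), ``False`` (no) or ``None`` (question
    not answered); missingness is preserved, never coerced to "no".
    """

    id: str
    sex: str = "female"
    menopausal: str = "post"
    age: Optional[float] = None
    height: Optional[float] = None  # cm
    weight: Optional[float] = None  # kg
    menopause_age: Optional[float] = None
    t_lumbar: Optional[float] = None
    t_femoral_neck: Optional[float] = None
    t_total_hip: Optional[float] = None
    previous_fracture: Optional[bool] = None
    parent_hip_fracture: Optional[bool] = None
    current_smoking: Optional[bool] = None
    glucocorticoids: Optional[bool] = None
    rheumatoid_arthritis: Optional[bool] = None
    secondary_osteoporosis: Optional[bool] = None
    alcohol_3plus_units: Optional[bool] = None

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise DomainError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.menopausal not in ("pre", "post", "unknown"):
            raise DomainError(f"menopausal must be pre/post/unknown, got {self.menopausal!r}")
        for name in ("age", "height", "weight"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise DomainError(f"{name} must be positive when present, got {v}")
        if (
            self.menopause_age is not None
            and self.age is not None
            and self.menopause_age > self.age
        ):
            raise DomainError("menopause_age cannot exceed age")

    @property
    def bmi(self) -> Optional[float]:
        """kg/m^2; only defined when both height and weight are present."""
        if self.height is None or self.weight is None:
            return None
        return self.weight / (self.height / 100.0) ** 2

    def t_scores(self) -> dict:
        """Available T-scores keyed by site name."""
        out = {}
        for site, col in T_COLUMNS.items():
            v = getattr(self, col)
            if v is not None and not (isinstance(v, float) and np.isnan(v)):
                out[site] = float(v)
        return out

    @classmethod
    def from_row(cls, row: pd.Series) -> "Participant":
        def _f(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v) else float(v)

        def _b(col):
            v = row.get(col)
            if v is None or pd.isna(v):
                return None
            return bool(int(v))

        return cls(
            id=str(row["id"]),
            sex=str(row.get("sex", "female")),
            menopausal=str(row.get("menopausal", "post")),
            age=_f("age"),
            height=_f("height_cm"),
            weight=_f("weight_kg"),
            menopause_age=_f("menopause_age"),
            t_lumbar=_f("t_lumbar"),
            t_femoral_neck=_f("t_femoral_neck"),
            t_total_hip=_f("t_total_hip"),
            **{rf: _b(rf) for rf in RISK_FACTORS},
        )

    def to_row(self) -> dict:
        row = {
            "id": self.id,
            "sex": self.sex,
            "menopausal": self.menopausal,
            "age": np.nan if self.age is None else self.age,
            "height_cm": np.nan if self.height is None else self.height,
            "weight_kg": np.nan if self.weight is None else self.weight,
            "menopause_age": np.nan if self.menopause_age is None else self.menopause_age,
            "t_lumbar": np.nan if self.t_lumbar is None else self.t_lumbar,
            "t_femoral_neck": np.nan if self.t_femoral_neck is None else self.t_femoral_neck,
            "t_total_hip": np.nan if self.t_total_hip is None else self.t_total_hip,
        }
        for rf in RISK_FACTORS:
            v = getattr(self, rf)
            row[rf] = np.nan if v is None else float(v)
        return row


@dataclass
class OsteoporosisStatus:
    """WHO case status for one participant: lowest T-score over available sites."""

    lowest_t: float
    osteoporotic: bool
    per_site: dict


@dataclass
class Cohort:
    """Ordered participant table plus a log of QC exclusions.

    ``data`` uses :data:`SCHEMA_COLUMNS`; ``qc_log`` has columns
    (id, step, reason), one row per excluded participant.
    """

    data: pd.DataFrame
    qc_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "step", "reason"])
    )
    rejects: Optional[pd.DataFrame] = None  # malformed input rows (set by io.read_cohort)
    #: reference (mean, sd) per variable used by the extreme-value screen,
    #: recorded by apply_exclusions so the pass can be replayed exactly
    qc_moments: Optional[dict] = None

    def __post_init__(self):
        missing = [c for c in SCHEMA_COLUMNS if c not in self.data.columns]
        if missing:
            raise DomainError(f"cohort frame missing columns: {missing}")
        ids = self.data["id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique().tolist()
            raise DomainError(f"participant ids not unique: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> pd.Series:
        return self.data["id"]

    def participants(self) -> Iterator[Participant]:
        for _, row in self.data.iterrows():
            yield Participant.from_row(row)

    @classmethod
    def from_participants(cls, participants, qc_log=None) -> "Cohort":
        rows = [p.to_row() for p in participants]
        df = pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS))
        if qc_log is None:
            qc_log = pd.DataFrame(columns=["id", "step", "reason"])
        return cls(data=df.reset_index(drop=True), qc_log=qc_log)


def lowest_t_scores(df: pd.DataFrame) -> pd.Series:
    """Row-wise minimum T-score over the sites that are present (NaN if none)."""
    t = df[[T_COLUMNS[s] for s in SITES]].astype(float)
    return t.min(axis=1, skipna=True)


def osteoporosis_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised case classification for a cohort frame.

    Returns a frame aligned with ``df`` holding ``lowest_t``, the boolean
    ``osteoporotic`` flag, and one boolean column per site.
    """
    out = pd.DataFrame(index=df.index)
    for site in SITES:
        out[site] = df[T_COLUMNS[site]].astype(float) <= T_THRESHOLD
    out["lowest_t"] = lowest_t_scores(df)
    out["osteoporotic"] = out["lowest_t"] <= T_THRESHOLD
    return out


def classify_osteoporosis(p: Participant) -> OsteoporosisStatus:
    """Apply the WHO definition: osteoporotic iff any available site T <= -2.5."""
    scores = p.t_scores()
    if not scores:
        raise DomainError(f"participant {p.id}: no T-score available at any site")
    lowest = min(scores.values())
    return OsteoporosisStatus(
        lowest_t=lowest,
        osteoporotic=lowest <= T_THRESHOLD,
        per_site={site: v <= T_THRESHOLD for site, v in scores.items()},
    )


def apply_exclusions(
    cohort: Cohort, sd_multiple: float = 3.0, reference: Optional[dict] = None
) -> Cohort:
    """Run the single-pass cohort disposition and return the analysable cohort.

    Steps, in order: (1) remove males; (2) remove non-postmenopausal women;
    (3) remove anyone missing a T-score at any of the three sites; (4) remove
    extreme values — age, height, weight, or menopause age deviating from
    that variable's mean by strictly more than ``sd_multiple`` SDs, where
    means and SDs are computed once, per variable on complete cases, on the
    sample surviving steps 1-3. A missing menopause age exempts a woman from
    that variable's rule only. Every removal is logged with a reason code.

    The reference moments actually used are recorded on the returned cohort
    (``qc_moments``); passing them back via ``reference`` replays the pass
    exactly, making the operation idempotent.
    """
    if not sd_multiple > 0:
        raise DomainError(f"sd_multiple must be positive, got {sd_multiple}")
    if len(cohort) == 0:
        raise DomainError("cannot apply exclusions to an empty cohort")

    df = cohort.data
    log_rows = []

    def _log(mask, step, reason):
        for pid in df.loc[mask, "id"]:
            log_rows.append({"id": pid, "step": step, "reason": reason})

    excluded = pd.Series(False, index=df.index)

    m_male = df["sex"] == "male"
    _log(m_male & ~excluded, 1, "male")
    excluded |= m_male

    m_pre = (df["menopausal"] != "post") & ~excluded
    _log(m_pre, 2, "not_postmenopausal")
    excluded |= m_pre

    t_cols = [T_COLUMNS[s] for s in SITES]
    m_missing = df[t_cols].isna().any(axis=1) & ~excluded
    _log(m_missing, 3, "missing_bmd")
    excluded |= m_missing

    survivors = df.loc[~excluded]
    # Reference moments: one pass, per-variable complete-case, on the
    # post-step-3 sample (or caller-supplied for an exact replay).
    moments = {}
    m_extreme = pd.Series(False, index=df.index)
    for col in EXTREME_VALUE_COLUMNS:
        vals = survivors[col].astype(float)
        if reference is not None and col in reference:
            mean, sd = reference[col]
        else:
            ok = vals.notna()
            if ok.sum() < 2:
                continue
            mean, sd = float(vals[ok].mean()), float(vals[ok].std(ddof=1))
        if sd == 0 or np.isnan(sd):
            continue
        moments[col] = (mean, sd)
        flag = (vals - mean).abs() > sd_multiple * sd  # strict: exactly k*SD retained
        flag = flag.fillna(False)  # missing value => rule not applied
        m_extreme.loc[flag[flag].index] = True
    m_extreme &= ~excluded
    _log(m_extreme, 4, "extreme_value")
    excluded |= m_extreme

    new_log = pd.concat(
        [cohort.qc_log, pd.DataFrame(log_rows, columns=["id", "step", "reason"])],
        ignore_index=True,
    )
    kept = df.loc[~excluded].reset_index(drop=True)
    if len(kept) == 0:
        raise DomainError("all participants excluded during QC", qc_log=new_log)
    return Cohort(data=kept, qc_log=new_log, qc_moments=moments)


def tabulate_site_combinations(cohort: Cohort) -> dict:
    """Count osteoporotic women by the exact subset of sites at or below -2.5.

    Returns a dict keyed by tuples of site names (the 7 non-empty subsets in
    canonical order); the values partition the osteoporotic participants, so
    they sum to the osteoporotic count and per-site totals are recoverable
    with :func:`per_site_totals`.
    """
    status = osteoporosis_frame(cohort.data)
    combos = {}
    for mask in range(1, 8):
        subset = tuple(s for i, s in enumerate(SITES) if mask >> i & 1)
        combos[subset] = 0
    if len(cohort) > 0:
        flags = status[list(SITES)].to_numpy(dtype=bool)
        codes = flags @ np.array([1, 2, 4])
        counts = np.bincount(codes, minlength=8)
        for mask in range(1, 8):
            subset = tuple(s for i, s in enumerate(SITES) if mask >> i & 1)
            combos[subset] = int(counts[mask])
    return combos


def per_site_totals(combos: dict) -> dict:
    """Per-site totals (a site's total = sum of every subset containing it)
    plus the grand total of osteoporotic participants."""
    totals = {site: 0 for site in SITES}
    for subset, n in combos.items():
        for site in subset:
            totals[site] += n
    totals["total"] = sum(combos.values())
    return totals
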