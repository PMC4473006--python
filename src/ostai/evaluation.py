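"""Diagnostic-performance engine for screening rules.

Confusion matrices, sensitivity/specificity/PPV/NPV (reported both as
proportions and as exact count fractions), ROC curves with trapezoidal AUC
(equal to the Mann-Whitney concordance probability with ties counted 1/2),
AUC confidence intervals by the DeLong variance estimator (Hanley-McNeil as
an option), OSTAi risk-category prevalence, and paired head-to-head rule
comparison.

Orientation: a LOWER index score means MORE at risk, so ROC thresholds
sweep "score < t". For a binary rule the ROC is the two-segment curve
through its single operating point and its trapezoidal AUC equals
(sensitivity + specificity) / 2 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .cohort import Cohort, lowest_t_scores, osteoporosis_frame
from .errors import DomainError
from .scoring import DEFAULT_CUTOFF, ScreeningDecision, categorize, nof2013_frame, ostai_frame


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """A proportion as a percentage rounded the way the tables print it."""
    if denominator == 0:
        raise DomainError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, decimals)


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:  # osteoporotic
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


def _as_bool(values, kind: str) -> np.ndarray:
    out = []
    for v in values:
        if isinstance(v, ScreeningDecision):
            out.append(v.positive)
        elif hasattr(v, "osteoporotic"):
            out.append(v.osteoporotic)
        else:
            out.append(bool(v))
    return np.asarray(out, dtype=bool)


def confusion(decisions: Sequence, statuses: Sequence) -> ConfusionMatrix:
    """Tally a 2x2 table from aligned per-participant decisions and statuses."""
    d = _as_bool(decisions, "decision")
    s = _as_bool(statuses, "status")
    if len(d) != len(s):
        raise DomainError(f"length mismatch: {len(d)} decisions vs {len(s)} statuses")
    return ConfusionMatrix(
        tp=int((d & s).sum()),
        fp=int((d & ~s).sum()),
        fn=int((~d & s).sum()),
        tn=int((~d & ~s).sum()),
    )


@dataclass
class Metrics:
    """The four screening proportions plus prevalence and referral burden.

    Each metric is None when its denominator is zero (undefined, not 0);
    ``counts`` holds the exact fractions, e.g. sensitivity (3674, 5027).
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    prevalence: Optional[float]
    positive_rate: Optional[float]
    counts: dict

    def pct(self, name: str, decimals: int = 1) -> float:
        num, den = self.counts[name]
        return percent(num, den, decimals)


def metrics(matrix: ConfusionMatrix) -> Metrics:
    """Sensitivity, specificity, PPV, NPV from a confusion matrix."""
    def ratio(num, den):
        return None if den == 0 else num / den

    m = matrix
    counts = {
        "sensitivity": (m.tp, m.tp + m.fn),
        "specificity": (m.tn, m.tn + m.fp),
        "ppv": (m.tp, m.tp + m.fp),
        "npv": (m.tn, m.tn + m.fn),
        "prevalence": (m.n_pos, m.n),
        "positive_rate": (m.tp + m.fp, m.n),
    }
    return Metrics(
        sensitivity=ratio(*counts["sensitivity"]),
        specificity=ratio(*counts["specificity"]),
        ppv=ratio(*counts["ppv"]),
        npv=ratio(*counts["npv"]),
        prevalence=ratio(*counts["prevalence"]),
        positive_rate=ratio(*counts["positive_rate"]),
        counts=counts,
    )


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class ROCResult:
    """ROC curve and AUC with a 95% confidence interval."""

    points: np.ndarray  # (k, 2) array of (fpr, tpr), monotone nondecreasing
    thresholds: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    ci_method: str = "delong"


def _delong_placements(case: np.ndarray, risk: np.ndarray):
    """Per-subject placement values (DeLong's V10/V01) and the AUC."""
    pos = risk[case]
    neg = risk[~case]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - rankdata(neg)) / m
    auc = v10.mean()
    return v10, v01, float(auc)


def delong_variance(case: np.ndarray, risk: np.ndarray):
    """(auc, variance) by DeLong's estimator; risk oriented higher = case-like."""
    v10, v01, auc = _delong_placements(case, risk)
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise DomainError("DeLong variance needs >= 2 subjects per class")
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return auc, float(var)


def delong_paired(case: np.ndarray, risk_a: np.ndarray, risk_b: np.ndarray):
    """Paired DeLong comparison of two risk scores on the same subjects.

    Returns (auc_a, auc_b, var of the AUC difference).
    """
    va10, va01, auc_a = _delong_placements(case, risk_a)
    vb10, vb01, auc_b = _delong_placements(case, risk_b)
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    s = s10 / m + s01 / n
    var_diff = float(s[0, 0] + s[1, 1] - 2 * s[0, 1])
    return auc_a, auc_b, var_diff


def _hanley_mcneil_variance(auc: float, m: int, n: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)


def roc_curve(
    scores: Sequence,
    statuses: Sequence,
    ci_method: str = "delong",
    level: float = 0.95,
) -> ROCResult:
    """ROC for an index where lower scores indicate higher risk.

    Thresholds sweep every observed score value plus an all-positive
    sentinel, positivity = score < threshold. AUC is the trapezoidal area,
    identical to the Mann-Whitney concordance probability with ties
    counted 1/2.
    """
    s = np.asarray(
        [v.value if hasattr(v, "value") else v for v in scores], dtype=float
    )
    case = _as_bool(statuses, "status")
    if len(s) != len(case):
        raise DomainError("scores and statuses must have equal length")
    m, n = int(case.sum()), int((~case).sum())
    if m == 0 or n == 0:
        raise DomainError("ROC needs both cases and controls")

    uniq = np.unique(s)
    thresholds = np.append(uniq, np.inf)  # score < inf: everyone positive
    pos_counts = np.array([(s[case] < t).sum() for t in thresholds], dtype=float)
    neg_counts = np.array([(s[~case] < t).sum() for t in thresholds], dtype=float)
    tpr = pos_counts / m
    fpr = neg_counts / n
    points = np.column_stack([fpr, tpr])

    auc = float(np.trapezoid(tpr, fpr))
    if ci_method == "delong":
        auc_mw, var = delong_variance(case, -s)
    elif ci_method == "hanley":
        var = _hanley_mcneil_variance(auc, m, n)
    else:
        raise DomainError(f"unknown CI method {ci_method!r}")
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return ROCResult(
        points=points,
        thresholds=thresholds,
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_pos=m,
        n_neg=n,
        ci_method=ci_method,
    )


def binary_roc(decisions: Sequence, statuses: Sequence, **kw) -> ROCResult:
    """Two-segment ROC through a binary rule's single operating point."""
    d = _as_bool(decisions, "decision")
    # positive decision = at risk = "low score": map to score 0 vs 1
    return roc_curve(np.where(d, 0.0, 1.0), statuses, **kw)


# ---------------------------------------------------------------------------
# Category prevalence and full reports


@dataclass
class CategoryPrevalence:
    cases: int
    total: int
    proportion: Optional[float]


def category_prevalence(scores: Sequence, statuses: Sequence) -> dict:
    """Osteoporosis prevalence within the low / medium / high OSTAi bands."""
    vals = np.asarray([v.value if hasattr(v, "value") else v for v in scores], dtype=float)
    case = _as_bool(statuses, "status")
    if len(vals) == 0:
        raise DomainError("category prevalence of an empty cohort")
    cats = categorize(vals)
    out = {}
    for cat in ("low", "medium", "high"):
        in_cat = cats == cat
        total = int(in_cat.sum())
        cases = int((in_cat & case).sum())
        out[cat] = CategoryPrevalence(
            cases=cases, total=total, proportion=None if total == 0 else cases / total
        )
    return out


@dataclass
class DiagnosticReport:
    """One screening rule's full diagnostic profile on one cohort."""

    rule: str
    matrix: ConfusionMatrix
    metrics: Metrics
    roc: Optional[ROCResult] = None
    category_prevalence: Optional[dict] = None
    ids: Optional[tuple] = None
    risk: Optional[np.ndarray] = None  # per-participant risk, higher = more at risk
    case: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        d = {
            "rule": self.rule,
            "confusion": {k: getattr(self.matrix, k) for k in ("tp", "fp", "fn", "tn")},
            "metrics": {
                name: {
                    "proportion": getattr(self.metrics, name),
                    "percent": self.metrics.pct(name),
                    "counts": list(self.metrics.counts[name]),
                }
                for name in self.metrics.counts
            },
        }
        if self.roc is not None:
            d["roc"] = {
                "auc": self.roc.auc,
                "ci_low": self.roc.ci_low,
                "ci_high": self.roc.ci_high,
                "ci_method": self.roc.ci_method,
                "n_pos": self.roc.n_pos,
                "n_neg": self.roc.n_neg,
            }
        if self.category_prevalence is not None:
            d["category_prevalence"] = {
                cat: {"cases": cp.cases, "total": cp.total, "proportion": cp.proportion}
                for cat, cp in self.category_prevalence.items()
            }
        return d


def evaluate_ostai(
    cohort: Cohort,
    cutoff: int = DEFAULT_CUTOFF,
    rounding: str = "nearest",
    ci_method: str = "delong",
) -> DiagnosticReport:
    """Score a post-QC cohort with OSTAi and report its diagnostic profile."""
    df = cohort.data
    scored = ostai_frame(df, cutoff=cutoff, rounding=rounding)
    status = osteoporosis_frame(df)
    ok = scored["ostai_value"].notna() & status["lowest_t"].notna()
    values = scored.loc[ok, "ostai_value"].to_numpy()
    case = status.loc[ok, "osteoporotic"].to_numpy()
    decisions = values < cutoff
    mat = confusion(decisions, case)
    return DiagnosticReport(
        rule="ostai",
        matrix=mat,
        metrics=metrics(mat),
        roc=roc_curve(values, case, ci_method=ci_method),
        category_prevalence=category_prevalence(values, case),
        ids=tuple(df.loc[ok, "id"]),
        risk=-values.astype(float),
        case=case,
    )


def evaluate_nof2013(cohort: Cohort, ci_method: str = "delong") -> DiagnosticReport:
    """Apply the NOF 2013 referral rule and report its diagnostic profile.

    As a binary rule its ROC is the two-segment curve through the single
    operating point, so the AUC equals (sens + spec)/2 by construction.
    """
    df = cohort.data
    nof = nof2013_frame(df)
    status = osteoporosis_frame(df)
    ok = status["lowest_t"].notna()
    decisions = nof.loc[ok, "nof2013_positive"].to_numpy(dtype=bool)
    case = status.loc[ok, "osteoporotic"].to_numpy()
    mat = confusion(decisions, case)
    return DiagnosticReport(
        rule="nof2013",
        matrix=mat,
        metrics=metrics(mat),
        roc=binary_roc(decisions, case, ci_method=ci_method),
        ids=tuple(df.loc[ok, "id"]),
        risk=decisions.astype(float),
        case=case,
    )


@dataclass
class RuleComparison:
    """Side-by-side comparison of two screening rules on the same cohort."""

    rule_a: str
    rule_b: str
    auc_a: float
    auc_b: float
    auc_diff: float
    diff_ci_low: Optional[float]
    diff_ci_high: Optional[float]
    p_value: Optional[float]
    referral_a: float  # proportion testing positive
    referral_b: float
    metrics_a: Metrics = field(repr=False, default=None)
    metrics_b: Metrics = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "rule_a": self.rule_a,
            "rule_b": self.rule_b,
            "auc_a": self.auc_a,
            "auc_b": self.auc_b,
            "auc_diff": self.auc_diff,
            "diff_ci": [self.diff_ci_low, self.diff_ci_high],
            "p_value": self.p_value,
            "referral_a": self.referral_a,
            "referral_b": self.referral_b,
        }


def compare_rules(report_a: DiagnosticReport, report_b: DiagnosticReport,
                  level: float = 0.95) -> RuleComparison:
    """Head-to-head comparison; paired DeLong when per-participant risks exist.

    Both reports must come from the identical cohort (same id set).
    """
    if report_a.ids is not None and report_b.ids is not None:
        if set(report_a.ids) != set(report_b.ids):
            raise DomainError("reports computed on different cohorts (id sets differ)")
    auc_a = report_a.roc.auc if report_a.roc else None
    auc_b = report_b.roc.auc if report_b.roc else None
    ci_low = ci_high = p_value = None
    if (
        report_a.risk is not None
        and report_b.risk is not None
        and report_a.ids == report_b.ids
    ):
        case = report_a.case
        auc_a, auc_b, var_diff = delong_paired(case, report_a.risk, report_b.risk)
        diff = auc_a - auc_b
        if var_diff > 0:
            z = norm.ppf(0.5 + level / 2.0)
            half = z * np.sqrt(var_diff)
            ci_low, ci_high = float(diff - half), float(diff + half)
            p_value = float(2 * norm.sf(abs(diff) / np.sqrt(var_diff)))
        else:  # identical risk vectors
            ci_low = ci_high = 0.0
            p_value = 1.0
    return RuleComparison(
        rule_a=report_a.rule,
        rule_b=report_b.rule,
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        auc_diff=float(auc_a - auc_b),
        diff_ci_low=ci_low,
        diff_ci_high=ci_high,
        p_value=p_value,
        referral_a=report_a.metrics.positive_rate,
        referral_b=report_b.metrics.positive_rate,
        metrics_a=report_a.metrics,
        metrics_b=report_b.metrics,
    )
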