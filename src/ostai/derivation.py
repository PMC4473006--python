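"""Rebuild an OSTA-style integer risk index from a cohort.

The pipeline mirrors the classical clinical-index construction:

1. univariate screen — simple OLS of the (lowest-site) BMD T-score on each
   FRAX candidate risk factor, continuous variables rescaled to per-10-unit
   increments; keep variables with p below alpha (default 0.05);
2. multivariable fit — one OLS with all retained variables;
3. integer index weights — each beta divided by a scale anchor and rounded
   to the nearest integer (ties away from zero). The default anchor is half
   the largest |beta|, which pins the dominant variable at weight +/-2 and
   is stable under resampling; the smallest-|beta| anchor is available as an
   option. Both reproduce the published OSTAi weight column;
4. item reduction — backward elimination scoring participants by the
   remaining weighted sum: at each step drop the variable whose removal
   costs the least AUC for discriminating osteoporosis, refitting betas on
   the survivors (against the frozen full-model anchor), while the loss
   stays within tolerance;
5. cutoff selection — the integer cutoff maximising Youden's J, positivity
   being score strictly below the cutoff.

Complete-case analysis throughout: rows missing any variable of a given
model are excluded from that model's fit, and the elimination AUCs are all
evaluated on the full model's complete-case rows so the comparison is
paired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .cohort import Cohort, RISK_FACTORS, T_COLUMNS, T_THRESHOLD, lowest_t_scores
from .errors import DomainError
from .scoring import round_half_away

#: Continuous candidates: variable name -> (cohort column, per-unit scale).
#: Betas are reported per 10 units (10 years, 10 cm, 10 kg).
CONTINUOUS_VARS = {
    "age": "age",
    "height": "height_cm",
    "weight": "weight_kg",
    "menopause_age": "menopause_age",
}
CONTINUOUS_INCREMENT = 10.0

#: All FRAX-derived candidates screened univariately (4 continuous + 7 binary).
CANDIDATE_VARS = tuple(CONTINUOUS_VARS) + RISK_FACTORS

#: Referent values: the published index anchors age and weight at 50; other
#: continuous variables use round cohort-typical values, binaries use "no".
DEFAULT_REFERENTS = {"age": 50.0, "weight": 50.0, "height": 150.0, "menopause_age": 50.0}


@dataclass
class RegressionFit:
    """One variable's coefficient in a univariate or multivariable OLS."""

    variable: str
    beta: float  # per 10 units for continuous variables, yes-vs-no for binary
    se: float
    p: float
    n: int = 0
    retained: bool = True
    note: Optional[str] = None


@dataclass
class IndexModel:
    """An OSTA-style integer index: variables, signed weights, and scale.

    The index value of a participant is
    ``sum_v weight[v] * (x_v - referent[v]) / increment[v]`` rounded to an
    integer; with variables {age, weight}, weights {-2, +2}, increments 10
    and referents 50 this is exactly 0.2*(weight - age).
    """

    variables: tuple
    weights: dict
    increments: dict
    referents: dict
    scale_anchor: float
    cutoff: Optional[int] = None
    rounding: str = "nearest"
    elimination_trace: list = field(default_factory=list)

    def __post_init__(self):
        for v in self.variables:
            w = self.weights[v]
            if w == 0 or int(w) != w:
                raise DomainError(f"index weight for {v} must be a nonzero integer, got {w}")

    def design_columns(self, df: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame({v: design_column(df, v, scaled=False) for v in self.variables})

    def raw_scores(self, df: pd.DataFrame) -> pd.Series:
        """Continuous weighted sum; NaN where any model variable is missing."""
        cols = self.design_columns(df)
        total = pd.Series(0.0, index=df.index)
        for v in self.variables:
            total = total + self.weights[v] * (cols[v] - self.referents.get(v, 0.0)) / self.increments[v]
        return total

    def scores(self, df: pd.DataFrame) -> pd.Series:
        """Integer index values (float series with NaN where not computable)."""
        raw = self.raw_scores(df)
        if self.rounding == "truncate":
            return np.trunc(np.round(raw, 9))
        return pd.Series(round_half_away(raw.to_numpy()), index=df.index)

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "weights": {v: int(self.weights[v]) for v in self.variables},
            "increments": {v: self.increments[v] for v in self.variables},
            "referents": {v: self.referents.get(v, 0.0) for v in self.variables},
            "scale_anchor": self.scale_anchor,
            "cutoff": self.cutoff,
            "rounding": self.rounding,
            "elimination_trace": [list(t) for t in self.elimination_trace],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IndexModel":
        return cls(
            variables=tuple(d["variables"]),
            weights={k: int(v) for k, v in d["weights"].items()},
            increments=dict(d["increments"]),
            referents=dict(d["referents"]),
            scale_anchor=float(d["scale_anchor"]),
            cutoff=None if d.get("cutoff") is None else int(d["cutoff"]),
            rounding=d.get("rounding", "nearest"),
            elimination_trace=[tuple(t) for t in d.get("elimination_trace", [])],
        )


def design_column(df: pd.DataFrame, variable: str, scaled: bool = True) -> pd.Series:
    """A candidate variable as a numeric column; per-10-unit if ``scaled``."""
    if variable in CONTINUOUS_VARS:
        col = df[CONTINUOUS_VARS[variable]].astype(float)
        return col / CONTINUOUS_INCREMENT if scaled else col
    if variable in RISK_FACTORS:
        return df[variable].astype(float)  # 0/1 with NaN = unanswered
    raise DomainError(f"unknown candidate variable {variable!r}")


def response_vector(df: pd.DataFrame, response: str = "lowest") -> pd.Series:
    """Regression response: the lowest-site T-score (default) or one site."""
    if response == "lowest":
        return lowest_t_scores(df)
    if response in T_COLUMNS:
        return df[T_COLUMNS[response]].astype(float)
    raise DomainError(f"unknown response {response!r}; use 'lowest' or a site name")


def flag_retained(fits: Sequence[RegressionFit], alpha: float) -> list:
    """Re-flag fits by the p < alpha univariate screen rule."""
    return [
        replace(f, retained=bool(np.isfinite(f.p) and f.p < alpha)) for f in fits
    ]


def univariate_screen(
    cohort: Cohort, alpha: float = 0.05, response: str = "lowest"
) -> list:
    """Screen every FRAX candidate with a simple linear regression.

    Returns one :class:`RegressionFit` per candidate, flagged retained when
    p < alpha. Zero-variance candidates are flagged dropped with a warning
    (beta/se/p left NaN).
    """
    if not 0 < alpha <= 1:
        raise DomainError(f"alpha must be in (0, 1], got {alpha}")
    y_all = response_vector(cohort.data, response)
    fits = []
    for var in CANDIDATE_VARS:
        x = design_column(cohort.data, var)
        ok = x.notna() & y_all.notna()
        xv, yv = x[ok].to_numpy(), y_all[ok].to_numpy()
        if len(xv) < 3 or np.ptp(xv) == 0:
            warnings.warn(f"candidate {var}: zero variance or too few rows; skipped")
            fits.append(RegressionFit(var, np.nan, np.nan, np.nan, n=len(xv), retained=False,
                                      note="zero_variance"))
            continue
        res = sm.OLS(yv, sm.add_constant(xv)).fit()
        fits.append(RegressionFit(
            variable=var, beta=float(res.params[1]), se=float(res.bse[1]),
            p=float(res.pvalues[1]), n=int(res.nobs),
            retained=bool(res.pvalues[1] < alpha),
        ))
    return fits


def _collinear_set(X: np.ndarray, names: Sequence[str]) -> list:
    """Greedy scan for columns that do not increase matrix rank."""
    bad, kept = [], np.ones((X.shape[0], 1))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            bad.append(name)
        else:
            kept = cand
    return bad


def fit_multivariable(
    cohort: Cohort, variables: Sequence[str], response: str = "lowest"
) -> list:
    """One OLS of the response on all listed variables simultaneously.

    Complete-case: rows missing any listed variable (or the response) are
    dropped; requires at least 10 rows per variable.
    """
    variables = list(variables)
    if len(variables) < 2:
        raise DomainError("multivariable fit needs at least 2 variables")
    df = cohort.data
    y = response_vector(df, response)
    X = pd.DataFrame({v: design_column(df, v) for v in variables})
    ok = X.notna().all(axis=1) & y.notna()
    Xc, yc = X[ok].to_numpy(), y[ok].to_numpy()
    if len(yc) < 10 * len(variables):
        raise DomainError(
            f"insufficient complete cases: {len(yc)} rows for {len(variables)} variables"
        )
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(yc)), Xc])) < len(variables) + 1:
        raise DomainError(f"design matrix rank deficient; collinear: {_collinear_set(Xc, variables)}")
    res = sm.OLS(yc, sm.add_constant(Xc)).fit()
    return [
        RegressionFit(variable=v, beta=float(res.params[j + 1]), se=float(res.bse[j + 1]),
                      p=float(res.pvalues[j + 1]), n=int(res.nobs))
        for j, v in enumerate(variables)
    ]


def make_index_weights(
    fits: Sequence[RegressionFit],
    anchor: str = "half_max",
    cutoff: Optional[int] = None,
    rounding: str = "nearest",
) -> IndexModel:
    """Turn multivariable betas into signed integer index weights.

    ``anchor='half_max'`` (default) scales by half the largest |beta| so the
    dominant variable carries weight +/-2; ``anchor='min_abs'`` scales by
    the smallest |beta| so the weakest variable carries +/-1. A numeric
    anchor may also be given. Weights keep the sign of the beta; a weight
    that would round to 0 under ``half_max`` is clamped to +/-1 so every
    retained variable contributes.
    """
    fits = list(fits)
    if not fits:
        raise DomainError("no fits supplied")
    betas = np.array([f.beta for f in fits], dtype=float)
    if np.any(betas == 0) or np.any(~np.isfinite(betas)):
        bad = [f.variable for f, b in zip(fits, betas) if b == 0 or not np.isfinite(b)]
        raise DomainError(f"zero or non-finite beta for {bad}; cannot weight")
    if isinstance(anchor, str):
        if anchor == "half_max":
            scale = float(np.max(np.abs(betas)) / 2.0)
        elif anchor == "min_abs":
            scale = float(np.min(np.abs(betas)))
        else:
            raise DomainError(f"unknown anchor mode {anchor!r}")
    else:
        scale = float(anchor)
        if not scale > 0:
            raise DomainError("numeric anchor must be positive")
    weights = {}
    for f, b in zip(fits, betas):
        w = int(round_half_away(b / scale))
        if w == 0:
            w = int(np.sign(b))
        weights[f.variable] = w
    variables = tuple(f.variable for f in fits)
    increments = {
        v: CONTINUOUS_INCREMENT if v in CONTINUOUS_VARS else 1.0 for v in variables
    }
    referents = {v: DEFAULT_REFERENTS.get(v, 0.0) for v in variables}
    return IndexModel(
        variables=variables, weights=weights, increments=increments,
        referents=referents, scale_anchor=scale, cutoff=cutoff, rounding=rounding,
    )


def concordance(case: np.ndarray, risk: np.ndarray) -> float:
    """Mann-Whitney AUC (ties counted 1/2) of ``risk`` for the case labels."""
    case = np.asarray(case, dtype=bool)
    m = int(case.sum())
    n = int((~case).sum())
    if m == 0 or n == 0:
        raise DomainError("AUC undefined: one class absent")
    ranks = rankdata(np.asarray(risk, dtype=float))
    return float((ranks[case].sum() - m * (m + 1) / 2.0) / (m * n))


def _model_auc(model: IndexModel, df: pd.DataFrame, case: np.ndarray) -> float:
    # lower index value = more at risk, so the risk score is the negated value
    return concordance(case, -model.scores(df).to_numpy())


def item_reduction(
    cohort: Cohort,
    model: IndexModel,
    tol_auc: float = 0.01,
    response: str = "lowest",
    stop: str = "step",
) -> IndexModel:
    """Backward elimination of index variables under an AUC-retention rule.

    At each step every one-variable-smaller model is refit (OLS on the
    surviving variables, integer weights against the full model's frozen
    scale anchor) and scored on the full model's complete-case rows; the
    variable whose removal costs the least AUC is dropped. With
    ``stop='step'`` (default) elimination continues while that best
    single-step loss is within ``tol_auc``; ``stop='full'`` instead bounds
    the cumulative loss versus the full model. The elimination trace
    (variable dropped, AUC after) is recorded on the returned model.
    """
    if tol_auc < 0:
        raise DomainError(f"tol_auc must be >= 0, got {tol_auc}")
    if stop not in ("step", "full"):
        raise DomainError(f"unknown stop rule {stop!r}")
    if len(model.variables) < 2:
        warnings.warn("item reduction needs >= 2 variables; returning input model")
        return model

    df = cohort.data
    y = response_vector(df, response)
    X = pd.DataFrame({v: design_column(df, v) for v in model.variables})
    ok = X.notna().all(axis=1) & y.notna()
    eval_df = df[ok]
    case = (y[ok] <= T_THRESHOLD).to_numpy()
    if case.all() or not case.any():
        raise DomainError("item reduction needs both cases and controls")

    eval_cohort = Cohort(data=eval_df.reset_index(drop=True), qc_log=model_qc_placeholder())
    anchor = model.scale_anchor
    current = replace(model, elimination_trace=list(model.elimination_trace))
    auc_full = _model_auc(current, eval_cohort.data, case)
    auc_current = auc_full
    trace = list(current.elimination_trace)

    while len(current.variables) > 1:
        best = None
        for v in current.variables:
            remaining = [w for w in current.variables if w != v]
            if len(remaining) >= 2:
                fits = fit_multivariable(eval_cohort, remaining, response)
            else:
                fits = _single_variable_fit(eval_cohort, remaining[0], response)
            cand = make_index_weights(fits, anchor=anchor, rounding=model.rounding)
            auc = _model_auc(cand, eval_cohort.data, case)
            if best is None or auc > best[0]:
                best = (auc, v, cand)
        auc_best, dropped, cand = best
        reference = auc_current if stop == "step" else auc_full
        if reference - auc_best <= tol_auc:
            trace.append((dropped, float(auc_best)))
            current = replace(cand, elimination_trace=trace)
            auc_current = auc_best
        else:
            break
    return current


def _single_variable_fit(cohort: Cohort, variable: str, response: str) -> list:
    y = response_vector(cohort.data, response)
    x = design_column(cohort.data, variable)
    ok = x.notna() & y.notna()
    res = sm.OLS(y[ok].to_numpy(), sm.add_constant(x[ok].to_numpy())).fit()
    return [RegressionFit(variable, float(res.params[1]), float(res.bse[1]),
                          float(res.pvalues[1]), n=int(res.nobs))]


def model_qc_placeholder() -> pd.DataFrame:
    return pd.DataFrame(columns=["id", "step", "reason"])


def select_cutoff(cohort: Cohort, model: IndexModel, response: str = "lowest") -> int:
    """Integer cutoff maximising Youden's J (sens + spec - 1).

    Every integer in the observed score range is evaluated with positivity
    = score < cutoff; ties break toward the higher-sensitivity (larger)
    cutoff. Warns when the J profile is essentially flat (score carries no
    signal).
    """
    scores = model.scores(cohort.data)
    y = response_vector(cohort.data, response)
    ok = scores.notna() & y.notna()
    s = scores[ok].to_numpy()
    case = (y[ok] <= T_THRESHOLD).to_numpy()
    n_pos, n_neg = int(case.sum()), int((~case).sum())
    if n_pos == 0 or n_neg == 0:
        raise DomainError("cutoff selection needs both cases and controls")
    lo, hi = int(np.min(s)), int(np.max(s))
    best_c, best_j = None, -np.inf
    for c in range(lo, hi + 1):
        positive = s < c
        sens = (positive & case).sum() / n_pos
        spec = (~positive & ~case).sum() / n_neg
        j = sens + spec - 1.0
        # ascending scan: on a tie the later (larger, higher-sensitivity)
        # cutoff wins
        if j >= best_j - 1e-12:
            best_c = c
            best_j = max(best_j, j)
    if best_j < 0.05:
        warnings.warn(f"Youden J profile is nearly flat (max J={best_j:.3f}); "
                      "the score may be uninformative")
    return int(best_c)


@dataclass
class DerivationResult:
    """Everything the derivation pipeline produced, end to end."""

    univariate: list
    multivariable: list
    full_model: IndexModel
    reduced_model: IndexModel
    cutoff: int
    auc_full: float
    auc_reduced: float


def derive_index(
    cohort: Cohort,
    alpha: float = 0.05,
    tol_auc: float = 0.01,
    response: str = "lowest",
    anchor: str = "half_max",
    rounding: str = "nearest",
    stop: str = "step",
) -> DerivationResult:
    """Run the full index-derivation pipeline on a post-QC cohort."""
    uni = univariate_screen(cohort, alpha=alpha, response=response)
    retained = [f.variable for f in uni if f.retained]
    if len(retained) < 2:
        raise DomainError(f"univariate screen retained {len(retained)} variables; need >= 2")
    multi = fit_multivariable(cohort, retained, response=response)
    full_model = make_index_weights(multi, anchor=anchor, rounding=rounding)
    reduced = item_reduction(cohort, full_model, tol_auc=tol_auc, response=response, stop=stop)
    cutoff = select_cutoff(cohort, reduced, response=response)
    reduced = replace(reduced, cutoff=cutoff)

    y = response_vector(cohort.data, response)

    def _auc(m):
        sc = m.scores(cohort.data)
        ok = sc.notna() & y.notna()
        return concordance((y[ok] <= T_THRESHOLD).to_numpy(), -sc[ok].to_numpy())

    return DerivationResult(
        univariate=uni, multivariable=multi, full_model=full_model,
        reduced_model=reduced, cutoff=cutoff,
        auc_full=_auc(full_model), auc_reduced=_auc(reduced),
    )
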