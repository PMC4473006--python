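"""Seeded generator of study-like postmenopausal screening cohorts.

The generator emulates a nationwide DXA-screening cohort of Taiwanese
postmenopausal women: correlated demographics (age, height, weight, age at
menopause) from a truncated multivariate normal; tri-state FRAX
questionnaire factors with realistic prevalence, age dependence, and
missing-completely-at-random non-response; and per-site BMD T-scores
(lumbar spine, femoral neck, total hip) generated as

    T_site = intercept_site + sum_j beta_j * x_j + u_shared + e_site

with one shared "bone level" noise term per woman (so the three sites
correlate ~0.6 as real DXA sites do) plus site-specific noise. The
structural betas default to the published per-unit regression coefficients,
and the intercepts are auto-calibrated by bisection on a large calibration
sample so that the realised prevalence of osteoporosis (lowest-site
T <= -2.5) hits the configured target (default 41.3%).

Every draw uses an explicitly specified PRNG (PCG64), so a given
(config, seed) pair reproduces the cohort byte-identically on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .cohort import Cohort, RISK_FACTORS, SCHEMA_COLUMNS, T_THRESHOLD
from .errors import DomainError

CONTINUOUS = ("age", "height_cm", "weight_kg", "menopause_age")

#: Cohort marginal means and SDs for the continuous variables.
DEFAULT_MEANS = {"age": 66.0, "height_cm": 153.9, "weight_kg": 56.9, "menopause_age": 49.3}
DEFAULT_SDS = {"age": 9.6, "height_cm": 5.8, "weight_kg": 8.8, "menopause_age": 4.5}

#: Correlations among (age, height, weight, menopause_age). These values
#: reproduce the published univariate-vs-multivariable coefficient
#: attenuation for the continuous variables (e.g. height 0.57 univariate
#: vs 0.18 multivariable).
DEFAULT_CORR = np.array(
    [
        #  age   height weight meno
        [1.00, -0.30, -0.15, 0.10],
        [-0.30, 1.00, 0.40, 0.00],
        [-0.15, 0.40, 1.00, 0.00],
        [0.10, 0.00, 0.00, 1.00],
    ]
)

#: Marginal prevalence of each questionnaire factor (among responders).
DEFAULT_PREVALENCES = {
    "previous_fracture": 0.150,
    "parent_hip_fracture": 0.107,
    "current_smoking": 0.013,
    "glucocorticoids": 0.068,
    "rheumatoid_arthritis": 0.074,
    "secondary_osteoporosis": 0.084,
    "alcohol_3plus_units": 0.007,
}

#: Per-question response rates (observed denominators / cohort size).
DEFAULT_RESPONSE_RATES = {
    "previous_fracture": 0.708,
    "parent_hip_fracture": 0.643,
    "current_smoking": 0.717,
    "glucocorticoids": 0.699,
    "rheumatoid_arthritis": 0.698,
    "secondary_osteoporosis": 0.708,
    "alcohol_3plus_units": 0.712,
}

#: Mean-age offset (years, yes minus no) per factor. Chosen so the
#: generator reproduces the published univariate-vs-multivariable beta
#: attenuation for the binary factors (fracture cases are older; smokers
#: and glucocorticoid users slightly younger).
DEFAULT_AGE_SHIFT_YEARS = {
    "previous_fracture": 6.5,
    "parent_hip_fracture": 0.0,
    "current_smoking": -1.8,
    "glucocorticoids": -2.1,
    "rheumatoid_arthritis": 0.0,
    "secondary_osteoporosis": 0.0,
    "alcohol_3plus_units": 0.0,
}

#: Structural per-unit effects on every site's T-score (SD units per year,
#: per cm, per kg, and yes-vs-no). Published per-10-unit multivariable
#: betas divided by 10 for the continuous variables; factors that were
#: null in the published univariate screen get no effect.
DEFAULT_COEFFICIENTS = {
    "age": -0.0364,
    "height_cm": 0.0175,
    "weight_kg": 0.0343,
    "menopause_age": 0.0161,
    "previous_fracture": -0.228,
    "parent_hip_fracture": 0.0,
    "current_smoking": -0.293,
    "glucocorticoids": -0.198,
    "rheumatoid_arthritis": 0.0,
    "secondary_osteoporosis": 0.0,
    "alcohol_3plus_units": 0.0,
}

#: Target marginal T-score means per site (before prevalence calibration).
DEFAULT_SITE_MEANS = {"lumbar_spine": -1.8, "femoral_neck": -1.8, "total_hip": -1.0}

#: Noise split chosen so marginal T-score SDs are ~1.3/1.1/1.1 and the
#: three sites correlate ~0.6.
DEFAULT_SHARED_NOISE_SD = 0.74
DEFAULT_SITE_NOISE_SDS = {"lumbar_spine": 0.91, "femoral_neck": 0.59, "total_hip": 0.59}

SITE_T_COLUMNS = {
    "lumbar_spine": "t_lumbar",
    "femoral_neck": "t_femoral_neck",
    "total_hip": "t_total_hip",
}


@dataclass
class GeneratorConfig:
    """All knobs of the cohort generator; defaults emulate the study cohort."""

    n: int = 12175
    seed: int = 0
    means: dict = field(default_factory=lambda: dict(DEFAULT_MEANS))
    sds: dict = field(default_factory=lambda: dict(DEFAULT_SDS))
    corr: np.ndarray = field(default_factory=lambda: DEFAULT_CORR.copy())
    prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    response_rates: dict = field(default_factory=lambda: dict(DEFAULT_RESPONSE_RATES))
    age_shift_years: dict = field(default_factory=lambda: dict(DEFAULT_AGE_SHIFT_YEARS))
    coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    site_means: dict = field(default_factory=lambda: dict(DEFAULT_SITE_MEANS))
    shared_noise_sd: float = DEFAULT_SHARED_NOISE_SD
    site_noise_sds: dict = field(default_factory=lambda: dict(DEFAULT_SITE_NOISE_SDS))
    target_prevalence: float = 0.413
    prevalence_tolerance: float = 0.005
    calibration_n: int = 200_000
    truncation_sd: float = 4.0

    def __post_init__(self):
        self.corr = np.asarray(self.corr, dtype=float)
        if self.n < 1:
            raise DomainError("n must be >= 1")
        if not np.allclose(self.corr, self.corr.T):
            raise DomainError("correlation matrix must be symmetric")
        try:
            np.linalg.cholesky(self.corr)
        except np.linalg.LinAlgError:
            raise DomainError("correlation matrix must be positive definite") from None
        for label, probs in (("prevalence", self.prevalences),
                             ("response rate", self.response_rates)):
            for name, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise DomainError(f"{label} for {name} outside [0, 1]: {p}")
        if not 0.0 < self.target_prevalence < 1.0:
            raise DomainError("target prevalence must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "n": self.n, "seed": self.seed,
            "means": self.means, "sds": self.sds, "corr": self.corr.tolist(),
            "prevalences": self.prevalences, "response_rates": self.response_rates,
            "age_shift_years": self.age_shift_years, "coefficients": self.coefficients,
            "site_means": self.site_means, "shared_noise_sd": self.shared_noise_sd,
            "site_noise_sds": self.site_noise_sds,
            "target_prevalence": self.target_prevalence,
            "prevalence_tolerance": self.prevalence_tolerance,
            "calibration_n": self.calibration_n, "truncation_sd": self.truncation_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "corr" in d:
            d["corr"] = np.asarray(d["corr"], dtype=float)
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator actually used — for parameter-recovery tests."""

    coefficients: dict
    intercepts: dict  # per site, after prevalence calibration
    intercept_shift: float
    shared_noise_sd: float
    site_noise_sds: dict
    true_risk_factors: pd.DataFrame  # pre-masking 0/1 values
    systematic: np.ndarray  # per-participant linear predictor (no intercept)
    seed: int


def _truncated_mvn(rng: np.random.Generator, n: int, cfg: GeneratorConfig) -> np.ndarray:
    """Correlated standard-normal draws, rejecting rows beyond +/-k SD."""
    chol = np.linalg.cholesky(cfg.corr)
    k = cfg.truncation_sd
    out = np.empty((n, len(CONTINUOUS)))
    filled = 0
    while filled < n:
        need = n - filled
        z = rng.standard_normal((int(need * 1.05) + 16, len(CONTINUOUS))) @ chol.T
        keep = z[(np.abs(z) <= k).all(axis=1)]
        take = min(len(keep), need)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _logistic_intercept(p_target: float, slope: float) -> float:
    """Intercept a with E[expit(a + slope*z)] = p_target over z ~ N(0,1)."""
    if slope == 0.0:
        return float(np.log(p_target / (1 - p_target))) if 0 < p_target < 1 else np.inf
    nodes = norm.ppf((np.arange(400) + 0.5) / 400)

    def f(a):
        return expit(a + slope * nodes).mean() - p_target

    return float(brentq(f, -30, 30, xtol=1e-12))


def _draw_block(rng: np.random.Generator, n: int, cfg: GeneratorConfig):
    """One block of participants: continuous vars, true binaries, T-score
    parts (systematic + noise, before intercepts)."""
    z = _truncated_mvn(rng, n, cfg)
    cont = {}
    for j, col in enumerate(CONTINUOUS):
        cont[col] = cfg.means[col] + cfg.sds[col] * z[:, j]
    # enforce menopause_age <= age (rare tail of the joint normal)
    cont["menopause_age"] = np.minimum(cont["menopause_age"], cont["age"])

    z_age = (cont["age"] - cfg.means["age"]) / cfg.sds["age"]
    true_rf = {}
    for rf in RISK_FACTORS:
        slope = cfg.age_shift_years.get(rf, 0.0) / cfg.sds["age"]
        if slope == 0.0:
            p = np.full(n, cfg.prevalences[rf])
        else:
            a = _logistic_intercept(cfg.prevalences[rf], slope)
            p = expit(a + slope * z_age)
        true_rf[rf] = (rng.random(n) < p).astype(float)

    sys = np.zeros(n)
    for col in CONTINUOUS:
        sys += cfg.coefficients.get(col, 0.0) * cont[col]
    for rf in RISK_FACTORS:
        sys += cfg.coefficients.get(rf, 0.0) * true_rf[rf]

    shared = rng.normal(0.0, cfg.shared_noise_sd, size=n)
    site_noise = {
        site: rng.normal(0.0, sd, size=n) for site, sd in cfg.site_noise_sds.items()
    }
    return cont, true_rf, sys, shared, site_noise


def _base_intercepts(cfg: GeneratorConfig) -> dict:
    """Intercepts putting each site's mean T at its configured target."""
    mean_sys = sum(cfg.coefficients.get(c, 0.0) * cfg.means[c] for c in CONTINUOUS)
    mean_sys += sum(
        cfg.coefficients.get(rf, 0.0) * cfg.prevalences[rf] for rf in RISK_FACTORS
    )
    return {site: cfg.site_means[site] - mean_sys for site in SITE_T_COLUMNS}


def _calibrate_shift(rng: np.random.Generator, cfg: GeneratorConfig,
                     base_int: dict, max_iter: int = 200) -> float:
    """Bisection on a common intercept shift so that the realised prevalence
    of lowest-site T <= -2.5 matches the target on a calibration sample."""
    _, _, sys, shared, site_noise = _draw_block(rng, cfg.calibration_n, cfg)
    lowest = np.min(
        np.column_stack(
            [base_int[s] + sys + shared + site_noise[s] for s in SITE_T_COLUMNS]
        ),
        axis=1,
    )

    def prev(delta):
        return float(np.mean(lowest + delta <= T_THRESHOLD))

    lo, hi = -4.0, 4.0
    if not (prev(hi) <= cfg.target_prevalence <= prev(lo)):
        raise DomainError(
            f"prevalence calibration cannot bracket target {cfg.target_prevalence}: "
            f"range [{prev(hi):.4f}, {prev(lo):.4f}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if prev(mid) > cfg.target_prevalence:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    delta = 0.5 * (lo + hi)
    if abs(prev(delta) - cfg.target_prevalence) > cfg.prevalence_tolerance:
        raise DomainError(
            f"prevalence calibration failed: reached {prev(delta):.4f} "
            f"for target {cfg.target_prevalence} after {max_iter} iterations"
        )
    return delta


def generate_cohort(
    config: Optional[GeneratorConfig] = None,
    n: Optional[int] = None,
    seed: Optional[int] = None,
):
    """Generate a study-like cohort; returns ``(Cohort, GroundTruth)``.

    ``n`` and ``seed`` override the config's values when given.
    """
    cfg = config or GeneratorConfig()
    if n is not None or seed is not None:
        cfg = replace(cfg, n=n if n is not None else cfg.n,
                      seed=seed if seed is not None else cfg.seed)

    ss = np.random.SeedSequence(cfg.seed)
    calib_seed, main_seed = ss.spawn(2)
    base_int = _base_intercepts(cfg)
    shift = _calibrate_shift(np.random.Generator(np.random.PCG64(calib_seed)), cfg, base_int)
    intercepts = {s: base_int[s] + shift for s in SITE_T_COLUMNS}

    rng = np.random.Generator(np.random.PCG64(main_seed))
    cont, true_rf, sys, shared, site_noise = _draw_block(rng, cfg.n, cfg)

    data = {
        "id": [f"S{i + 1:06d}" for i in range(cfg.n)],
        "sex": ["female"] * cfg.n,
        "menopausal": ["post"] * cfg.n,
    }
    for col in CONTINUOUS:
        data[col] = np.round(cont[col], 2)
    for site, col in SITE_T_COLUMNS.items():
        data[col] = np.round(intercepts[site] + sys + shared + site_noise[site], 3)
    for rf in RISK_FACTORS:
        observed = true_rf[rf].copy()
        observed[rng.random(cfg.n) >= cfg.response_rates[rf]] = np.nan
        data[rf] = observed

    df = pd.DataFrame({c: data[c] for c in SCHEMA_COLUMNS})
    truth = GroundTruth(
        coefficients=dict(cfg.coefficients),
        intercepts=intercepts,
        intercept_shift=shift,
        shared_noise_sd=cfg.shared_noise_sd,
        site_noise_sds=dict(cfg.site_noise_sds),
        true_risk_factors=pd.DataFrame(true_rf),
        systematic=sys,
        seed=cfg.seed,
    )
    return Cohort(data=df), truth


# ---------------------------------------------------------------------------
# Pathology injection for QC-pipeline tests


@dataclass
class PathologySpec:
    """What to inject into a clean cohort to exercise the QC rules."""

    males: int = 0
    premenopausal: int = 0
    missing_bmd_frac: float = 0.0
    extremes: dict = field(default_factory=dict)  # column -> count
    extreme_sd_multiple: float = 5.0
    seed: int = 0


def inject_pathologies(cohort: Cohort, spec: PathologySpec):
    """Return (modified cohort, manifest of id -> expected exclusion reason).

    Males and premenopausal women are appended as new rows (cloned from
    random existing rows); missing T-scores and extreme values modify
    randomly chosen existing rows. Each existing row receives at most one
    pathology so the manifest maps one-to-one onto QC reasons.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    df = cohort.data.copy().reset_index(drop=True)
    manifest = {}
    existing = set(df["id"])

    def _new_id(prefix, i):
        pid = f"INJ-{prefix}-{i + 1}"
        if pid in existing:
            raise DomainError(f"injection id collision: {pid}")
        existing.add(pid)
        return pid

    new_rows = []
    for i in range(spec.males):
        row = df.iloc[int(rng.integers(len(df)))].copy()
        row["id"] = _new_id("M", i)
        row["sex"] = "male"
        manifest[row["id"]] = "male"
        new_rows.append(row)
    for i in range(spec.premenopausal):
        row = df.iloc[int(rng.integers(len(df)))].copy()
        row["id"] = _new_id("P", i)
        row["sex"] = "female"
        row["menopausal"] = "pre"
        manifest[row["id"]] = "not_postmenopausal"
        new_rows.append(row)

    untouched = np.arange(len(df))
    rng.shuffle(untouched)
    untouched = list(untouched)

    n_missing = int(round(spec.missing_bmd_frac * len(df)))
    t_cols = list(SITE_T_COLUMNS.values())
    for _ in range(n_missing):
        idx = untouched.pop()
        col = t_cols[int(rng.integers(len(t_cols)))]
        df.loc[idx, col] = np.nan
        manifest[df.loc[idx, "id"]] = "missing_bmd"

    for col, count in spec.extremes.items():
        vals = df[col].astype(float)
        mean, sd = vals.mean(), vals.std(ddof=1)
        for _ in range(count):
            idx = untouched.pop()
            df.loc[idx, col] = mean + spec.extreme_sd_multiple * sd
            manifest[df.loc[idx, "id"]] = "extreme_value"

    if new_rows:
        df = pd.concat([df, pd.DataFrame(new_rows)], ignore_index=True)
    return Cohort(data=df, qc_log=cohort.qc_log.copy()), manifest
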