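"""Published summary statistics from the OSTAi development cohort.

The index was developed on a nationwide Taiwanese DXA screening survey of
12,175 postmenopausal women (osteoporosis prevalence 41.3% by the
lowest-site WHO rule). The raw cohort is not distributed with this package;
these printed summary values serve as fixed verification fixtures for the
scoring, weighting, and evaluation machinery (``ostai reproduce --fixtures
published``) and as test oracles.
"""

from __future__ import annotations

from .derivation import RegressionFit
from .evaluation import ConfusionMatrix

COHORT_N = 12175
N_OSTEOPOROTIC = 5027
N_NON_OSTEOPOROTIC = 7148

#: OSTAi at cutoff -1: 6,393 referred, 2x2 counts (tp, fp, fn, tn).
OSTAI_CONFUSION = ConfusionMatrix(tp=3674, fp=2719, fn=1353, tn=4429)

#: NOF 2013 referral rule on the same cohort.
NOF_CONFUSION = ConfusionMatrix(tp=3936, fp=3813, fn=1091, tn=3335)

#: Osteoporotic women by exact site subset (T <= -2.5), keyed by site names.
SITE_COMBINATIONS = {
    ("lumbar_spine",): 1896,
    ("femoral_neck",): 850,
    ("total_hip",): 16,
    ("lumbar_spine", "femoral_neck"): 1209,
    ("lumbar_spine", "total_hip"): 31,
    ("femoral_neck", "total_hip"): 176,
    ("lumbar_spine", "femoral_neck", "total_hip"): 849,
}

#: Osteoporosis cases / totals within the OSTAi risk bands
#: (low >= -1, medium between, high <= -4).
CATEGORY_COUNTS = {
    "low": (1353, 5782),
    "medium": (1418, 3170),
    "high": (2256, 3223),
}

#: Multivariable regression of the lowest-site T-score on the seven
#: retained variables (betas per 10 years / 10 cm / 10 kg, yes-vs-no).
MULTIVARIABLE_FITS = [
    RegressionFit("age", -0.364, 0.011, 1e-4),
    RegressionFit("height", 0.175, 0.019, 1e-4),
    RegressionFit("weight", 0.343, 0.012, 1e-4),
    RegressionFit("menopause_age", 0.161, 0.022, 1e-4),
    RegressionFit("previous_fracture", -0.228, 0.028, 1e-4),
    RegressionFit("current_smoking", -0.293, 0.090, 0.001),
    RegressionFit("glucocorticoids", -0.198, 0.039, 1e-4),
]

#: Univariate screening stage: (beta, se, p) for every FRAX candidate.
UNIVARIATE_FITS = [
    RegressionFit("age", -0.433, 0.009, 1e-4),
    RegressionFit("height", 0.573, 0.016, 1e-4),
    RegressionFit("weight", 0.439, 0.010, 1e-4),
    RegressionFit("menopause_age", 0.145, 0.021, 1e-4),
    RegressionFit("previous_fracture", -0.464, 0.032, 1e-4),
    RegressionFit("current_smoking", -0.227, 0.102, 0.026),
    RegressionFit("glucocorticoids", -0.122, 0.046, 0.008),
    RegressionFit("parent_hip_fracture", 0.018, 0.039, 0.634),
    RegressionFit("rheumatoid_arthritis", -0.026, 0.044, 0.552),
    RegressionFit("secondary_osteoporosis", 0.064, 0.041, 0.124),
    RegressionFit("alcohol_3plus_units", -0.002, 0.140, 0.987),
]

#: Integer index weights printed alongside the multivariable betas.
INDEX_WEIGHTS = {
    "age": -2,
    "height": 1,
    "weight": 2,
    "menopause_age": 1,
    "previous_fracture": -1,
    "current_smoking": -2,
    "glucocorticoids": -1,
}

#: Reported discrimination of the continuous models.
AUC_SEVEN_VARIABLE = 0.749
AUC_AGE_WEIGHT = 0.739

SELECTED_CUTOFF = -1
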