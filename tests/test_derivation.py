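"""Index derivation: screening, multivariable fit, weighting, reduction, cutoff."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ostai import (
    Cohort,
    DomainError,
    IndexModel,
    RegressionFit,
    derive_index,
    fit_multivariable,
    generate_cohort,
    item_reduction,
    make_index_weights,
    ostai_score,
    select_cutoff,
    univariate_screen,
)
from ostai.derivation import concordance, flag_retained
from ostai.published import INDEX_WEIGHTS, MULTIVARIABLE_FITS, UNIVARIATE_FITS
from ostai.scoring import round_half_away


class TestUnivariateScreen:
    def test_published_p_values_split_candidates(self):
        """The four null factors are dropped at alpha=0.05, the rest retained."""
        fits = flag_retained(UNIVARIATE_FITS, alpha=0.05)
        retained = {f.variable for f in fits if f.retained}
        assert retained == {"age", "height", "weight", "menopause_age",
                            "previous_fracture", "current_smoking", "glucocorticoids"}

    def test_alpha_one_retains_everything(self, small_cohort):
        cohort, _ = small_cohort
        fits = univariate_screen(cohort, alpha=1.0)
        assert all(f.retained for f in fits if f.note is None)

    def test_truly_associated_variable_retained_nulls_near_alpha(self):
        """With one real signal, the screen keeps it and keeps nulls ~alpha."""
        null_hits = []
        for seed in range(12):
            cohort, _ = generate_cohort(n=5000, seed=100 + seed)
            fits = {f.variable: f for f in univariate_screen(cohort)}
            assert fits["age"].retained and fits["weight"].retained
            null_hits += [fits[v].retained for v in
                          ("parent_hip_fracture", "rheumatoid_arthritis",
                           "secondary_osteoporosis", "alcohol_3plus_units")]
        assert np.mean(null_hits) < 0.25  # ~alpha, generous Monte-Carlo bound

    def test_zero_variance_candidate_skipped(self, small_cohort):
        cohort, _ = small_cohort
        df = cohort.data.copy()
        df["current_smoking"] = 0.0
        with pytest.warns(UserWarning, match="zero variance"):
            fits = univariate_screen(Cohort(data=df))
        smoking = next(f for f in fits if f.variable == "current_smoking")
        assert not smoking.retained and smoking.note == "zero_variance"


class TestFitMultivariable:
    def test_identity_response_recovers_scaling(self, small_cohort):
        """Response == age exactly: age beta equals its 10-unit scaling, rest 0."""
        cohort, _ = small_cohort
        df = cohort.data.copy()
        for col in ("t_lumbar", "t_femoral_neck", "t_total_hip"):
            df[col] = df["age"]
        fits = {f.variable: f for f in
                fit_multivariable(Cohort(data=df), ["age", "weight", "height"])}
        assert fits["age"].beta == pytest.approx(10.0, abs=1e-8)
        assert fits["weight"].beta == pytest.approx(0.0, abs=1e-8)
        assert fits["height"].beta == pytest.approx(0.0, abs=1e-8)

    def test_parameter_recovery_within_3se(self, study_cohort):
        """Recovered per-10-unit betas sit within 3 SE of the generator truth."""
        cohort, truth = study_cohort
        variables = ["age", "height", "weight", "menopause_age",
                     "previous_fracture", "current_smoking", "glucocorticoids"]
        fits = fit_multivariable(cohort, variables)
        per10 = {"age": -0.364, "height": 0.175, "weight": 0.343,
                 "menopause_age": 0.161, "previous_fracture": -0.228,
                 "current_smoking": -0.293, "glucocorticoids": -0.198}
        for f in fits:
            assert abs(f.beta - per10[f.variable]) < 3 * f.se, f

    def test_collinear_design_rejected(self, small_cohort):
        cohort, _ = small_cohort
        df = cohort.data.copy()
        df["menopause_age"] = df["age"]  # exact collinearity
        with pytest.raises(DomainError, match="collinear"):
            fit_multivariable(Cohort(data=df), ["age", "menopause_age", "weight"])

    def test_insufficient_complete_cases_rejected(self, small_cohort):
        cohort, _ = small_cohort
        tiny = Cohort(data=cohort.data.head(25).reset_index(drop=True))
        with pytest.raises(DomainError, match="complete cases"):
            fit_multivariable(tiny, ["age", "weight", "height"])


class TestMakeIndexWeights:
    def test_reproduces_published_weight_column(self):
        model = make_index_weights(MULTIVARIABLE_FITS)
        assert {v: model.weights[v] for v in model.variables} == INDEX_WEIGHTS

    def test_min_abs_anchor_also_reproduces_published_weights(self):
        model = make_index_weights(MULTIVARIABLE_FITS, anchor="min_abs")
        assert {v: model.weights[v] for v in model.variables} == INDEX_WEIGHTS
        assert model.scale_anchor == pytest.approx(0.161)

    def test_equal_betas_self_anchor(self):
        fits = [RegressionFit(v, 0.37, 0.01, 1e-4) for v in ("age", "height", "weight")]
        model = make_index_weights(fits, anchor="min_abs")
        assert all(w == 1 for w in model.weights.values())

    def test_matches_oneline_recomputation_on_random_betas(self):
        """weights == round(beta / anchor) for 1000 random beta vectors."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            k = rng.integers(2, 8)
            betas = rng.uniform(0.05, 2.0, size=k) * rng.choice([-1, 1], size=k)
            fits = [RegressionFit(f"v{i}", b, 0.01, 1e-4) for i, b in enumerate(betas)]
            for anchor, scale in (("min_abs", np.min(np.abs(betas))),
                                  ("half_max", np.max(np.abs(betas)) / 2)):
                model = make_index_weights(fits, anchor=anchor)
                expected = round_half_away(betas / scale)
                expected[expected == 0] = np.sign(betas)[expected == 0]
                assert [model.weights[f"v{i}"] for i in range(k)] == list(expected)

    @given(scale=st.floats(0.01, 100), seed=st.integers(0, 10_000))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        betas = rng.uniform(0.1, 1.0, size=5) * rng.choice([-1, 1], size=5)
        fits1 = [RegressionFit(f"v{i}", b, 0.01, 1e-4) for i, b in enumerate(betas)]
        fits2 = [RegressionFit(f"v{i}", b * scale, 0.01, 1e-4) for i, b in enumerate(betas)]
        w1 = make_index_weights(fits1).weights
        w2 = make_index_weights(fits2).weights
        assert w1 == w2

    def test_zero_beta_rejected(self):
        with pytest.raises(DomainError):
            make_index_weights([RegressionFit("a", 0.0, 0.01, 0.9),
                                RegressionFit("b", 0.3, 0.01, 1e-4)])


def _age_weight_model(cutoff=None):
    return IndexModel(
        variables=("age", "weight"),
        weights={"age": -2, "weight": 2},
        increments={"age": 10.0, "weight": 10.0},
        referents={"age": 50.0, "weight": 50.0},
        scale_anchor=0.182,
        cutoff=cutoff,
    )


class TestIndexModelScoring:
    def test_age_weight_model_equals_published_formula(self, small_cohort):
        """The derived two-variable model and the published OSTAi agree exactly."""
        cohort, _ = small_cohort
        model = _age_weight_model()
        values = model.scores(cohort.data)
        for (_, row), v in zip(cohort.data.iterrows(), values):
            assert ostai_score(row["age"], row["weight_kg"]).value == v


class TestItemReduction:
    def test_reduction_finds_age_weight_on_study_like_cohort(self, study_cohort):
        cohort, _ = study_cohort
        res = derive_index(cohort)
        assert set(res.reduced_model.variables) == {"age", "weight"}
        assert res.reduced_model.weights == {"age": -2, "weight": 2}
        assert [v for v, _ in res.reduced_model.elimination_trace]  # trace recorded
        assert 0.70 < res.auc_reduced < 0.80

    def test_tol_zero_informative_variables_kept(self):
        """With tol 0 and strongly informative variables nothing is dropped."""
        rng = np.random.default_rng(5)
        n = 4000
        df = pd.DataFrame({
            "id": [str(i) for i in range(n)],
            "sex": "female", "menopausal": "post",
            "age": rng.normal(66, 9.6, n),
            "height_cm": rng.normal(154, 5.8, n),
            "weight_kg": rng.normal(57, 8.8, n),
            "menopause_age": rng.normal(49, 4.5, n),
        })
        for rf in ("previous_fracture", "parent_hip_fracture", "current_smoking",
                   "glucocorticoids", "rheumatoid_arthritis",
                   "secondary_osteoporosis", "alcohol_3plus_units"):
            df[rf] = 0.0
        # two equally strong, independent drivers and almost no noise
        t = -2.5 + 0.08 * (df["weight_kg"] - 57) - 0.08 * (df["age"] - 66) \
            + rng.normal(0, 0.05, n)
        for col in ("t_lumbar", "t_femoral_neck", "t_total_hip"):
            df[col] = t
        cohort = Cohort(data=df)
        fits = fit_multivariable(cohort, ["age", "weight"])
        model = make_index_weights(fits)
        reduced = item_reduction(cohort, model, tol_auc=0.0)
        assert set(reduced.variables) == {"age", "weight"}

    def test_single_variable_model_returned_with_warning(self, small_cohort):
        cohort, _ = small_cohort
        model = IndexModel(variables=("age",), weights={"age": -2},
                           increments={"age": 10.0}, referents={"age": 50.0},
                           scale_anchor=0.18)
        with pytest.warns(UserWarning, match="2 variables"):
            out = item_reduction(cohort, model)
        assert out.variables == ("age",)


class TestSelectCutoff:
    def test_perfect_separation_tie_breaks_high(self):
        n = 40
        df = pd.DataFrame({
            "id": [str(i) for i in range(n)],
            "sex": "female", "menopausal": "post",
            "age": 65.0, "height_cm": 155.0, "menopause_age": 49.0,
        })
        # cases score 0.2*(50-65) = -3, controls score 0.2*(65-65) = 0
        case = np.arange(n) < 15
        df["weight_kg"] = np.where(case, 50.0, 65.0)
        for col in ("t_lumbar", "t_femoral_neck", "t_total_hip"):
            df[col] = np.where(case, -3.0, -1.0)
        for rf in ("previous_fracture", "parent_hip_fracture", "current_smoking",
                   "glucocorticoids", "rheumatoid_arthritis",
                   "secondary_osteoporosis", "alcohol_3plus_units"):
            df[rf] = 0.0
        cutoff = select_cutoff(Cohort(data=df), _age_weight_model())
        assert cutoff == 0  # any of {-2, -1, 0} gives J=1; tie-break picks 0

    def test_matches_exhaustive_j_maximisation(self):
        cohort, _ = generate_cohort(n=12000, seed=21)
        model = _age_weight_model()
        cutoff = select_cutoff(cohort, model)

        scores = model.scores(cohort.data).to_numpy()
        from ostai.cohort import osteoporosis_frame
        case = osteoporosis_frame(cohort.data)["osteoporotic"].to_numpy()
        best = None
        for c in range(int(scores.min()), int(scores.max()) + 1):
            pos = scores < c
            j = (pos & case).sum() / case.sum() + (~pos & ~case).sum() / (~case).sum() - 1
            if best is None or j > best[0] + 1e-12 or abs(j - best[0]) <= 1e-12:
                best = (j, c)
        assert cutoff == best[1]

    def test_uninformative_score_warns_flat_j(self):
        cohort, _ = generate_cohort(n=10000, seed=31)
        df = cohort.data.copy()
        rng = np.random.default_rng(0)
        df["age"] = rng.permutation(df["age"].to_numpy())  # break the association
        df["weight_kg"] = rng.permutation(df["weight_kg"].to_numpy())
        with pytest.warns(UserWarning, match="flat"):
            select_cutoff(Cohort(data=df), _age_weight_model())

    def test_degenerate_cohort_rejected(self, small_cohort):
        cohort, _ = small_cohort
        df = cohort.data.copy()
        for col in ("t_lumbar", "t_femoral_neck", "t_total_hip"):
            df[col] = -3.0  # everyone is a case
        with pytest.raises(DomainError):
            select_cutoff(Cohort(data=df), _age_weight_model())


class TestConcordance:
    def test_matches_pairwise_definition(self):
        rng = np.random.default_rng(3)
        risk = rng.integers(-5, 5, size=200).astype(float)
        case = rng.random(200) < 0.4
        auc = concordance(case, risk)
        pos, neg = risk[case], risk[~case]
        brute = np.mean((pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :]))
        assert auc == pytest.approx(brute, abs=1e-12)
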