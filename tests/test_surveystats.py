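"""Design-based logistic regression: IRLS point estimates, linearized
variances, subgroup/interaction machinery, weighted descriptives."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pharmepi import surveystats, synthdata
from pharmepi.surveystats import (
    DegenerateOutcomeError,
    ModelSpec,
    SeparationError,
    SurveyDesign,
    fit_weighted_logistic,
    interaction_test,
    linearized_covariance,
    model_series,
    subgroup_analysis,
    weighted_descriptives,
)


def iid_design(n, weight=1.0):
    """Equal weights, one stratum, every record its own PSU."""
    return SurveyDesign(np.full(n, weight), np.zeros(n, int), np.arange(n))


def small_fit_frame(n=400, seed=0):
    rng = np.random.default_rng(seed)
    exposed = rng.random(n) < 0.3
    p = 1 / (1 + np.exp(-(-1.0 + 0.8 * exposed)))
    y = rng.random(n) < p
    return pd.DataFrame(
        {
            "exposure": np.where(exposed, "exposed", "control"),
            "outcome": np.where(y, "memory_loss", "none"),
        }
    )


class TestFit:
    def test_iid_collapse_matches_unweighted_mle(self, default_cohort):
        """Equal weights + singleton PSUs reproduce ordinary ML estimates."""
        cohort, _ = default_cohort
        cohort = cohort.head(3000)
        fit = fit_weighted_logistic(
            cohort, iid_design(len(cohort)), ModelSpec(tier="model3")
        )
        from pharmepi.surveystats import build_design_matrix

        Xdf, y = build_design_matrix(cohort, ModelSpec(tier="model3"))
        ref = sm.Logit(y, Xdf.to_numpy(float)).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-6)

    def test_linearized_covariance_matches_longhand(self):
        """Sandwich assembly equals an explicit loop-written computation."""
        rng = np.random.default_rng(3)
        n = 80
        df = small_fit_frame(n, seed=3)
        w = rng.uniform(0.5, 3.0, n)
        stratum = rng.integers(0, 2, n)
        psu = rng.integers(0, 2, n)
        design = SurveyDesign(w, stratum, psu)
        fit = fit_weighted_logistic(df, design, ModelSpec(tier="model1"))

        X = np.column_stack([np.ones(n), (df["exposure"] == "exposed").to_numpy(float)])
        y = (df["outcome"] == "memory_loss").to_numpy(float)
        beta = fit.params.to_numpy()
        p = 1 / (1 + np.exp(-X @ beta))
        info = np.zeros((2, 2))
        for i in range(n):
            info += w[i] * p[i] * (1 - p[i]) * np.outer(X[i], X[i])
        G = np.zeros((2, 2))
        for s in (0, 1):
            totals = []
            for u in (0, 1):
                mask = (stratum == s) & (psu == u)
                totals.append(
                    sum(w[i] * (y[i] - p[i]) * X[i] for i in np.flatnonzero(mask))
                )
            zbar = (totals[0] + totals[1]) / 2
            for t in totals:
                G += 2.0 * np.outer(t - zbar, t - zbar)  # n_h/(n_h-1) = 2
        expected = np.linalg.inv(info) @ G @ np.linalg.inv(info)
        np.testing.assert_allclose(fit.cov.to_numpy(), expected, rtol=1e-8)
        assert fit.df_design == 4 - 2

    def test_point_estimates_maximise_weighted_likelihood(self):
        """IRLS solution agrees with a generic optimiser on the same objective."""
        from scipy.optimize import minimize

        df = small_fit_frame(300, seed=8)
        rng = np.random.default_rng(8)
        w = rng.uniform(0.2, 5.0, len(df))
        design = SurveyDesign(w, np.zeros(len(df), int), np.arange(len(df)))
        fit = fit_weighted_logistic(df, design, ModelSpec(tier="model1"))

        X = np.column_stack([np.ones(len(df)), (df["exposure"] == "exposed").to_numpy(float)])
        y = (df["outcome"] == "memory_loss").to_numpy(float)

        def nll(beta):
            eta = X @ beta
            return -np.sum(w * (y * eta - np.log1p(np.exp(eta))))

        ref = minimize(nll, np.zeros(2), method="BFGS")
        np.testing.assert_allclose(fit.params.to_numpy(), ref.x, atol=1e-5)

    def test_weight_rescaling_changes_nothing(self, default_cohort):
        cohort, _ = default_cohort
        cohort = cohort.head(4000)
        d1 = SurveyDesign.from_frame(cohort)
        d2 = SurveyDesign(d1.weight * 7.5, d1.stratum, d1.psu)
        f1 = fit_weighted_logistic(cohort, d1, ModelSpec(tier="model3"))
        f2 = fit_weighted_logistic(cohort, d2, ModelSpec(tier="model3"))
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-10)
        np.testing.assert_allclose(
            f1.summary[["se", "p_value"]], f2.summary[["se", "p_value"]], atol=1e-10
        )

    def test_fitresult_invariants(self, default_cohort):
        cohort, _ = default_cohort
        fit = fit_weighted_logistic(
            cohort, SurveyDesign.from_frame(cohort), ModelSpec(tier="model2")
        )
        V = fit.cov.to_numpy()
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(V) > -1e-10)
        s = fit.summary
        assert (s["ci_low"] <= s["odds_ratio"]).all()
        assert (s["odds_ratio"] <= s["ci_high"]).all()
        np.testing.assert_allclose(s["odds_ratio"], np.exp(s["coef"]), rtol=1e-12)

    def test_degenerate_outcome_raises(self):
        df = small_fit_frame(100, seed=1)
        df["outcome"] = "none"
        with pytest.raises(DegenerateOutcomeError):
            fit_weighted_logistic(df, iid_design(100), ModelSpec(tier="model1"))

    def test_complete_separation_detected(self):
        df = pd.DataFrame(
            {
                "exposure": ["exposed"] * 50 + ["control"] * 50,
                "outcome": ["memory_loss"] * 50 + ["none"] * 50,
            }
        )
        with pytest.raises(SeparationError):
            fit_weighted_logistic(df, iid_design(100), ModelSpec(tier="model1"))

    def test_planted_or_recovered_within_3se(self, default_cohort):
        cohort, truth = default_cohort
        fit = fit_weighted_logistic(
            cohort, SurveyDesign.from_frame(cohort), ModelSpec(tier="model3")
        )
        t = fit.term("exposure")
        se = fit.summary.loc["exposure", "se"]
        assert abs(np.log(t["odds_ratio"]) - truth.realized["log_conditional_or"]) < 3 * se

    def test_design_se_exceeds_iid_se_under_clustering(self):
        """Positive intra-PSU correlation inflates the design-based SE."""
        ratios = []
        for seed in range(5):
            cohort, _ = synthdata.gen_survey_cohort(
                synthdata.SurveyGenParams(
                    n_participants=4000, psu_effect_sd=0.6, seed=100 + seed
                )
            )
            spec = ModelSpec(tier="model1")
            f_design = fit_weighted_logistic(cohort, SurveyDesign.from_frame(cohort), spec)
            f_iid = fit_weighted_logistic(
                cohort,
                SurveyDesign(
                    cohort["survey_weight"].to_numpy(),
                    np.zeros(len(cohort), int),
                    np.arange(len(cohort)),
                ),
                spec,
            )
            ratios.append(
                f_design.summary.loc["exposure", "se"] / f_iid.summary.loc["exposure", "se"]
            )
        assert np.mean(ratios) > 1.0


class TestDesign:
    def test_positive_weights_enforced(self):
        with pytest.raises(ValueError):
            SurveyDesign(np.array([1.0, -1.0]), np.zeros(2), np.arange(2))

    def test_lonely_psu_warns_under_certainty_policy(self):
        with pytest.warns(UserWarning, match="lonely PSU"):
            SurveyDesign(np.ones(4), np.array([0, 0, 1, 1]), np.array([0, 1, 0, 0]))

    def test_lonely_psu_error_policy(self):
        with pytest.raises(ValueError, match="single PSU"):
            SurveyDesign(
                np.ones(4), np.array([0, 0, 1, 1]), np.array([0, 1, 0, 0]),
                lonely_psu="error",
            )

    def test_df_design_counts_psus_minus_strata(self, default_cohort):
        cohort, _ = default_cohort
        d = SurveyDesign.from_frame(cohort)
        assert d.df_design == 15 * 2 - 15


class TestModelSeries:
    def test_tiers_nested(self):
        tiers = surveystats.MODEL_TIERS
        assert set(tiers["model1"]) < set(tiers["model2"]) < set(tiers["model3"])

    def test_series_shows_confounding_pattern(self, default_cohort):
        """Adjustment moves the exposure OR downward toward the planted
        protective effect."""
        cohort, _ = default_cohort
        fits = model_series(cohort, SurveyDesign.from_frame(cohort))
        or1 = fits["model1"].term("exposure")["odds_ratio"]
        or3 = fits["model3"].term("exposure")["odds_ratio"]
        assert or3 < or1
        assert or3 < 1.0

    def test_single_tier_equals_direct_fit(self, default_cohort):
        cohort, _ = default_cohort
        design = SurveyDesign.from_frame(cohort)
        series = model_series(cohort, design, tiers=("model2",))
        direct = fit_weighted_logistic(cohort, design, ModelSpec(tier="model2"))
        np.testing.assert_allclose(series["model2"].params, direct.params, atol=1e-12)


def two_arm_cohort(n_per, or_a, or_b, seed, n_strata=15):
    """Two generator draws with different conditional ORs glued on gender."""
    ca, _ = synthdata.gen_survey_cohort(
        synthdata.SurveyGenParams(n_participants=n_per, true_conditional_or=or_a, seed=seed)
    )
    cb, _ = synthdata.gen_survey_cohort(
        synthdata.SurveyGenParams(n_participants=n_per, true_conditional_or=or_b, seed=seed + 1)
    )
    ca = ca.copy()
    cb = cb.copy()
    ca["gender"] = "female"
    cb["gender"] = "male"
    cb["stratum"] = cb["stratum"] + n_strata
    return pd.concat([ca, cb], ignore_index=True)


class TestSubgroups:
    def test_null_cohort_subgroups_near_null(self, null_cohort):
        cohort, _ = null_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            groups = subgroup_analysis(
                cohort, SurveyDesign.from_frame(cohort), "gender", tiers=("model1",)
            )
        # truth is log OR 0; allow generous Monte-Carlo + cluster noise
        for level, fits in groups.items():
            row = fits["model1"].summary.loc["exposure"]
            assert abs(row["coef"]) < 0.8, level

    def test_differential_effect_recovered(self):
        cohort = two_arm_cohort(6000, 0.5, 1.0, seed=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            groups = subgroup_analysis(
                cohort, SurveyDesign.from_frame(cohort), "gender", tiers=("model3",)
            )
        f_row = groups["female"]["model3"].summary.loc["exposure"]
        m_row = groups["male"]["model3"].summary.loc["exposure"]
        assert abs(f_row["coef"] - np.log(0.5)) < 3 * f_row["se"]
        assert abs(m_row["coef"] - 0.0) < 3 * m_row["se"]

    def test_constant_stratifier_warns_single_stratum(self, default_cohort):
        cohort, _ = default_cohort
        cohort = cohort.head(2000).copy()
        cohort["gender"] = "female"
        with pytest.warns(UserWarning, match="constant"):
            groups = subgroup_analysis(
                cohort, SurveyDesign.from_frame(cohort), "gender", tiers=("model1",)
            )
        assert list(groups) == ["female"]

    def test_unknown_stratifier_rejected(self, default_cohort):
        cohort, _ = default_cohort
        with pytest.raises(ValueError, match="unknown stratifier"):
            subgroup_analysis(cohort, SurveyDesign.from_frame(cohort), "race5")


class TestInteraction:
    def test_modifier_equal_to_exposure_rejected(self, default_cohort):
        cohort, _ = default_cohort
        with pytest.raises(ValueError, match="collinear"):
            interaction_test(cohort, SurveyDesign.from_frame(cohort), "exposure")

    def test_planted_interaction_detected(self):
        cohort = two_arm_cohort(8000, 0.2, 2.0, seed=70)
        p = interaction_test(cohort, SurveyDesign.from_frame(cohort), "gender")
        assert p < 0.001

    def test_null_interaction_type_i_error_calibrated(self):
        """With no planted interaction the test rejects at roughly its level."""
        hits = 0
        reps = 200
        for s in range(reps):
            cohort, _ = synthdata.gen_survey_cohort(
                synthdata.SurveyGenParams(n_participants=4000, seed=50_000 + s)
            )
            p = interaction_test(cohort, SurveyDesign.from_frame(cohort), "gender")
            hits += p < 0.05
        assert 0.01 <= hits / reps <= 0.10


class TestDescriptives:
    @pytest.fixture
    def tiny(self):
        df = pd.DataFrame(
            {
                "outcome": ["memory_loss"] * 3 + ["none"] * 4,
                "age": [60.0, 70.0, 50.0, 30.0, 40.0, 35.0, 45.0],
                "gender": ["male", "female", "male", "male", "female", "male", "female"],
                "survey_weight": [2.0, 1.0, 1.0, 3.0, 1.0, 1.0, 1.0],
                "stratum": [0, 0, 0, 0, 1, 1, 1],
                "psu": [0, 1, 0, 1, 0, 1, 0],
            }
        )
        return df, SurveyDesign.from_frame(df)

    def test_hand_computed_weighted_means(self, tiny):
        df, design = tiny
        out = weighted_descriptives(
            df, design, continuous=("age",), categorical=("gender",)
        )
        # memory_loss group: weights (2,1,1) on ages (60,70,50) -> 240/4 = 60
        # none group: weights (3,1,1,1) on ages (30,40,35,45) -> 210/6 = 35
        row = out[out["variable"] == "age"].iloc[0]
        assert row["memory_loss"].startswith("60.0")
        assert row["none"].startswith("35.0")
        overall = (2 * 60 + 70 + 50 + 3 * 30 + 40 + 35 + 45) / 10
        assert row["overall"].startswith(f"{overall:.1f}")

    def test_equal_weights_give_arithmetic_mean(self, tiny):
        df, _ = tiny
        df = df.assign(survey_weight=1.0)
        out = weighted_descriptives(
            df, SurveyDesign.from_frame(df), continuous=("age",), categorical=()
        )
        row = out.iloc[0]
        assert row["memory_loss"].startswith("60.0")  # (60+70+50)/3
        assert row["none"].startswith("37.5")

    def test_weight_doubling_invariance(self, tiny):
        df, design = tiny
        d2 = SurveyDesign(design.weight * 2, design.stratum, design.psu)
        a = weighted_descriptives(df, design, continuous=("age",), categorical=("gender",))
        b = weighted_descriptives(df, d2, continuous=("age",), categorical=("gender",))
        pd.testing.assert_frame_equal(a, b)

    def test_counts_unweighted_percentages_weighted(self, tiny):
        df, design = tiny
        out = weighted_descriptives(df, design, continuous=(), categorical=("gender",))
        male = out[(out["variable"] == "gender") & (out["level"] == "male")].iloc[0]
        # memory_loss males: records 1,3 -> count 2, weight 3 of 4 -> 75%
        assert male["memory_loss"] == "2 (75.0%)"
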