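"""Logistic fitting, stepwise AIC, interaction tests, descriptives."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polygre.regression import (
    ConvergenceError,
    EmptyCellError,
    ModelSpec,
    RankDeficiencyError,
    descriptive_table,
    fit_logistic,
    interaction_test,
    joint_effects,
    stepwise_aic,
)


def _two_by_two(a, b, c, d):
    """exposed cases a, exposed controls b, unexposed cases c, unexposed controls d."""
    return pd.DataFrame({
        "case": [1] * a + [0] * b + [1] * c + [0] * d,
        "x": [1.0] * (a + b) + [0.0] * (c + d),
    })


class TestFitLogistic:
    def test_two_by_two_matches_cross_product_or(self):
        data = _two_by_two(30, 10, 10, 30)
        m = fit_logistic(data, ModelSpec(exposure=None, adjust=("x",)))
        assert np.exp(m.params["x"]) == pytest.approx(9.0, abs=1e-6)

    def test_null_data_small_coefficients(self, rng):
        n = 2000
        data = pd.DataFrame({
            "case": rng.integers(0, 2, n),
            "x": rng.normal(size=n),
            "z": rng.normal(size=n),
        })
        m = fit_logistic(data, ModelSpec(exposure=None, adjust=("x", "z")))
        z_scores = (m.params / m.se()).drop("const")
        assert (z_scores.abs() < 4).all()

    def test_covariance_properties_and_aic(self, scored_cohort):
        spec = ModelSpec(exposure="exposure", adjust=("age", "sex"),
                         prs="percentile")
        m = fit_logistic(scored_cohort, spec)
        cov = m.cov.to_numpy()
        assert np.allclose(cov, cov.T, atol=1e-10)
        assert (np.linalg.eigvalsh(cov) > -1e-12).all()
        assert m.aic == pytest.approx(2 * m.k_params - 2 * m.loglik)
        tab = m.or_table()
        assert ((tab["ci_low"] <= tab["OR"]) & (tab["OR"] <= tab["ci_high"])).all()

    def test_exposure_or_brackets_and_counts(self, scored_cohort):
        m = fit_logistic(scored_cohort,
                         ModelSpec(exposure="exposure", adjust=("age", "sex")))
        for r in m.exposure_ors():
            assert r.ci_low <= r.odds_ratio <= r.ci_high
            assert r.n_cases > 0 and r.n_controls > 0

    def test_missing_rows_dropped_and_counted(self, scored_cohort):
        data = scored_cohort.copy()
        data.loc[data.index[:25], "age"] = np.nan
        m = fit_logistic(data, ModelSpec(exposure="exposure",
                                         adjust=("age", "sex")))
        assert m.n_dropped == 25
        assert m.n_used == len(data) - 25

    def test_separation_raises_diagnostic(self):
        data = pd.DataFrame({"case": [0] * 30 + [1] * 30,
                             "x": [0.0] * 30 + [1.0] * 30})
        with pytest.raises(ConvergenceError):
            fit_logistic(data, ModelSpec(exposure=None, adjust=("x",)))

    def test_rank_deficiency_names_aliased_terms(self, rng):
        n = 200
        x = rng.normal(size=n)
        data = pd.DataFrame({"case": rng.integers(0, 2, n), "x": x,
                             "x_copy": x})
        with pytest.raises(RankDeficiencyError, match="x_copy"):
            fit_logistic(data, ModelSpec(exposure=None, adjust=("x", "x_copy")))

    def test_nonbinary_outcome_rejected(self, rng):
        data = pd.DataFrame({"case": rng.integers(0, 3, 100),
                             "x": rng.normal(size=100)})
        with pytest.raises(ValueError, match="binary"):
            fit_logistic(data, ModelSpec(exposure=None, adjust=("x",)))

    def test_json_round_trip(self, scored_cohort):
        from polygre.regression import FittedLogisticModel
        m = fit_logistic(scored_cohort, ModelSpec(exposure="exposure",
                                                  adjust=("age",),
                                                  prs="per10"))
        m2 = FittedLogisticModel.from_json(m.to_json())
        assert np.allclose(m2.params, m.params)
        assert np.allclose(m2.cov, m.cov)
        assert m2.prs_percentiles_per_unit == 10.0


def _noise_frame(rng, n, n_noise):
    data = {"case": rng.integers(0, 2, n), "age": rng.normal(70, 10, n)}
    for j in range(n_noise):
        data[f"noise{j}"] = rng.normal(size=n)
    return pd.DataFrame(data)


class TestStepwiseAIC:
    def test_zero_candidates_returns_forced_only(self, rng):
        data = _noise_frame(rng, 500, 0)
        res = stepwise_aic(data, forced=("age",), candidates=(),
                           base_spec=ModelSpec(exposure=None, adjust=()))
        assert res.spec.adjust == ("age",)

    def test_strong_candidate_selected_and_forced_kept(self, rng):
        n = 5000
        x = rng.normal(size=n)
        age = rng.normal(70, 10, n)
        p = 1 / (1 + np.exp(-(x - 0.0)))
        data = pd.DataFrame({"case": (rng.random(n) < p).astype(int),
                             "x": x, "age": age,
                             "noise": rng.normal(size=n)})
        res = stepwise_aic(data, forced=("age",), candidates=("x", "noise"),
                           base_spec=ModelSpec(exposure=None, adjust=()))
        assert "x" in res.spec.adjust
        assert "age" in res.spec.adjust  # forced survives every move

    def test_overlapping_forced_and_candidates_rejected(self, rng):
        data = _noise_frame(rng, 300, 1)
        with pytest.raises(ValueError, match="disjoint"):
            stepwise_aic(data, forced=("age",), candidates=("age",),
                         base_spec=ModelSpec(exposure=None, adjust=()))

    def test_deterministic_given_data(self, rng):
        data = _noise_frame(rng, 800, 3)
        kw = dict(forced=("age",), candidates=("noise0", "noise1", "noise2"),
                  base_spec=ModelSpec(exposure=None, adjust=()))
        assert stepwise_aic(data, **kw).spec == stepwise_aic(data, **kw).spec


class TestInteractionTest:
    def test_wald_and_lrt_agree_at_large_n(self, study_dataset):
        from polygre.prs import attach_prs
        data = attach_prs(study_dataset.cohort, study_dataset.dosages,
                          study_dataset.panel)
        spec = ModelSpec(exposure="exposure", adjust=("age", "sex"),
                         prs="percentile")
        lrt = interaction_test(data, spec, ("exposure", "prs"), "lrt")
        wald = interaction_test(data, spec, ("exposure", "prs"), "wald")
        assert lrt.df == wald.df == 3
        assert wald.p_value == pytest.approx(lrt.p_value, rel=0.10)

    def test_categorical_prs_df_12(self, scored_cohort):
        spec = ModelSpec(exposure="exposure", adjust=("age", "sex"),
                         prs="category")
        res = interaction_test(scored_cohort, spec, ("exposure", "prs"))
        assert res.df == 12
        assert 0 < res.p_value <= 1

    def test_empty_cross_cell_raises(self, scored_cohort):
        data = scored_cohort[~((scored_cohort["prs_category"] == "very_low")
                               & (scored_cohort["exposure"] == ">1/day"))]
        spec = ModelSpec(exposure="exposure", adjust=("age",), prs="category")
        with pytest.raises(EmptyCellError, match="very_low"):
            interaction_test(data, spec, ("exposure", "prs"))

    def test_unknown_method_rejected(self, scored_cohort):
        spec = ModelSpec(exposure="exposure", adjust=("age",), prs="percentile")
        with pytest.raises(ValueError):
            interaction_test(scored_cohort, spec, method="score")


class TestJointEffects:
    def test_reference_cell_unit_or_and_20_cells(self, scored_cohort):
        grid = joint_effects(scored_cohort, adjust=("age", "sex"))
        assert len(grid) == 20
        ref = grid.query("prs_category == 'medium' and exposure == '<=1/week'")
        assert ref["OR"].iloc[0] == 1.0
        rest = grid.drop(ref.index)
        assert ((rest["ci_low"] <= rest["OR"])
                & (rest["OR"] <= rest["ci_high"])).all()

    def test_empty_cell_error_names_cell(self, scored_cohort):
        data = scored_cohort[~((scored_cohort["prs_category"] == "very_high")
                               & (scored_cohort["exposure"] == ">1/day"))]
        with pytest.raises(EmptyCellError, match="very_high"):
            joint_effects(data, adjust=("age",))


class TestDescriptiveTable:
    def test_pearson_chi_square_oracle_2x2(self):
        # hand-computed: table (50,50 / 25,75) -> chi2 = 13.333, p = 2.6e-4
        data = pd.DataFrame({
            "case": [1] * 100 + [0] * 100,
            "flag": ["yes"] * 50 + ["no"] * 50 + ["yes"] * 25 + ["no"] * 75,
        })
        tab = descriptive_table(data, characteristics=["flag"])
        stat = tab["statistic"].dropna().iloc[0]
        p = tab["p_value"].dropna().iloc[0]
        assert stat == pytest.approx(13.3333, abs=1e-3)
        assert p == pytest.approx(stats.chi2.sf(13.3333, 1), rel=1e-3)

    def test_published_intake_distribution_is_significant(self):
        # case/control intake counts of a large CRC case-control study:
        # the difference is overwhelming (p < 0.0001)
        cases = [387, 2925, 1358, 222]
        controls = [469, 2444, 979, 124]
        levels = ["<=1/week", "multiple/week", "1/day", ">1/day"]
        rows = []
        for lvl, ca, co in zip(levels, cases, controls):
            rows += [{"case": 1, "intake": lvl}] * ca
            rows += [{"case": 0, "intake": lvl}] * co
        tab = descriptive_table(pd.DataFrame(rows), characteristics=["intake"])
        assert tab["p_value"].dropna().iloc[0] < 1e-4

    def test_identical_distributions_p_one(self):
        data = pd.DataFrame({"case": [1, 1, 0, 0] * 25,
                             "flag": ["a", "b"] * 50})
        tab = descriptive_table(data, characteristics=["flag"])
        assert tab["p_value"].dropna().iloc[0] == pytest.approx(1.0)

    def test_single_level_skipped_and_matching_flagged(self, scored_cohort):
        data = scored_cohort.copy()
        data["constant"] = "only"
        tab = descriptive_table(data, characteristics=["constant", "sex", "age"])
        notes = dict(zip(tab["characteristic"], tab["note"]))
        assert "skipped" in notes["constant"]
        assert "matching factor" in notes["sex"]
        assert "matching factor" in notes["age"]

    def test_missing_values_counted(self, scored_cohort):
        data = scored_cohort.copy()
        data.loc[data.index[:7], "smoking"] = np.nan
        tab = descriptive_table(data, characteristics=["smoking"])
        miss = tab[tab["level"] == "(missing)"]
        assert len(miss) == 1 and "excluded" in miss["note"].iloc[0]
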