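"""Mixed models, deviance tests, contrasts and orderings against oracles."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from camobreak.inference import (
    REFERENCE_TREATMENT,
    _design,
    _fit_binomial,
    _treatment_contrast,
    anova_crosscheck,
    arcsine_sqrt,
    analyse_experiment,
    contrasts_vs_reference,
    count_errors,
    fit_mixed,
    level_means,
    lrt,
    ordering_summary,
    tukey_pairwise,
)
from camobreak.scene import TREATMENTS


def balanced_cells(n_subjects, tau=0.3, effects=None, seed=0, response="mean_hat"):
    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    for i in range(n_subjects):
        u = rng.normal(0, tau)
        for s in ("small", "large"):
            for t in TREATMENTS:
                rows.append(
                    {
                        "subject_id": f"S{i:03d}",
                        "treatment": t,
                        "square_size": s,
                        response: 2.0 + effects.get(t, 0.0) + u + rng.normal(0, 0.4),
                    }
                )
    return pd.DataFrame(rows)


def balanced_errors(n_subjects, logits, n=40, seed=0, tau=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        v = rng.normal(0, tau)
        for s in ("small", "large"):
            for t in TREATMENTS:
                p = 1 / (1 + math.exp(-(logits[t] + v)))
                rows.append(
                    {
                        "subject_id": f"S{i:03d}",
                        "treatment": t,
                        "square_size": s,
                        "responded": n,
                        "errors": int(rng.binomial(n, p)),
                    }
                )
    return pd.DataFrame(rows)


class TestNormalMixed:
    def test_balanced_fixed_effects_equal_gls_ols(self):
        """On balanced one-intercept designs, ML mixed fixed effects
        coincide with ordinary least squares (GLS oracle)."""
        data = balanced_cells(12, tau=0.5, effects={"Border": 1.0}, seed=2)
        fit = fit_mixed(data, "normal_mean_rt", ("size", "treatment"))
        mat = _design(data, ("size", "treatment"))
        ols = sm.OLS(data["mean_hat"].to_numpy(), np.asarray(mat)).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params, rtol=1e-5)
        assert fit.subject_intercept_variance > 0.1

    def test_zero_generative_variance_degrades_to_ols(self):
        data = balanced_cells(12, tau=0.0, seed=3)
        fit = fit_mixed(data, "normal_mean_rt", ("treatment",))
        mat = _design(data, ("treatment",))
        ols = sm.OLS(data["mean_hat"].to_numpy(), np.asarray(mat)).fit()
        assert fit.subject_intercept_variance < 0.02
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params, rtol=1e-4, atol=1e-5)

    def test_single_subject_falls_back_with_warning(self):
        data = balanced_cells(1, tau=0.0, seed=4)
        with pytest.warns(UserWarning, match="single subject"):
            fit = fit_mixed(data, "normal_mean_rt", ("treatment",))
        assert fit.subject_intercept_variance == 0.0


class TestBinomialMixed:
    def test_single_subject_equals_plain_logistic(self):
        data = balanced_errors(1, {t: -2.0 for t in TREATMENTS}, seed=5)
        with pytest.warns(UserWarning, match="single subject"):
            fit = fit_mixed(data, "binomial_errors", ("treatment",))
        mat = _design(data, ("treatment",))
        glm = sm.GLM(
            np.column_stack([data["errors"], data["responded"] - data["errors"]]),
            np.asarray(mat),
            family=sm.families.Binomial(),
        ).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), glm.params, atol=1e-6)
        assert fit.log_likelihood == pytest.approx(glm.llf, abs=1e-6)

    def test_quadrature_stability_of_lrt(self):
        """LRT statistics stable to 3 significant figures across orders."""
        logits = {"Dark": -3.5, "Light": -3.5, "Stripe": -2.5, "Square": -2.5, "Border": -1.5}
        data = balanced_errors(8, logits, seed=6, tau=0.4)
        stats = []
        for q in (5, 9, 15):
            full = _fit_binomial(data, ("treatment",), quad_order=q)
            red = _fit_binomial(data, (), quad_order=q)
            stats.append(red.deviance - full.deviance)
        assert max(stats) - min(stats) < 5e-3 * abs(np.mean(stats))

    def test_recovers_planted_logit_effects(self):
        logits = {t: -3.0 for t in TREATMENTS} | {"Border": -1.5}
        data = balanced_errors(20, logits, n=80, seed=7, tau=0.3)
        fit = fit_mixed(data, "binomial_errors", ("treatment",))
        means = level_means(fit)
        assert means["Border"] == pytest.approx(-1.5, abs=0.4)
        assert means["Dark"] == pytest.approx(-3.0, abs=0.4)

    def test_zero_error_level_flagged_non_estimable(self):
        logits = {t: -2.0 for t in TREATMENTS}
        data = balanced_errors(6, logits, seed=8)
        data.loc[data["treatment"] == "Dark", "errors"] = 0
        fit = fit_mixed(data, "binomial_errors", ("treatment",))
        assert "Dark" in fit.non_estimable_levels
        tk = tukey_pairwise(fit)
        dark_rows = tk[tk["pair"].str.contains("Dark")]
        assert (~dark_rows["estimable"]).all()
        assert dark_rows["p_adjusted"].isna().all()
        # ordering still renders without silently dropping the level
        summary = ordering_summary(tk)
        assert any("Dark" in g for g in summary.groups)


class TestLrt:
    def test_identical_models_give_null_result(self, small_cells):
        fit = fit_mixed(small_cells, "normal_mean_rt", ("treatment",))
        res = lrt(fit, fit)
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_interaction_has_four_df(self, small_cells):
        full = fit_mixed(small_cells, "normal_mean_rt", ("size", "treatment", "size:treatment"))
        add = fit_mixed(small_cells, "normal_mean_rt", ("size", "treatment"))
        assert lrt(full, add).df == 4

    def test_chi2_additivity_over_nested_chain(self, small_cells):
        full = fit_mixed(small_cells, "normal_mean_rt", ("size", "treatment"))
        mid = fit_mixed(small_cells, "normal_mean_rt", ("size",))
        null = fit_mixed(small_cells, "normal_mean_rt", ())
        total = lrt(full, null).chi2
        assert total == pytest.approx(lrt(full, mid).chi2 + lrt(mid, null).chi2, abs=1e-4)

    def test_non_nested_rejected(self, small_cells):
        a = fit_mixed(small_cells, "normal_mean_rt", ("size",))
        b = fit_mixed(small_cells, "normal_mean_rt", ("treatment",))
        with pytest.raises(ValueError):
            lrt(a, b)


class TestContrasts:
    def test_reference_contrast_signs_with_border_slowest(self, small_cells):
        fit = fit_mixed(small_cells, "normal_mean_rt", ("size", "treatment"))
        table = contrasts_vs_reference(fit)
        assert len(table) == 4
        assert (table["estimate"] < 0).all()  # everything faster than Border
        assert (table["adjustment"] == "none_simple_vs_reference").all()

    def test_self_contrast_is_zero(self, small_cells):
        fit = fit_mixed(small_cells, "normal_mean_rt", ("size", "treatment"))
        L = _treatment_contrast(fit, "Dark", "Dark")
        assert float(L @ fit.params.to_numpy()) == 0.0

    def test_missing_reference_rejected(self, small_cells):
        sub = small_cells[small_cells["treatment"] != REFERENCE_TREATMENT]
        fit = fit_mixed(sub, "normal_mean_rt", ("treatment",))
        with pytest.raises(ValueError):
            contrasts_vs_reference(fit)


class TestTukey:
    def test_adjusted_never_below_raw(self, small_cells):
        fit = fit_mixed(small_cells, "normal_mean_rt", ("size", "treatment"))
        tk = tukey_pairwise(fit)
        assert len(tk) == 10
        ok = tk["estimable"]
        assert (tk.loc[ok, "p_adjusted"] >= tk.loc[ok, "p_raw"] - 1e-12).all()

    def test_two_level_family_needs_no_adjustment(self, small_cells):
        sub = small_cells[small_cells["treatment"].isin(["Dark", "Border"])]
        fit = fit_mixed(sub, "normal_mean_rt", ("treatment",))
        tk = tukey_pairwise(fit)
        assert len(tk) == 1
        assert tk["p_adjusted"].iloc[0] == pytest.approx(tk["p_raw"].iloc[0])

    def test_bonferroni_brackets_adjustment(self, small_cells):
        fit = fit_mixed(small_cells, "normal_mean_rt", ("size", "treatment"))
        tk = tukey_pairwise(fit)
        ok = tk["estimable"]
        upper = np.minimum(1.0, 10 * tk.loc[ok, "p_raw"])
        assert (tk.loc[ok, "p_adjusted"] <= upper + 0.005).all()
        assert (tk.loc[ok, "p_adjusted"] >= tk.loc[ok, "p_raw"] - 1e-12).all()

    def test_monte_carlo_seed_is_reproducible(self, small_cells):
        fit = fit_mixed(small_cells, "normal_mean_rt", ("size", "treatment"))
        a = tukey_pairwise(fit)["p_adjusted"]
        b = tukey_pairwise(fit)["p_adjusted"]
        pd.testing.assert_series_equal(a, b)


def _toy_contrast_table(means, sig_pairs):
    levels = list(means)
    rows = []
    import itertools

    for a, b in itertools.combinations(levels, 2):
        p = 0.001 if frozenset((a, b)) in sig_pairs else 0.5
        rows.append(
            {"pair": f"{a} - {b}", "estimate": means[a] - means[b], "se": 0.1,
             "t": 0.0, "p_raw": p, "p_adjusted": p, "adjustment": "tukey_single_step",
             "estimable": True}
        )
    df = pd.DataFrame(rows)
    df.attrs["level_means"] = means
    return df


class TestOrdering:
    def test_all_significant_gives_strict_chain(self):
        means = {"a": 1.0, "b": 2.0, "c": 3.0}
        import itertools

        table = _toy_contrast_table(
            means, {frozenset(p) for p in itertools.combinations(means, 2)}
        )
        s = ordering_summary(table)
        assert s.text == "c>b>a"
        assert not s.overlapping

    def test_grouped_rendering(self):
        means = {"Border": 3.5, "Square": 2.5, "Stripe": 2.45, "Dark": 1.5, "Light": 1.45}
        sig = {
            frozenset(p)
            for p in [
                ("Border", "Square"), ("Border", "Stripe"), ("Border", "Dark"),
                ("Border", "Light"), ("Square", "Dark"), ("Square", "Light"),
                ("Stripe", "Dark"), ("Stripe", "Light"),
            ]
        }
        s = ordering_summary(_toy_contrast_table(means, sig))
        assert s.text == "Border>(Square = Stripe)>(Dark = Light)"
        assert s.groups == (("Border",), ("Square", "Stripe"), ("Dark", "Light"))

    def test_non_transitive_pattern_flagged(self):
        # a ~ b, b ~ c, but a vs c significant: overlapping groups
        means = {"a": 3.0, "b": 2.0, "c": 1.0}
        s_table = _toy_contrast_table(means, {frozenset(("a", "c"))})
        with pytest.warns(UserWarning, match="overlap"):
            s = ordering_summary(s_table)
        assert s.overlapping
        assert ">=" in s.text


class TestAnovaCrosscheck:
    def test_arcsine_transform_endpoints(self):
        assert arcsine_sqrt(0.0) == 0.0
        assert arcsine_sqrt(1.0) == pytest.approx(math.pi / 2)
        with pytest.raises(ValueError):
            arcsine_sqrt(1.2)

    def test_concordant_with_lrt_on_planted_effect(self, small_cells, small_errors):
        merged = small_cells.merge(small_errors, on=["subject_id", "treatment", "square_size"])
        merged["err_prop"] = merged["errors"] / merged["responded"]
        table = anova_crosscheck(merged)
        f_treat = table[(table["response"] == "mean_rt") & (table["term"] == "treatment")]
        assert f_treat["p"].iloc[0] < 1e-6  # the planted effect is unmissable
        fit = fit_mixed(small_cells, "normal_mean_rt", ("size", "treatment"))
        red = fit_mixed(small_cells, "normal_mean_rt", ("size",))
        assert lrt(fit, red).p < 1e-6

    def test_unbalanced_rejected(self, small_cells):
        with pytest.raises(ValueError):
            anova_crosscheck(small_cells.iloc[:-3])


class TestErrorDenominator:
    def test_censored_trials_excluded_from_error_counts(self):
        trials = pd.DataFrame(
            {
                "subject_id": ["S1"] * 4,
                "treatment": ["Dark"] * 4,
                "square_size": ["small"] * 4,
                "censored": [False, False, True, False],
                "error": pd.array([True, False, None, False], dtype="boolean"),
                "practice": [False] * 4,
            }
        )
        out = count_errors(trials)
        assert out["responded"].iloc[0] == 3
        assert out["errors"].iloc[0] == 1
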