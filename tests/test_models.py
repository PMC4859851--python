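"""Formula layer: VIF, LR tests, backward selection, contrasts, predictions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from berryforage.models import (
    FormulaSpec,
    backward_select,
    fit_glmm,
    fit_hurdle,
    lr_test,
    pairwise_contrasts,
    pearson_cor,
    predict_population,
    vif_screen,
    welch_t,
)


class TestVifScreen:
    def test_orthogonal_predictors_all_one(self):
        n = 64
        t = np.arange(n)
        design = pd.DataFrame(
            {
                "a": np.cos(2 * np.pi * t / n),
                "b": np.sin(2 * np.pi * t / n),
                "c": np.cos(4 * np.pi * t / n),
            }
        )
        res = vif_screen(design)
        assert all(v == pytest.approx(1.0, abs=1e-8) for v in res.vif.values())
        assert res.dropped == ()

    def test_duplicated_predictor_infinite_and_dropped(self, rng):
        x = rng.normal(size=100)
        design = pd.DataFrame({"x1": x, "x2": x, "x3": rng.normal(size=100)})
        res = vif_screen(design)
        assert np.isinf(max(res.vif.values()))
        assert len(res.dropped) == 1 and res.dropped[0] in ("x1", "x2")

    def test_matches_direct_r2_recomputation(self, rng):
        n = 200
        z = rng.normal(size=n)
        design = pd.DataFrame(
            {
                "x1": z + 0.5 * rng.normal(size=n),
                "x2": z + 0.5 * rng.normal(size=n),
                "x3": rng.normal(size=n),
            }
        )
        res = vif_screen(design, cutoff=1e9)  # no drops, just the numbers
        for col in design:
            others = design.drop(columns=col)
            import statsmodels.api as sm

            r2 = sm.OLS(design[col], sm.add_constant(others)).fit().rsquared
            assert res.vif[col] == pytest.approx(1.0 / (1.0 - r2), rel=1e-6)

    def test_iterative_drop_until_under_cutoff(self, rng):
        n = 300
        z = rng.normal(size=n)
        design = pd.DataFrame(
            {
                "x1": z + 0.1 * rng.normal(size=n),
                "x2": z + 0.1 * rng.normal(size=n),
                "x3": rng.normal(size=n),
            }
        )
        res = vif_screen(design, cutoff=3.0)
        assert all(v <= 3.0 for v in res.final_vif.values())
        assert set(res.retained) | set(res.dropped) == {"x1", "x2", "x3"}


def _gaussian_frame(rng, n=300, beta_noise=0.0):
    df = pd.DataFrame(
        {
            "x": rng.normal(size=n),
            "w": rng.normal(size=n),
            "g": rng.choice(list("abcdefg"), n),
        }
    )
    df["y"] = 1.0 + 0.8 * df["x"] + beta_noise * df["w"] + rng.normal(0, 1.0, n)
    return df


class TestLrTest:
    def test_identical_models_give_zero_statistic(self, rng):
        df = _gaussian_frame(rng)
        spec = FormulaSpec("y", ("x",), group="g")
        full = fit_glmm(df, spec, "gaussian")
        refit = fit_glmm(df, spec, "gaussian")
        res = lr_test(full, refit)
        assert res.statistic == pytest.approx(0.0, abs=1e-5)
        assert res.df == 0 and res.p == 1.0

    def test_matches_closed_form_for_fixed_effect_gaussian(self, rng):
        # ML LR for nested linear models: chi2 = n * log(RSS_r / RSS_f)
        df = _gaussian_frame(rng, beta_noise=0.15)
        full_spec = FormulaSpec("y", ("x", "w"))
        red_spec = FormulaSpec("y", ("x",))
        full = fit_glmm(df, full_spec, "gaussian")
        red = fit_glmm(df, red_spec, "gaussian")
        res = lr_test(full, red)
        X = np.c_[np.ones(len(df)), df["x"], df["w"]]
        rss_f = np.sum((df["y"] - X @ np.linalg.lstsq(X, df["y"], rcond=None)[0]) ** 2)
        Xr = X[:, :2]
        rss_r = np.sum((df["y"] - Xr @ np.linalg.lstsq(Xr, df["y"], rcond=None)[0]) ** 2)
        expected = len(df) * np.log(rss_r / rss_f)
        assert res.statistic == pytest.approx(expected, abs=2e-3)
        assert res.df == 1
        assert res.p == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-4)

    def test_non_nested_specs_rejected(self, rng):
        df = _gaussian_frame(rng)
        full = fit_glmm(df, FormulaSpec("y", ("x",)), "gaussian")
        other = fit_glmm(df, FormulaSpec("y", ("x", "w")), "gaussian")
        with pytest.raises(ValueError):
            lr_test(full, other)  # "full" has fewer parameters

    def test_negative_statistic_clamped_with_warning(self, rng):
        df = _gaussian_frame(rng)
        good = fit_glmm(df, FormulaSpec("y", ("x", "w")), "gaussian")
        bad = fit_glmm(df, FormulaSpec("y", ("x",)), "gaussian")
        bad.loglik = good.loglik + 0.5  # simulate a non-converged 'full' fit
        with pytest.warns(UserWarning, match="clamped"):
            res = lr_test(good, bad)
        assert res.statistic == 0.0 and res.p == 1.0


class TestBackwardSelection:
    def test_strong_effects_are_kept(self, rng):
        df = _gaussian_frame(rng, beta_noise=1.5)
        spec = FormulaSpec("y", ("x", "w"), group="g")
        final, trace = backward_select(df, spec, "gaussian")
        assert set(final.spec.terms) == {"x", "w"}
        assert trace.dropped == []

    def test_pure_noise_covariate_is_dropped(self, rng):
        drops = 0
        for rep in range(10):
            df = _gaussian_frame(np.random.default_rng(rep), beta_noise=0.0)
            final, trace = backward_select(
                df, FormulaSpec("y", ("x", "w")), "gaussian"
            )
            drops += "w" in trace.dropped_terms()
        assert drops >= 8

    def test_marginality_protects_main_effects(self, rng):
        n = 400
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "f": rng.choice(["u", "v"], n),
            }
        )
        # pure interaction signal: the interaction stays, so its main effects
        # must stay too even though they are individually weak
        df["y"] = 2.0 * df["x"] * (df["f"] == "v") + rng.normal(0, 1.0, n)
        spec = FormulaSpec("y", ("x", "f", "x:f"))
        final, trace = backward_select(df, spec, "gaussian")
        assert "x:f" in final.spec.terms
        assert {"x", "f"} <= set(final.spec.terms)

    def test_can_reduce_to_intercept_only(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=200), "w": rng.normal(size=200)})
        df["y"] = rng.normal(size=200)
        final, trace = backward_select(df, FormulaSpec("y", ("x", "w")), "gaussian")
        # with pure noise both terms usually go; the model must remain valid
        assert final.converged
        assert len(final.spec.terms) + len(trace.dropped) == 2


class TestHurdle:
    def test_loglik_factorises(self, used_available_frame):
        spec = FormulaSpec("count_bilberry", ("plottype",), group="bear_id")
        h = fit_hurdle(used_available_frame, "count_bilberry", spec, spec)
        assert h.loglik == pytest.approx(h.occurrence.loglik + h.abundance.loglik)
        assert h.abundance.n_obs == int((used_available_frame["count_bilberry"] >= 1).sum())

    def test_all_positive_counts_flagged_degenerate(self, used_available_frame):
        df = used_available_frame.copy()
        df["count_bilberry"] = df["count_bilberry"].clip(lower=1)
        spec = FormulaSpec("count_bilberry", ("plottype",), group="bear_id")
        h = fit_hurdle(df, "count_bilberry", spec, spec)
        assert "degenerate_occurrence" in h.occurrence.flags

    def test_too_few_positive_rows_refused(self, used_available_frame):
        df = used_available_frame.copy()
        df.loc[df.index[25:], "count_bilberry"] = 0
        spec = FormulaSpec("count_bilberry", ("plottype",), group="bear_id")
        with pytest.raises(ValueError, match="positive-count rows"):
            fit_hurdle(df, "count_bilberry", spec, spec)

    def test_negative_counts_rejected(self, used_available_frame):
        df = used_available_frame.copy()
        df.loc[0, "count_bilberry"] = -1
        spec = FormulaSpec("count_bilberry", ("plottype",), group="bear_id")
        with pytest.raises(ValueError, match="non-negative"):
            fit_hurdle(df, "count_bilberry", spec, spec)


class TestContrasts:
    def _fit(self, rng, n=500):
        df = pd.DataFrame(
            {
                "f": rng.choice(["a", "b", "c"], n),
                "x": rng.normal(size=n),
            }
        )
        df["y"] = (
            0.5 * (df["f"] == "b")
            + 1.0 * (df["f"] == "c")
            + 0.3 * df["x"]
            + rng.normal(0, 1.0, n)
        )
        fit = fit_glmm(df, FormulaSpec("y", ("f", "x"), reference={"f": "a"}), "gaussian")
        return fit, df

    def test_single_contrast_adjustment_is_identity(self, rng):
        n = 400
        df = pd.DataFrame({"f": rng.choice(["a", "b"], n)})
        df["y"] = 0.4 * (df["f"] == "b") + rng.normal(size=n)
        fit = fit_glmm(df, FormulaSpec("y", ("f",), reference={"f": "a"}), "gaussian")
        (res,) = pairwise_contrasts(fit, "f", df, rng=np.random.default_rng(0))
        assert res.p_adj == pytest.approx(res.p_raw, abs=5e-3)

    def test_adjusted_p_never_below_raw_and_monotone_in_z(self, rng):
        fit, df = self._fit(rng)
        results = pairwise_contrasts(fit, "f", df, rng=np.random.default_rng(0))
        assert len(results) == 3
        for r in results:
            assert r.p_adj >= r.p_raw - 1e-12
        by_z = sorted(results, key=lambda r: abs(r.z), reverse=True)
        padj = [r.p_adj for r in by_z]
        assert padj == sorted(padj)

    def test_sidak_closed_form_for_independent_contrasts(self, rng):
        # one-factor balanced design: construct two orthogonal (independent)
        # contrasts by hand from fitted cell means
        n = 6000
        df = pd.DataFrame({"f": np.repeat(["a", "b", "c", "d"], n // 4)})
        df["y"] = rng.normal(size=n) + 0.08 * (df["f"] == "b")
        fit = fit_glmm(df, FormulaSpec("y", ("f",), reference={"f": "a"}), "gaussian")
        import patsy

        cells = pd.DataFrame({"f": ["a", "b", "c", "d"]})
        (X,) = patsy.build_design_matrices([fit.design_info], cells)
        X = np.asarray(X)
        C = np.array([X[1] - X[0], X[3] - X[2]])  # a-b and c-d: independent
        est = C @ fit.beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", C, fit.vcov, C))
        z = est / se
        p_raw = 2 * stats.norm.sf(np.abs(z))
        m = len(z)
        sidak = 1 - (1 - p_raw) ** m
        # Monte-Carlo max-|z| with the fitted (near-diagonal) correlation
        R = np.corrcoef((C @ fit.vcov @ C.T))
        draws = np.random.default_rng(1).standard_normal((100_000, m))
        p_adj = [np.mean(np.max(np.abs(draws), axis=1) >= abs(zi)) for zi in z]
        np.testing.assert_allclose(p_adj, sidak, atol=5e-3)

    def test_numeric_only_term_rejected(self, rng):
        fit, df = self._fit(rng)
        with pytest.raises(ValueError, match="categorical"):
            pairwise_contrasts(fit, "x", df)


class TestPredictPopulation:
    def test_logit_at_zero_eta_gives_half(self, rng):
        n = 600
        df = pd.DataFrame({"x": rng.normal(size=n)})
        df["y"] = rng.binomial(1, 0.5, n).astype(float)
        fit = fit_glmm(df, FormulaSpec("y", ("x",)), "binomial")
        # force eta = 0 exactly by zeroing the coefficients
        fit.beta = np.zeros_like(fit.beta)
        pred = predict_population(fit, pd.DataFrame({"x": [0.0]}))
        assert pred["fit"].iloc[0] == pytest.approx(0.5)
        # CI is symmetric on the link scale
        lo, hi = pred["lower"].iloc[0], pred["upper"].iloc[0]
        assert lo + hi == pytest.approx(1.0, abs=1e-10)

    def test_identity_link_is_linear_predictor(self, rng):
        df = _gaussian_frame(rng)
        fit = fit_glmm(df, FormulaSpec("y", ("x",)), "gaussian")
        nd = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        pred = predict_population(fit, nd)
        expected = fit.beta[0] + fit.beta[1] * nd["x"]
        np.testing.assert_allclose(pred["fit"], expected, rtol=1e-12)

    def test_ci_matches_parametric_bootstrap(self, rng):
        df = _gaussian_frame(rng)
        fit = fit_glmm(df, FormulaSpec("y", ("x",)), "gaussian")
        nd = pd.DataFrame({"x": [1.5]})
        pred = predict_population(fit, nd)
        draws = np.random.default_rng(2).multivariate_normal(
            fit.beta, fit.vcov, size=200_000
        )
        eta = draws[:, 0] + 1.5 * draws[:, 1]
        lo, hi = np.quantile(eta, [0.025, 0.975])
        assert pred["lower"].iloc[0] == pytest.approx(lo, abs=0.01)
        assert pred["upper"].iloc[0] == pytest.approx(hi, abs=0.01)

    def test_unseen_factor_level_raises(self, rng):
        n = 200
        df = pd.DataFrame({"f": rng.choice(["a", "b"], n)})
        df["y"] = rng.normal(size=n)
        fit = fit_glmm(df, FormulaSpec("y", ("f",), reference={"f": "a"}), "gaussian")
        with pytest.raises(ValueError, match="incompatible"):
            predict_population(fit, pd.DataFrame({"f": ["zzz"]}))


class TestSimpleTests:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = pearson_cor(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_pearson_matches_textbook_formula(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, p = pearson_cor(x, y)
        rr = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        t = rr * np.sqrt(48 / (1 - rr**2))
        assert r == pytest.approx(rr)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 48), rel=1e-10)

    def test_welch_matches_textbook_formula(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 2, 25)
        t, p = welch_t(x, y)
        vx, vy = x.var(ddof=1) / 40, y.var(ddof=1) / 25
        tt = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        dof = (vx + vy) ** 2 / (vx**2 / 39 + vy**2 / 24)
        assert t == pytest.approx(tt)
        assert p == pytest.approx(2 * stats.t.sf(abs(tt), dof), rel=1e-9)

    def test_equal_means_rarely_significant(self, rng):
        x, y = rng.normal(size=200), rng.normal(size=200)
        _, p = welch_t(x, y)
        assert p > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_cor([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            welch_t([2.0, 2.0], [2.0, 2.0])
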