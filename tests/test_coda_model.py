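"""Compositional regression and MANOVA, checked against statsmodels'
univariate sequential ANOVA (the p=1 reduction) and against structural and
invariance properties of Wilks' lambda."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.stats import ortho_group

from neocoda import coda_model, composition, validation
from neocoda.composition import IlrBasis, IlrCoordinates, make_ilr_basis


def make_dataset(rng, n=20, p=3, beta=None, noise=0.0):
    spo2 = rng.uniform(85, 100, n)
    delivery = rng.integers(0, 2, n).astype(float)
    X = np.column_stack([np.ones(n), spo2, delivery, spo2 * delivery])
    if beta is None:
        beta = rng.normal(size=(4, p))
    Y = X @ beta + noise * rng.normal(size=(n, p))
    basis = make_ilr_basis([f"g{i}" for i in range(p + 1)])
    coords = IlrCoordinates([f"s{i}" for i in range(n)], basis, Y)
    spec = coda_model.build_model(coords, spo2, delivery, interaction=True)
    return spec, beta, basis


class TestFit:
    def test_noise_free_fit_has_zero_residual_sscp(self, rng):
        spec, beta, _ = make_dataset(rng, noise=0.0)
        fit = coda_model.fit_multivariate_lm(spec)
        np.testing.assert_allclose(fit.coef, beta, atol=1e-8)
        np.testing.assert_allclose(fit.residual_sscp, 0.0, atol=1e-8)
        assert fit.error_df == 16

    def test_intercept_only_coefficients_are_column_means(self, rng):
        Y = rng.normal(size=(15, 4))
        basis = make_ilr_basis([f"g{i}" for i in range(5)])
        coords = IlrCoordinates([f"s{i}" for i in range(15)], basis, Y)
        spec = coda_model.ModelSpec(coords, np.ones((15, 1)),
                                    {"intercept": [0]}, ["intercept"])
        fit = coda_model.fit_multivariate_lm(spec)
        np.testing.assert_allclose(fit.coef[0], Y.mean(axis=0), atol=1e-12)

    def test_rank_deficient_design_names_columns(self, rng):
        n = 12
        spo2 = np.full(n, 90.0)  # constant SpO2 -> collinear with intercept
        delivery = rng.integers(0, 2, n).astype(float)
        Y = rng.normal(size=(n, 2))
        basis = make_ilr_basis(list("abc"))
        coords = IlrCoordinates([f"s{i}" for i in range(n)], basis, Y)
        with pytest.raises(ValueError, match="collinear.*spo2"):
            coda_model.build_model(coords, spo2, delivery)

    def test_parameter_recovery_within_3_se(self):
        rate = validation.slope_recovery(n_reps=10, seed=11, n=200)
        assert rate >= 0.9


class TestManova:
    def test_univariate_reduction_matches_statsmodels_sequential_anova(self, rng):
        """With a single response, the Wilks approximate F for each term is
        the sequential (Type I) ANOVA F."""
        n = 25
        spo2 = rng.uniform(85, 100, n)
        delivery = rng.integers(0, 2, n).astype(float)
        y = 0.3 * spo2 - 1.0 * delivery + rng.normal(size=n)
        basis = make_ilr_basis(["a", "b"])
        coords = IlrCoordinates([f"s{i}" for i in range(n)], basis, y[:, None])
        spec = coda_model.build_model(coords, spo2, delivery, interaction=True)
        res = coda_model.manova(coda_model.fit_multivariate_lm(spec))

        frame = pd.DataFrame({"y": y, "spo2": spo2, "delivery": delivery})
        ols = smf.ols("y ~ spo2 + delivery + spo2:delivery", frame).fit()
        table = sm.stats.anova_lm(ols, typ=1)
        for term, sm_term in [("spo2", "spo2"), ("delivery", "delivery"),
                              ("spo2:delivery", "spo2:delivery")]:
            assert res[term].approx_f == pytest.approx(table.loc[sm_term, "F"],
                                                       rel=1e-9)
            assert res[term].p_value == pytest.approx(table.loc[sm_term, "PR(>F)"],
                                                      rel=1e-9)

    def test_cohort_shape_df_structure(self):
        """9-part composition, 13 patients, intercept+SpO2+delivery+interaction
        gives the approximate F its (8, 2) degrees of freedom."""
        fit, *_ = validation.model_dataset(seed=0)
        entry = coda_model.manova(fit, "spo2")
        assert (entry.df_num, entry.df_den) == (8, 2)
        assert fit.error_df == 9

    def test_insufficient_error_df_rejected(self, rng):
        # p = 9 responses but only 9 error df: df_den = 1... n=12 -> error df 8 < p
        Y = rng.normal(size=(12, 9))
        basis = make_ilr_basis([f"g{i}" for i in range(10)])
        coords = IlrCoordinates([f"s{i}" for i in range(12)], basis, Y)
        spec = coda_model.build_model(coords, rng.uniform(85, 100, 12),
                                      rng.integers(0, 2, 12).astype(float))
        fit = coda_model.fit_multivariate_lm(spec)
        with pytest.raises(ValueError, match="insufficient error df"):
            coda_model.manova(fit)

    def test_basis_invariance(self, rng):
        """Wilks lambda, F and p are identical under any orthonormal ilr
        basis; only coordinates change."""
        fit, basis, core, _ = validation.model_dataset(seed=4)
        res1 = coda_model.manova(fit)
        D = core.n_parts
        # rotate the default basis by a random orthogonal map of R^(D-1)
        Q = ortho_group.rvs(D - 1, random_state=7)
        basis2 = IlrBasis(core.parts, Q @ basis.contrasts)
        coords2 = composition.ilr(core, basis2)
        spec2 = coda_model.build_model(
            coords2, fit.spec.spo2,
            fit.spec.design[:, fit.spec.term_map["delivery"][0]])
        res2 = coda_model.manova(coda_model.fit_multivariate_lm(spec2))
        for term in res1:
            assert res1[term].statistic == pytest.approx(res2[term].statistic,
                                                         abs=1e-9)
            assert res1[term].p_value == pytest.approx(res2[term].p_value,
                                                       abs=1e-9)

    def test_null_pvalues_roughly_uniform(self):
        pv = validation.null_manova_pvalues(n_sims=60, seed=30)
        assert stats.kstest(pv, "uniform").pvalue > 0.01

    def test_permutation_oracle_agreement(self):
        fit, *_ = validation.model_dataset(seed=2, n_chd=50)
        ana = coda_model.manova(fit, "spo2").p_value
        perm = validation.manova_permutation_pvalue(fit, n_perm=500, seed=8)
        assert ana == pytest.approx(perm, abs=0.06)


class TestPrediction:
    def test_noise_free_training_point_recovered(self, rng):
        spec, beta, basis = make_dataset(rng, n=15, p=3, noise=0.0)
        fit = coda_model.fit_multivariate_lm(spec)
        i = 4
        level = "cesarean" if spec.design[i, 2] == 1 else "vaginal"
        curve = coda_model.predict_composition(fit, [spec.spo2[i]], level, basis)
        expected = composition.ilr_inverse(
            spec.response.coords[[i]], basis).values
        np.testing.assert_allclose(curve.composition.values, expected, atol=1e-8)

    def test_zero_slopes_give_constant_curve(self):
        basis = make_ilr_basis(list("abcd"))
        intercept = np.array([0.3, -0.2, 0.1])
        coords = IlrCoordinates(["s1", "s2", "s3", "s4", "s5", "s6"], basis,
                                np.tile(intercept, (6, 1)))
        spec = coda_model.build_model(
            coords, [86, 90, 94, 88, 92, 96], ["vaginal", "cesarean"] * 3)
        fit = coda_model.fit_multivariate_lm(spec)
        curve = coda_model.predict_composition(fit, np.linspace(85, 100, 7),
                                               "vaginal", basis)
        expected = composition.ilr_inverse(intercept[None], basis).values[0]
        for row in curve.composition.values:
            np.testing.assert_allclose(row, expected, atol=1e-8)

    def test_monotone_two_part_model(self):
        basis = make_ilr_basis(["a", "b"])
        rng = np.random.default_rng(0)
        spo2 = np.linspace(85, 100, 12)
        y = (0.2 * spo2)[:, None]  # positive slope on the single coordinate
        coords = IlrCoordinates([f"s{i}" for i in range(12)], basis, y)
        spec = coda_model.build_model(coords, spo2,
                                      rng.integers(0, 2, 12).astype(float))
        fit = coda_model.fit_multivariate_lm(spec)
        curve = coda_model.predict_composition(fit, np.linspace(85, 100, 20),
                                               "vaginal", basis)
        first = curve.composition.values[:, 0]
        assert np.all(np.diff(first) > 0)

    def test_rows_on_simplex_and_continuous(self):
        fit, basis, *_ = validation.model_dataset(seed=6)
        grid = np.arange(85, 100.01, 0.5)
        curve = coda_model.predict_composition(fit, grid, "cesarean", basis)
        vals = curve.composition.values
        np.testing.assert_allclose(vals.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(vals > 0)
        assert np.max(np.abs(np.diff(vals, axis=0))) < 0.2  # no jumps on a 0.5% grid

    def test_extrapolation_warns_but_proceeds(self, caplog):
        fit, basis, *_ = validation.model_dataset(seed=6)
        with caplog.at_level("WARNING"):
            curve = coda_model.predict_composition(fit, [60.0], "vaginal", basis)
        assert "outside observed SpO2 range" in caplog.text
        assert curve.composition.values.shape[0] == 1


class TestAdjustedR2:
    def test_collinear_data(self):
        x = np.arange(10.0)
        assert coda_model.adjusted_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_independent_data_near_zero(self, rng):
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        assert abs(coda_model.adjusted_r2(x, y)) < 0.05

    def test_matches_hand_formula(self, rng):
        """Independent second implementation from the definition."""
        x = rng.uniform(80, 100, 13)
        y = 0.65 * x + rng.normal(0, 0.5, 13)
        xc, yc = x - x.mean(), y - y.mean()
        beta = (xc @ yc) / (xc @ xc)
        resid = yc - beta * xc
        r2 = 1 - (resid @ resid) / (yc @ yc)
        expected = 1 - (1 - r2) * (13 - 1) / (13 - 2)
        assert coda_model.adjusted_r2(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            coda_model.adjusted_r2([1, 1, 1], [1, 2, 3])
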