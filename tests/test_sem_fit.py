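"""Covariance-structure ML fitting: closed forms, identities, invariances."""

import numpy as np
import pandas as pd
import pytest

from xylemsem.fit import (
    HeywoodWarning,
    SemFitError,
    fit_indices,
    fit_ml,
    implied_covariance,
    standardized_solution,
)
from xylemsem.model import (
    build_ram,
    independence_model,
    parse_model_spec,
    saturated_model,
)
from xylemsem.simulate import default_population, population_covariance
from xylemsem.xylem_models import full_model


def _spd(seed, p=4, n=60):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    return np.cov(x, rowvar=False, ddof=1)


class TestImpliedCovariance:
    def test_no_paths_gives_diagonal(self):
        spec = parse_model_spec("var(x) = free\nvar(y) = free")
        ram = build_ram(spec)
        sigma = implied_covariance(ram, np.array([2.0, 3.0]))
        np.testing.assert_allclose(sigma, np.diag([2.0, 3.0]))

    def test_single_path_hand_algebra(self):
        # x -> y with beta=0.5, var(x)=2, residual psi=1.5:
        # var(y) = beta^2*2 + psi = 2, cov = beta*2 = 1
        spec = parse_model_spec("y <- x")
        ram = build_ram(spec)
        theta = np.zeros(3)
        for k, (kind, i, j) in enumerate(spec.free_parameters()):
            if kind == "path":
                theta[k] = 0.5
            elif i == "x":
                theta[k] = 2.0
            else:
                theta[k] = 1.5
        sigma = implied_covariance(ram, theta)
        order = list(spec.observed)
        df = pd.DataFrame(sigma, index=order, columns=order)
        assert df.loc["y", "y"] == pytest.approx(2.0)
        assert df.loc["x", "y"] == pytest.approx(1.0)
        assert df.loc["x", "x"] == pytest.approx(2.0)

    def test_feedback_loop_matches_series_limit(self):
        # a -> b (b1), b -> a (b2), |b1 b2| < 1: the RAM inverse equals
        # the geometric-series limit of iterated substitution
        b1, b2 = 0.4, 0.6
        va, vb = 1.3, 0.8
        spec = parse_model_spec("b <- a\na <- b")
        ram = build_ram(spec)
        theta = np.zeros(4)
        for k, (kind, i, j) in enumerate(spec.free_parameters()):
            if kind == "path" and (i, j) == ("a", "b"):
                theta[k] = b1
            elif kind == "path":
                theta[k] = b2
            elif i == "b":
                theta[k] = vb
            else:
                theta[k] = va
        sigma = implied_covariance(ram, theta)

        # brute-force series: B = sum_k A^k
        m = ram.dim
        a_mat, s_mat = ram.fill(theta)
        b_sum = np.zeros((m, m))
        term = np.eye(m)
        for _ in range(2000):
            b_sum += term
            term = term @ a_mat
        series = (b_sum @ s_mat @ b_sum.T)[:m, :m]
        np.testing.assert_allclose(sigma, series[:2, :2], atol=1e-10)

    def test_unit_gain_cycle_diagnosed(self):
        spec = parse_model_spec("b <- 1.0*a\na <- 1.0*b")
        ram = build_ram(spec)
        with pytest.raises(SemFitError, match="cycle"):
            implied_covariance(ram, np.array([1.0, 1.0]))


class TestClosedForms:
    def test_saturated_model_reproduces_sample(self):
        s = _spd(1, p=3)
        fit = fit_ml(saturated_model(["a", "b", "c"]), s, 50)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.df == 0
        np.testing.assert_allclose(fit.implied, s, atol=1e-8)

    def test_independence_chi2_closed_form(self):
        # two variables, r = 0.5, n = 30, c = n-1: chi2 = -29 ln(1 - 0.25)
        s = np.array([[1.0, 0.5], [0.5, 1.0]])
        fit = fit_ml(independence_model(["x", "y"]), s, 30)
        assert fit.chi2 == pytest.approx(-29 * np.log(0.75), abs=1e-6)
        assert fit.df == 1

    def test_just_identified_regression_slope(self):
        s = _spd(2, p=2)
        spec = parse_model_spec("y <- x")
        # observed order is (y, x): y touched first
        df = pd.DataFrame(s, index=["y", "x"], columns=["y", "x"])
        fit = fit_ml(spec, df, 40)
        beta = fit.theta[0]
        assert fit.spec.free_parameters()[0][0] == "path"
        assert beta == pytest.approx(s[0, 1] / s[1, 1], abs=1e-8)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)

    def test_chi2_multiplier_switch(self):
        s = np.array([[1.0, 0.5], [0.5, 1.0]])
        f1 = fit_ml(independence_model(["x", "y"]), s, 30, chi2_multiplier="n")
        assert f1.chi2 == pytest.approx(-30 * np.log(0.75), abs=1e-6)


class TestFitProperties:
    def test_information_identities_hold(self, species_table):
        s = species_table.covariance()
        fit = fit_ml(full_model(), s, 29)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k, abs=1e-8)
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + fit.k * np.log(fit.n), abs=1e-8)
        assert fit.chi2 == pytest.approx(
            2 * (fit.loglik_saturated - fit.loglik), abs=1e-8)

    def test_chi2_invariant_to_per_variable_rescaling(self, species_table):
        s = species_table.covariance().to_numpy()
        spec = full_model()
        fit = fit_ml(spec, species_table.covariance(), 29)
        rng = np.random.default_rng(3)
        d = np.diag(rng.uniform(0.2, 5.0, size=9))
        cols = species_table.covariance().columns
        s2 = pd.DataFrame(d @ s @ d, index=cols, columns=cols)
        fit2 = fit_ml(spec, s2, 29)
        assert fit2.chi2 == pytest.approx(fit.chi2, rel=1e-6)

    def test_non_spd_sample_rejected(self):
        s = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(SemFitError, match="positive definite"):
            fit_ml(independence_model(["x", "y"]), s, 20)

    def test_heywood_detection_and_zero_fix(self):
        # one-factor model generated with a near-zero error variance on the
        # first indicator; a finite sample can push its estimate negative
        text = "L ~ a + b + c"
        spec = parse_model_spec(text)
        rng = np.random.default_rng(11)
        lam = np.array([1.0, 0.8, 0.7])
        found = False
        for seed in range(40):
            rng = np.random.default_rng(seed)
            f = rng.normal(size=200)
            errs = rng.normal(size=(200, 3)) * np.sqrt([1e-4, 0.5, 0.5])
            x = np.outer(f, lam) + errs
            s = pd.DataFrame(np.cov(x, rowvar=False, ddof=1),
                             index=["a", "b", "c"], columns=["a", "b", "c"])
            import warnings as w

            with w.catch_warnings(record=True) as rec:
                w.simplefilter("always")
                fit = fit_ml(spec, s, 200)
            if any(issubclass(r.category, HeywoodWarning) for r in rec):
                found = True
                with w.catch_warnings():
                    w.simplefilter("ignore")
                    fixed = fit_ml(spec, s, 200, fix_heywood=True)
                assert fixed.spec.variances["a"] == 0.0
                assert not fixed.heywood
                break
        assert found, "no Heywood case arose across seeds"


class TestStandardized:
    def test_simple_path_standardization(self):
        # x -> y with beta=0.5 and equal implied variances -> std 0.5
        s = np.array([[2.0, 1.0], [1.0, 2.0]])
        spec = parse_model_spec("y <- x")
        df = pd.DataFrame(s, index=["y", "x"], columns=["y", "x"])
        fit = fit_ml(spec, df, 100)
        tab = standardized_solution(fit)
        path = tab[tab["kind"] == "path"].iloc[0]
        assert path["std_estimate"] == pytest.approx(0.5, abs=1e-6)
        # R^2 of y = std_beta^2
        assert tab.attrs["r_squared"]["y"] == pytest.approx(0.25, abs=1e-6)

    def test_standardized_invariant_to_latent_scale_indicator(self):
        # swapping which loading carries the latent's scale must not
        # change the standardized solution
        cfg = default_population(seed=5)
        sigma = population_covariance(cfg)
        n = 500
        t1 = "CT ~ fiber + vessel + parenchyma\nstarch <- CT\nvar(fiber) = 0"
        t2 = "CT ~ vessel + fiber + parenchyma\nstarch <- CT\nvar(fiber) = 0"
        sub = sigma.loc[["fiber", "vessel", "parenchyma", "starch"],
                        ["fiber", "vessel", "parenchyma", "starch"]]
        out = {}
        for key, text in (("a", t1), ("b", t2)):
            fit = fit_ml(parse_model_spec(text), sub, n)
            tab = standardized_solution(fit)
            path = tab[(tab["kind"] == "path")].iloc[0]
            out[key] = abs(path["std_estimate"])
        assert out["a"] == pytest.approx(out["b"], abs=1e-6)


class TestFitIndices:
    def test_cfi_is_one_when_chi2_below_df(self):
        cfg = default_population(seed=9)
        sigma = population_covariance(cfg)
        fit = fit_ml(full_model(), sigma, 29)  # population covariance: F=0
        idx = fit_indices(fit)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)
        assert idx.cfi == 1.0

    def test_tli_na_when_df_zero(self):
        s = _spd(4, p=3)
        fit = fit_ml(saturated_model(["a", "b", "c"]), s, 50)
        idx = fit_indices(fit)
        assert idx.tli is None

    def test_aicc_guard(self):
        s = _spd(5, p=3)
        fit = fit_ml(saturated_model(["a", "b", "c"]), s, 7)  # n = K+1
        with pytest.raises(SemFitError, match="AICc"):
            _ = fit.aicc
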