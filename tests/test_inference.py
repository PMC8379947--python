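"""Bollen-Stine bootstrap, pruning, comparison, reversal, variants."""

import numpy as np
import pandas as pd
import pytest

from xylemsem.fit import SemFitError, fit_ml
from xylemsem.inference import (
    bollen_stine_pvalue,
    bollen_stine_transform,
    compare_models,
    drop_variable_variant,
    prune_paths,
    reverse_path_test,
)
from xylemsem.model import parse_model_spec
from xylemsem.simulate import SimConfig, population_covariance
from xylemsem.xylem_models import best_model, full_model


class TestBollenStineTransform:
    def test_identity_when_sigma_equals_sample(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 3))
        s = np.cov(x, rowvar=False, ddof=1)
        z = bollen_stine_transform(x, s)
        np.testing.assert_allclose(z, x - x.mean(axis=0), atol=1e-10)

    def test_transform_reproduces_target_exactly(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 3))
        a = rng.normal(size=(3, 3))
        target = a @ a.T + 3 * np.eye(3)
        z = bollen_stine_transform(x, target)
        np.testing.assert_allclose(np.cov(z, rowvar=False, ddof=1), target,
                                   atol=1e-10)
        assert z.shape == x.shape

    def test_rank_deficient_sample_rejected(self):
        x = np.ones((5, 3))  # zero variance
        with pytest.raises(SemFitError, match="positive definite"):
            bollen_stine_transform(x, np.eye(3))


class TestBollenStinePvalue:
    def test_seed_determinism_and_domain(self, species_table):
        data = species_table.traits
        model = full_model()
        r1 = bollen_stine_pvalue(model, data, b=30, seed=4)
        r2 = bollen_stine_pvalue(model, data, b=30, seed=4)
        assert r1.p_value == r2.p_value
        assert 0.0 <= r1.p_value <= 1.0
        # observed chi2 must come from the model-ordered covariance
        ref = fit_ml(model, species_table.covariance(), len(data))
        assert r1.chi2_observed == pytest.approx(ref.chi2, rel=1e-10)
        with pytest.raises(ValueError):
            bollen_stine_pvalue(model, data, b=0, seed=4)
        with pytest.raises(ValueError):
            bollen_stine_pvalue(model, data, b=10, seed=None)


    def test_p_values_uniform_under_correct_specification(self):
        """Under a correctly specified model the bootstrap p-value should
        be uniform on [0,1] across datasets.  Checked on a small 3-variable
        chain at n = 29 (100 simulations, B = 99) with a KS test."""
        from scipy import stats

        spec = parse_model_spec("y <- x\nz <- y")
        rng = np.random.default_rng(123)
        pvals = []
        for sim in range(100):
            x = rng.normal(size=29)
            y = 0.6 * x + rng.normal(size=29) * 0.8
            z = 0.6 * y + rng.normal(size=29) * 0.8
            data = np.c_[y, x, z]  # model's observed order
            res = bollen_stine_pvalue(spec, data, b=99, seed=1000 + sim)
            pvals.append(res.p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestPruning:
    def test_no_op_when_all_paths_significant(self):
        # strong 2-path chain at large n: nothing to prune
        spec = parse_model_spec("y <- x\nz <- y")
        rng = np.random.default_rng(7)
        x = rng.normal(size=5000)
        y = 0.8 * x + rng.normal(size=5000) * 0.5
        z = 0.8 * y + rng.normal(size=5000) * 0.5
        s = pd.DataFrame(np.cov(np.c_[y, x, z], rowvar=False, ddof=1),
                         index=["y", "x", "z"], columns=["y", "x", "z"])
        trace = prune_paths(spec, s, 5000)
        assert trace.removed_paths == []
        assert trace.final_model.k == spec.k

    def test_true_zero_path_removed(self):
        # y <- x (strong) and y <- w (true zero), x and w independent
        spec = parse_model_spec("y <- x + w\ncov(x, w) = free")
        rng = np.random.default_rng(8)
        n = 500
        x = rng.normal(size=n)
        w = rng.normal(size=n)
        y = 0.7 * x + rng.normal(size=n) * 0.7
        s = pd.DataFrame(np.cov(np.c_[y, x, w], rowvar=False, ddof=1),
                         index=["y", "x", "w"], columns=["y", "x", "w"])
        trace = prune_paths(spec, s, n)
        assert ("w", "y") in trace.removed_paths
        assert ("x", "y") not in trace.removed_paths

    def test_k_never_increases_and_subset(self, species_table):
        spec = full_model()
        trace = prune_paths(spec, species_table.covariance(), 29)
        assert trace.final_model.k <= spec.k
        final_paths = {(s, d) for s, d, _ in trace.final_model.paths}
        initial_paths = {(s, d) for s, d, _ in spec.paths}
        assert final_paths <= initial_paths
        ks = [spec.k]
        for step in trace.steps:
            if step["kept_removed"]:
                ks.append(ks[-1] - 1)
        assert trace.final_model.k == ks[-1]


class TestComparison:
    def test_identical_models_have_zero_deltas(self, species_table):
        s = species_table.covariance()
        f1 = fit_ml(best_model(), s, 29)
        f2 = fit_ml(best_model(), s, 29)
        tab = compare_models([f1, f2])
        assert (tab["dAICc"] == 0).all()
        assert (tab["dBIC"] == 0).all()

    def test_mismatched_data_rejected(self, species_table):
        s = species_table.covariance()
        f1 = fit_ml(best_model(), s, 29)
        f2 = fit_ml(best_model(), s * 2.0, 29)
        with pytest.raises(SemFitError, match="different data"):
            compare_models([f1, f2])

    def test_small_sample_aicc_flagged(self):
        # K = 6 free parameters at n = 8 puts AICc at the n - K - 1 = 1 edge
        rng = np.random.default_rng(2)
        x = rng.normal(size=(8, 3))
        s = np.cov(x, rowvar=False, ddof=1)
        spec = parse_model_spec("b <- a\nc <- b\ncov(a, c) = free")
        cols = list(spec.observed)
        f = fit_ml(spec, pd.DataFrame(s, index=cols, columns=cols), 8)
        tab = compare_models([f])
        assert "AICc_note" in tab.columns

    def test_table_columns_follow_reporting_layout(self, species_table):
        f = fit_ml(best_model(), species_table.covariance(), 29)
        tab = compare_models([f], labels=["best"])
        for col in ("K", "AICc", "AIC", "BIC", "CFI", "TLI", "LL", "df",
                    "chi2", "P"):
            assert col in tab.columns


class TestReversal:
    def test_reversal_keeps_k_df(self, species_table):
        s = species_table.covariance()
        fit = fit_ml(best_model(), s, 29)
        rev = reverse_path_test(best_model(), ("p75", "ks"), s, 29)
        assert rev.k == fit.k and rev.df == fit.df

    def test_just_identified_two_variable_model_saturated_either_way(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(40, 2))
        s = np.cov(x, rowvar=False, ddof=1)
        spec = parse_model_spec("y <- x")
        sdf = pd.DataFrame(s, index=["y", "x"], columns=["y", "x"])
        f = fit_ml(spec, sdf, 40)
        r = reverse_path_test(spec, ("x", "y"), sdf, 40)
        assert f.chi2 == pytest.approx(0.0, abs=1e-8)
        assert r.chi2 == pytest.approx(0.0, abs=1e-8)

    def test_reversal_worsens_fit_under_known_direction(self):
        # instrument-like upstream covariate: z -> x -> y; reversing
        # x -> y misses the z-y covariance channel
        rng = np.random.default_rng(6)
        n = 2000
        z = rng.normal(size=n)
        x = 0.8 * z + rng.normal(size=n) * 0.6
        y = 0.7 * x + rng.normal(size=n) * 0.6
        spec = parse_model_spec("x <- z\ny <- x")
        s = pd.DataFrame(np.cov(np.c_[x, z, y], rowvar=False, ddof=1),
                         index=["x", "z", "y"], columns=["x", "z", "y"])
        f = fit_ml(spec, s, n)
        r = reverse_path_test(spec, ("x", "y"), s, n)
        assert r.chi2 > f.chi2 + 10


class TestDropVariable:
    def test_drop_central_hub_variable(self):
        spec = drop_variable_variant(full_model(), "pmin")
        assert spec.n_observed == 8
        assert all("pmin" not in (s, d) for s, d, _ in spec.paths)

    def test_dropped_variant_fits(self, species_table):
        spec = drop_variable_variant(full_model(), "pmin")
        cols = [c for c in species_table.traits.columns if c != "pmin"]
        s = species_table.covariance().loc[cols, cols]
        fit = fit_ml(spec, s, 29)
        assert fit.converged
        assert fit.df == spec.df
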