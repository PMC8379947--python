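"""Correlation network, strength centrality, PCA, variance partitioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xylemsem.descriptive import (
    correlation_matrix,
    network_strength,
    pca_summary,
    variance_components,
)
from xylemsem.simulate import simulate_nested


class TestCorrelations:
    def test_perfect_linearity_top_tier(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": 2 * x})
        corr = correlation_matrix(df)
        assert corr.r.loc["x", "y"] == pytest.approx(1.0)
        assert corr.tiers.loc["x", "y"] == "***"

    def test_diagonal_and_symmetry(self, species_table):
        corr = correlation_matrix(species_table)
        r = corr.r.to_numpy()
        np.testing.assert_allclose(np.diag(r), 1.0)
        np.testing.assert_allclose(r, r.T)
        assert np.all(np.abs(r) <= 1.0)

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_matrix(df)

    def test_through_origin_mode_for_contrasts(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(30, 2))
        corr = correlation_matrix(pd.DataFrame(z, columns=["a", "b"]),
                                  through_origin=True)
        cross = z.T @ z
        expected = cross[0, 1] / np.sqrt(cross[0, 0] * cross[1, 1])
        assert corr.r.loc["a", "b"] == pytest.approx(expected)


class TestStrength:
    def test_enumerated_example(self):
        r = pd.DataFrame(
            [[1.0, 0.5, 0.3], [0.5, 1.0, -0.2], [0.3, -0.2, 1.0]],
            index=list("abc"), columns=list("abc"))
        from xylemsem.descriptive import CorrelationMatrix

        cm = CorrelationMatrix(r=r, p=r * 0, tiers=r * 0, n=10)
        s = network_strength(cm)
        assert s["a"] == pytest.approx(0.8)
        assert s["b"] == pytest.approx(0.7)
        assert s["c"] == pytest.approx(0.5)

    def test_zero_correlations_zero_strength(self):
        from xylemsem.descriptive import CorrelationMatrix

        r = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        cm = CorrelationMatrix(r=r, p=r * 0, tiers=r * 0, n=10)
        assert (network_strength(cm) == 0).all()

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(perm_seed=st.integers(0, 1000))
    def test_invariant_to_trait_ordering(self, perm_seed, species_table):
        corr = correlation_matrix(species_table)
        s1 = network_strength(corr)
        rng = np.random.default_rng(perm_seed)
        cols = list(corr.r.columns)
        perm = list(rng.permutation(cols))
        from xylemsem.descriptive import CorrelationMatrix

        cm = CorrelationMatrix(
            r=corr.r.loc[perm, perm], p=corr.p.loc[perm, perm],
            tiers=corr.tiers.loc[perm, perm], n=corr.n)
        s2 = network_strength(cm)
        for c in cols:
            assert s1[c] == pytest.approx(s2[c])


class TestPca:
    def test_two_variable_fraction_closed_form(self):
        # standardized 2-variable PCA: eigenvalues 1 +/- r
        rng = np.random.default_rng(1)
        x = rng.normal(size=400)
        y = 0.6 * x + rng.normal(size=400) * 0.8
        df = pd.DataFrame({"x": x, "y": y})
        r = np.corrcoef(x, y)[0, 1]
        out = pca_summary(df)
        assert out["variance_fraction"]["PC1"] == pytest.approx(
            (1 + abs(r)) / 2, abs=1e-10)

    def test_fractions_sum_to_one_loadings_orthonormal(self, species_table):
        out = pca_summary(species_table)
        assert out["variance_fraction"].sum() == pytest.approx(1.0)
        l = out["loadings"].to_numpy()
        np.testing.assert_allclose(l.T @ l, np.eye(l.shape[1]), atol=1e-10)

    def test_sign_convention(self, species_table):
        out = pca_summary(species_table)
        for col in out["loadings"]:
            v = out["loadings"][col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0


class TestVarianceComponents:
    def test_zero_within_species_spread(self):
        df = simulate_nested(3, 4, 5, 1.0, 2.0, 0.0, seed=1)
        vc = variance_components(df, method="anova")[0]
        assert vc.intraspecific == pytest.approx(0.0, abs=1e-20)

    def test_equal_site_means_zero_site_component(self):
        # species differ within site but site means are identical
        rows = []
        for s in range(3):
            for k, eff in enumerate([-1.0, 0.0, 1.0]):
                for r in range(4):
                    rows.append({"site": f"s{s}", "species": f"sp{s}_{k}",
                                 "y": eff})
        df = pd.DataFrame(rows)
        vc = variance_components(df, method="anova")[0]
        assert vc.site == pytest.approx(0.0, abs=1e-12)
        assert vc.species_within_site > 0

    def test_balanced_recovery_mean_over_seeds(self):
        # balanced design with known components; mean estimate within 10%
        truth = {"site": 1.0, "species_within_site": 2.0, "intraspecific": 0.5}
        acc = {k: 0.0 for k in truth}
        reps = 200
        for seed in range(reps):
            df = simulate_nested(10, 10, 6, 1.0, 2.0, 0.5, seed=seed)
            vc = variance_components(df, method="anova")[0]
            acc["site"] += vc.site
            acc["species_within_site"] += vc.species_within_site
            acc["intraspecific"] += vc.intraspecific
        for k, v in truth.items():
            assert acc[k] / reps == pytest.approx(v, rel=0.10)

    def test_reml_agrees_with_anova_on_balanced_data(self):
        df = simulate_nested(6, 8, 6, 1.0, 2.0, 0.5, seed=3)
        a = variance_components(df, method="anova")[0]
        r = variance_components(df, method="reml")[0]
        assert r.species_within_site == pytest.approx(
            a.species_within_site, rel=0.05)
        assert r.intraspecific == pytest.approx(a.intraspecific, rel=0.05)

    def test_single_site_flagged(self):
        df = simulate_nested(1, 5, 4, 0.0, 1.0, 0.5, seed=2)
        vc = variance_components(df)[0]
        assert vc.site == 0.0
        assert any("single site" in f for f in vc.flags)

    def test_proportions_sum_to_one(self, replicate_table):
        for vc in variance_components(replicate_table, traits=["ks", "density"],
                                      method="anova"):
            assert sum(vc.proportions.values()) == pytest.approx(1.0)
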