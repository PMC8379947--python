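"""Non-SEM analyses: Pearson correlation network with significance
tiers, network strength centrality, PCA on the correlation matrix, and
nested variance partitioning (site / species-within-site / within-species).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "VarianceComponents",
    "correlation_matrix",
    "network_strength",
    "pca_summary",
    "variance_components",
]

_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.10, "."))


def _tier(p: float) -> str:
    for cut, label in _TIERS:
        if p < cut:
            return label
    return ""


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r with two-sided p-values and significance tiers
    (*** < 0.001, ** < 0.01, * < 0.05, . < 0.10)."""

    r: pd.DataFrame
    p: pd.DataFrame
    tiers: pd.DataFrame
    n: int
    through_origin: bool = False

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str, float]]:
        out = []
        cols = list(self.r.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                if self.p.loc[a, b] < alpha:
                    out.append((a, b, float(self.r.loc[a, b])))
        return out


def correlation_matrix(
    table, through_origin: bool = False
) -> CorrelationMatrix:
    """Pearson correlations among all trait columns.

    ``table`` is a TraitTable or a numeric DataFrame.  With
    ``through_origin`` (for independent contrasts) r is the uncentered
    cross-product correlation and the t test uses n - 1 degrees of
    freedom; otherwise the ordinary Pearson r with n - 2 df.
    """
    df = getattr(table, "traits", None)
    if df is None:
        df = getattr(table, "data", table)
        df = df.select_dtypes(include=[np.number])
    x = df.to_numpy(float)
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 complete rows")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(df.columns, sd) if s == 0]
        raise ValueError(f"zero-variance column(s): {bad}")
    if through_origin:
        cross = x.T @ x
        d = np.sqrt(np.diag(cross))
        r = cross / np.outer(d, d)
        dof = n - 1
    else:
        r = np.corrcoef(x, rowvar=False)
        dof = n - 2
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / (1.0 - r**2))
    pmat = 2.0 * stats.t.sf(np.abs(t), dof)
    pmat = np.where(np.isnan(pmat), 0.0, pmat)  # |r| = 1 -> p = 0
    np.fill_diagonal(pmat, 0.0)
    cols = list(df.columns)
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(pmat, index=cols, columns=cols)
    tiers = pdf.map(_tier)
    for c in cols:
        tiers.loc[c, c] = ""
    return CorrelationMatrix(r=rdf, p=pdf, tiers=tiers, n=n,
                             through_origin=through_origin)


def network_strength(
    corr: CorrelationMatrix, significant_only: bool = False, alpha: float = 0.05
) -> pd.Series:
    """Strength centrality: for each trait, the sum of |r| to all other
    traits (diagonal excluded), sorted descending.  ``significant_only``
    restricts the sum to edges with p below ``alpha``."""
    r = corr.r.to_numpy().copy()
    np.fill_diagonal(r, 0.0)
    w = np.abs(r)
    if significant_only:
        mask = corr.p.to_numpy() < alpha
        np.fill_diagonal(mask, False)
        w = w * mask
    s = pd.Series(w.sum(axis=1), index=corr.r.columns, name="strength")
    return s.sort_values(ascending=False)


def pca_summary(table, standardize: bool = True) -> dict:
    """PCA by eigendecomposition of the correlation (default) or
    covariance matrix.

    Returns a dict with ``loadings`` (columns PC1, PC2, ...),
    ``variance_fraction`` (the scree), ``eigenvalues``, and ``scores``.
    Components are ordered by eigenvalue; each column's sign is fixed so
    its largest-magnitude loading is positive.
    """
    df = getattr(table, "traits", None)
    if df is None:
        df = getattr(table, "data", table)
        df = df.select_dtypes(include=[np.number])
    x = df.to_numpy(float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rows for PCA")
    xc = x - x.mean(axis=0)
    if standardize:
        xc = xc / xc.std(axis=0, ddof=1)
    c = np.cov(xc, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(c)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.maximum(vals[order], 0.0), vecs[:, order]
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    cols = [f"PC{i + 1}" for i in range(len(vals))]
    loadings = pd.DataFrame(vecs, index=df.columns, columns=cols)
    frac = vals / vals.sum()
    return {
        "loadings": loadings,
        "eigenvalues": pd.Series(vals, index=cols),
        "variance_fraction": pd.Series(frac, index=cols),
        "scores": pd.DataFrame(xc @ vecs, columns=cols),
    }


@dataclass
class VarianceComponents:
    """Nested variance decomposition for one trait."""

    trait: str
    site: float
    species_within_site: float
    intraspecific: float
    method: str
    flags: list[str]

    @property
    def total(self) -> float:
        return self.site + self.species_within_site + self.intraspecific

    @property
    def proportions(self) -> dict[str, float]:
        t = self.total
        if t <= 0:
            return {"site": 0.0, "species_within_site": 0.0, "intraspecific": 0.0}
        return {
            "site": self.site / t,
            "species_within_site": self.species_within_site / t,
            "intraspecific": self.intraspecific / t,
        }


def _anova_components(df: pd.DataFrame, trait: str) -> tuple[float, float, float]:
    """Nested-ANOVA (method-of-moments) estimator for the balanced
    two-level design: sites, species within site, replicates within
    species.  Negative solutions are truncated to zero."""
    y = df[trait].to_numpy(float)
    grand = y.mean()
    sites = df.groupby("site")
    n = len(y)
    n_site = sites.ngroups
    ss_site = sum(len(g) * (g[trait].mean() - grand) ** 2 for _, g in sites)
    ss_species = 0.0
    ss_within = 0.0
    n_species_tot = 0
    for _, g in sites:
        smean = g[trait].mean()
        for _, gg in g.groupby("species"):
            n_species_tot += 1
            ss_species += len(gg) * (gg[trait].mean() - smean) ** 2
            ss_within += ((gg[trait] - gg[trait].mean()) ** 2).sum()
    df_site = n_site - 1
    df_species = n_species_tot - n_site
    df_within = n - n_species_tot
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    ms_species = ss_species / df_species if df_species > 0 else 0.0
    ms_site = ss_site / df_site if df_site > 0 else 0.0
    # balanced expected mean squares: r reps/species, m species/site
    r = n / n_species_tot
    m = n_species_tot / n_site
    var_e = ms_within
    var_sp = max((ms_species - ms_within) / r, 0.0)
    var_site = max((ms_site - ms_species) / (r * m), 0.0)
    return var_site, var_sp, var_e


def _reml_components(df: pd.DataFrame, trait: str) -> tuple[float, float, float]:
    """REML fit of the nested random-effects model via statsmodels
    MixedLM: random site intercept + species-within-site component."""
    import statsmodels.formula.api as smf

    d = df[["site", "species", trait]].rename(columns={trait: "y"}).copy()
    d["site"] = d["site"].astype(str)
    d["species"] = d["species"].astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(
            "y ~ 1", d, groups="site", re_formula="1",
            vc_formula={"species": "0 + C(species)"},
        )
        res = md.fit(reml=True)
    var_site = float(res.cov_re.iloc[0, 0])
    var_sp = float(res.vcomp[0])
    var_e = float(res.scale)
    return max(var_site, 0.0), max(var_sp, 0.0), max(var_e, 0.0)


def variance_components(
    table, traits: list[str] | None = None, method: str = "reml"
) -> list[VarianceComponents]:
    """Partition each trait's variance among site, species within site,
    and within-species (intraspecific) levels.

    ``table`` is a replicate-level TraitTable or DataFrame with ``site``
    and ``species`` columns.  ``method`` is "reml" (mixed model via
    statsmodels) or "anova" (method-of-moments for balanced designs).
    A single site makes the site component structurally zero (flagged).
    """
    df = getattr(table, "data", table)
    for col in ("site", "species"):
        if col not in df.columns:
            raise ValueError(f"replicate table needs a {col!r} column")
    if traits is None:
        traits = [
            c for c in df.columns
            if c not in ("site", "species", "replicate")
            and np.issubdtype(df[c].dtype, np.number)
        ]
    out = []
    single_site = df["site"].nunique() < 2
    for trait in traits:
        flags = []
        if single_site:
            flags.append("single site: site component structurally 0")
            sub = df[["species", trait]].copy()
            sub["site"] = "only"
            v_site, v_sp, v_e = 0.0, *_anova_components(sub, trait)[1:]
            method_used = "anova"
        elif method == "anova":
            v_site, v_sp, v_e = _anova_components(df, trait)
            method_used = "anova"
        else:
            v_site, v_sp, v_e = _reml_components(df, trait)
            method_used = "reml"
        out.append(
            VarianceComponents(
                trait=trait, site=v_site, species_within_site=v_sp,
                intraspecific=v_e, method=method_used, flags=flags,
            )
        )
    return out
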