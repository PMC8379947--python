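"""Synthetic data with the statistical structure the analysis assumes.

Three generators cover the three arms of the pipeline:

* species means drawn multivariate-normal from the covariance implied by
  a population path model (the RAM identity), for SEM recovery tests;
* replicate-level tables with additive site effects and intraspecific
  noise on the transformed scale, for variance partitioning;
* pure-birth trees with multivariate Brownian-motion tip traits, for the
  independent-contrasts arm.

Every generator is a pure function of (config, seed).  The default
configuration mirrors the study design this package is built around:
29 species across 4 sites with 6 replicate stems per species.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .fit import fit_ml, implied_covariance, SemFitError
from .model import ModelSpec, build_ram
from .phylo import Phylogeny
from .traits import TraitTable, DEFAULT_TRANSFORMS
from .xylem_models import TRAIT_NAMES, full_model

__all__ = [
    "SimConfig",
    "default_population",
    "population_covariance",
    "simulate_from_sem",
    "simulate_replicates",
    "simulate_nested",
    "simulate_tree_bm",
    "parameter_recovery_report",
]

# Population coefficients for the 14-path xylem topology: moderate
# standardized-scale magnitudes (|0.2| to |0.7|).  Keys follow
# ModelSpec.free_parameters() labels.
DEFAULT_THETA = {
    ("loading", "vessel", "CT"): -0.7,
    ("loading", "parenchyma", "CT"): -0.5,
    ("path", "capacitance", "pmin"): 0.4,
    ("path", "pmin", "p75"): 0.7,
    ("path", "density", "p75"): 0.2,
    ("path", "CT", "p75"): -0.2,
    ("path", "pmin", "ks"): -0.3,
    ("path", "p75", "ks"): -0.6,
    ("path", "density", "ks"): -0.2,
    ("path", "CT", "ks"): 0.2,
    ("path", "pmin", "CT"): 0.5,
    ("path", "pmin", "density"): 0.4,
    ("path", "CT", "density"): -0.3,
    ("path", "pmin", "starch"): 0.6,
    ("path", "CT", "starch"): -0.4,
    ("path", "density", "capacitance"): -0.5,
    ("cov", "vessel", "parenchyma"): 0.05,
}
DEFAULT_RESIDUAL_VARIANCE = 0.5

# plausible transformed-scale trait means (ln units except density and
# capacitance); cosmetic only -- the covariance structure carries the model
DEFAULT_MEANS = {
    "pmin": 1.5, "p75": 1.8, "ks": 0.0, "capacitance": 0.08, "starch": 1.1,
    "density": 0.58, "fiber": -0.6, "vessel": -2.1, "parenchyma": -1.4,
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration for the synthetic-data generators.

    ``theta_pop`` maps free-parameter labels of ``model`` to population
    values; unlisted variances default to
    ``DEFAULT_RESIDUAL_VARIANCE``.  ``seed`` is mandatory for every
    stochastic call.
    """

    model: ModelSpec = field(default_factory=full_model)
    theta_pop: dict = field(default_factory=lambda: dict(DEFAULT_THETA))
    n_species: int = 29
    n_sites: int = 4
    n_reps: int = 6
    site_variance: float = 0.05
    intraspecific_variance: float = 0.25
    tree_tips: int = 29
    birth_rate: float = 1.0
    seed: int | None = None

    def theta_vector(self) -> np.ndarray:
        out = []
        for label in self.model.free_parameters():
            if label in self.theta_pop:
                out.append(self.theta_pop[label])
            elif label[0] == "var":
                out.append(DEFAULT_RESIDUAL_VARIANCE)
            else:
                raise KeyError(f"no population value for parameter {label}")
        return np.asarray(out, dtype=float)


def default_population(seed: int | None = None) -> SimConfig:
    """The shipped population: 14-path xylem topology, moderate effects."""
    return SimConfig(seed=seed)


def population_covariance(config: SimConfig) -> pd.DataFrame:
    """Population covariance Sigma(theta_pop) of the observed traits,
    from the same RAM identity the fitting engine uses."""
    ram = build_ram(config.model)
    sigma = implied_covariance(ram, config.theta_vector())
    vals = np.linalg.eigvalsh(sigma)
    if vals.min() <= 0:
        raise SemFitError("population covariance is not positive definite")
    cols = list(config.model.observed)
    return pd.DataFrame(sigma, index=cols, columns=cols)


def simulate_from_sem(config: SimConfig, seed: int | None = None) -> TraitTable:
    """Draw a species-level trait table from the population model.

    Species means are multivariate normal with covariance
    Sigma(theta_pop); sites are assigned round-robin.  The table is
    marked as already transformed (the model lives on the transformed
    scale).
    """
    seed = config.seed if seed is None else seed
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    sigma = population_covariance(config)
    cols = list(sigma.columns)
    mu = np.array([DEFAULT_MEANS.get(c, 0.0) for c in cols])
    x = rng.multivariate_normal(mu, sigma.to_numpy(), size=config.n_species,
                                method="cholesky")
    df = pd.DataFrame(x, columns=cols)
    # reorder to the canonical trait order when all nine are present
    if set(TRAIT_NAMES) <= set(cols):
        df = df[list(TRAIT_NAMES)]
    df.insert(0, "species", [f"sp{i + 1:02d}" for i in range(config.n_species)])
    df.insert(1, "site", [f"site{i % config.n_sites + 1}"
                          for i in range(config.n_species)])
    return TraitTable(
        data=df, level="species",
        transforms={c: DEFAULT_TRANSFORMS.rule(c) for c in TRAIT_NAMES
                    if c in df.columns},
    )


def simulate_replicates(
    species_table: TraitTable, config: SimConfig, seed: int | None = None
) -> TraitTable:
    """Expand species means to replicate stems.

    Each replicate value is species mean + site effect + intraspecific
    noise, all additive on the transformed scale; site effects are
    shared by the species of a site (drawn once per site and trait).
    """
    seed = config.seed if seed is None else seed
    if seed is None:
        raise ValueError("a seed is required")
    if config.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed + 1)
    df = species_table.data
    trait_cols = [c for c in df.columns if c not in ("species", "site")]
    sites = sorted(df["site"].unique())
    site_eff = {
        s: rng.normal(0.0, np.sqrt(config.site_variance), size=len(trait_cols))
        for s in sites
    }
    rows = []
    for _, sp in df.iterrows():
        for rep in range(config.n_reps):
            noise = rng.normal(0.0, np.sqrt(config.intraspecific_variance),
                               size=len(trait_cols))
            vals = sp[trait_cols].to_numpy(float) + site_eff[sp["site"]] + noise
            rows.append([sp["species"], sp["site"], f"r{rep + 1}", *vals])
    out = pd.DataFrame(rows, columns=["species", "site", "replicate", *trait_cols])
    return TraitTable(data=out, level="replicate",
                      transforms=dict(species_table.transforms))


def simulate_nested(
    n_sites: int,
    n_species_per_site: int,
    n_reps: int,
    var_site: float,
    var_species: float,
    var_intra: float,
    seed: int,
    trait: str = "y",
) -> pd.DataFrame:
    """Balanced nested design with known variance components, for
    calibration of the variance-partitioning estimators."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sites):
        se = rng.normal(0.0, np.sqrt(var_site))
        for k in range(n_species_per_site):
            spe = rng.normal(0.0, np.sqrt(var_species))
            for r in range(n_reps):
                rows.append({
                    "site": f"site{s + 1}",
                    "species": f"sp{s + 1}_{k + 1}",
                    "replicate": f"r{r + 1}",
                    trait: se + spe + rng.normal(0.0, np.sqrt(var_intra)),
                })
    return pd.DataFrame(rows)


def simulate_tree_bm(
    tips: int, trait_cov: np.ndarray | pd.DataFrame, seed: int,
    birth_rate: float = 1.0,
) -> tuple[Phylogeny, pd.DataFrame]:
    """Pure-birth tree plus multivariate Brownian-motion tip traits.

    The tree is a Yule (birth-only) process stopped at ``tips`` extant
    tips; trait values evolve from 0 at the root with per-unit-time
    covariance ``trait_cov`` along each branch.  Returns the tree and a
    DataFrame of tip trait values with a ``species`` column.
    """
    if tips < 2:
        raise ValueError("need at least 2 tips")
    cov = np.asarray(getattr(trait_cov, "to_numpy", lambda: trait_cov)(), float)
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError("trait covariance must be positive definite")
    cols = (list(trait_cov.columns) if isinstance(trait_cov, pd.DataFrame)
            else [f"trait{i + 1}" for i in range(cov.shape[0])])
    rng_py = random.Random(int(seed))
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=tips,
        rng=rng_py,
    )
    chol = np.linalg.cholesky(cov)
    rng = np.random.default_rng(int(seed))
    values: dict[int, np.ndarray] = {id(tree.seed_node): np.zeros(cov.shape[0])}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        b = nd.edge.length if nd.edge.length else 0.0
        step = chol @ rng.standard_normal(cov.shape[0]) * np.sqrt(max(b, 0.0))
        values[id(nd)] = values[id(nd.parent_node)] + step
    rows = []
    for i, leaf in enumerate(tree.leaf_node_iter()):
        if leaf.taxon is None:
            leaf.taxon = tree.taxon_namespace.new_taxon(label=f"T{i + 1}")
        rows.append({"species": leaf.taxon.label,
                     **dict(zip(cols, values[id(leaf)]))})
    df = pd.DataFrame(rows)
    return Phylogeny(tree=tree), df


def parameter_recovery_report(
    config: SimConfig,
    replications: int = 200,
    n: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Monte-Carlo recovery of every free population parameter.

    For each replicate, draws ``n`` species (default: the config's
    species count), fits the model, and records the estimate, its SE,
    and whether the 95% Wald interval covers the truth.  Reports
    per-parameter bias, the Monte-Carlo SE of the bias, RMSE, SE
    calibration (mean SE / SD of estimates), and coverage.  Replicates
    that fail to converge are dropped; more than 5% failures is flagged.
    """
    seed = config.seed if seed is None else seed
    if seed is None:
        raise ValueError("a seed is required")
    n = config.n_species if n is None else n
    truth = config.theta_vector()
    labels = config.model.free_parameters()
    sigma = population_covariance(config).to_numpy()
    cols = list(config.model.observed)
    rng = np.random.default_rng(seed)
    ests, ses, covers = [], [], []
    failed = 0
    for _ in range(replications):
        x = rng.multivariate_normal(np.zeros(len(cols)), sigma, size=n,
                                    method="cholesky")
        s = np.cov(x, rowvar=False, ddof=1)
        try:
            fit = fit_ml(config.model, s, n)
        except SemFitError:
            failed += 1
            continue
        ests.append(fit.theta)
        ses.append(fit.se)
        covers.append(np.abs(fit.theta - truth) <= 1.96 * fit.se)
    if not ests:
        raise SemFitError("all recovery replicates failed to converge")
    est = np.asarray(ests)
    se = np.asarray(ses)
    cov95 = np.asarray(covers, dtype=float)
    r = est.shape[0]
    bias = est.mean(axis=0) - truth
    mc_se = est.std(axis=0, ddof=1) / np.sqrt(r)
    report = pd.DataFrame({
        "kind": [l[0] for l in labels],
        "lhs": [l[1] for l in labels],
        "rhs": [l[2] for l in labels],
        "truth": truth,
        "mean_estimate": est.mean(axis=0),
        "bias": bias,
        "mc_se": mc_se,
        "rmse": np.sqrt(((est - truth) ** 2).mean(axis=0)),
        "se_calibration": se.mean(axis=0) / est.std(axis=0, ddof=1),
        "coverage_95": cov95.mean(axis=0),
    })
    report.attrs["n_replicates"] = r
    report.attrs["n_failed"] = failed
    report.attrs["failure_flag"] = failed > 0.05 * replications
    return report
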