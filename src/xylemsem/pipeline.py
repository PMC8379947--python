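"""End-to-end orchestration: transform -> fit -> prune -> bootstrap ->
compare -> contrasts arm -> reduced-variable arm -> reversal test ->
descriptive layer, with a comparison-table report bundle on disk.

The report mirrors the conventional model-comparison layout (columns
K, AICc, AIC, BIC, CFI, TLI, LL, df, chi2, P, P_BS) with separate blocks
for raw traits and for independent contrasts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .descriptive import (
    correlation_matrix,
    network_strength,
    pca_summary,
    variance_components,
)
from .fit import fit_indices, fit_ml, standardized_solution
from .inference import bollen_stine_pvalue, prune_paths, reverse_path_test
from .model import parse_model_spec
from .phylo import contrasts_covariance, independent_contrasts, read_newick
from .simulate import SimConfig, simulate_from_sem, simulate_replicates
from .traits import DEFAULT_TRANSFORMS, apply_transforms, load_trait_table
from .xylem_models import FULL_MODEL_TEXT

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_full_analysis"]

log = logging.getLogger("xylemsem")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Inputs, conventions, and options for one full analysis run.

    When ``trait_csv`` is None a synthetic species table is generated
    from the shipped population model (``simulate=True`` implied), which
    makes a complete demonstration run possible with no input files.
    """

    trait_csv: str | None = None
    replicate_csv: str | None = None
    newick: str | None = None
    full_model_text: str = FULL_MODEL_TEXT
    best_model_text: str | None = None
    apply_transform: bool = True
    chi2_multiplier: str = "n-1"
    bootstrap_b: int = 1000
    seed: int | None = None
    prune_alpha: float = 0.05
    prune_criterion: str = "AICc"
    drop_variable: str | None = "pmin"
    reverse_path: tuple[str, str] | None = ("p75", "ks")
    output_dir: str = "xylemsem_output"
    simulate: bool = False
    n_species: int = 29

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("full_model_text", "best_model_text"):
            # model text may be given inline or as a file path
            if isinstance(raw.get(key), str) and Path(raw[key]).is_file():
                raw[key] = Path(raw[key]).read_text()
        if "reverse_path" in raw and raw["reverse_path"] is not None:
            raw["reverse_path"] = tuple(raw["reverse_path"])
        return cls(**raw)


def validate_config(config: RunConfig) -> dict:
    """Resolve paths and conventions; enumerate K of each model file.

    Returns a report dict; raises :class:`ConfigError` on missing files
    or a stochastic stage enabled without a seed.
    """
    report: dict = {"version": __version__}
    for name in ("trait_csv", "replicate_csv", "newick"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{name} path does not exist: {p}")
        report[name] = p
    stochastic = config.bootstrap_b > 0 or config.simulate or config.trait_csv is None
    if stochastic and config.seed is None:
        raise ConfigError("a seed is required when any stochastic stage is enabled")
    if config.chi2_multiplier not in ("n-1", "n"):
        raise ConfigError(f"unknown chi2 multiplier {config.chi2_multiplier!r}")
    full = parse_model_spec(config.full_model_text)
    report["full_model_K"] = full.k
    report["full_model_df"] = full.df
    if config.best_model_text:
        best = parse_model_spec(config.best_model_text)
        report["best_model_K"] = best.k
        report["best_model_df"] = best.df
    report["chi2_multiplier"] = config.chi2_multiplier
    report["seed"] = config.seed
    return report


def _fmt(x) -> str:
    if x is None:
        return "na"
    if isinstance(x, float):
        return f"{x:,.1f}" if abs(x) >= 1000 else f"{x:.2f}"
    return str(x)


def _comparison_tsv(rows: list[dict], path: Path) -> None:
    cols = ["block", "model", "K", "AICc", "AIC", "BIC", "CFI", "TLI",
            "LL", "df", "chi2", "P", "P_BS"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(_fmt(r.get(c)) for c in cols) + "\n")


def _stage(name: str, t0: float, **extra) -> None:
    log.info("stage=%s wall_s=%.2f %s", name, time.time() - t0,
             " ".join(f"{k}={v}" for k, v in extra.items()))


def run_full_analysis(config: RunConfig) -> dict:
    """Run the complete pipeline and write the report bundle.

    Writes the comparison TSV, parameter tables (unstandardized and
    standardized with R^2), the prune trace, the descriptive outputs,
    and a JSON manifest with versions, seed, and a config hash.
    Returns a dict of in-memory results keyed by stage.
    """
    validate_config(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    comparison_rows: list[dict] = []

    # ---- data -----------------------------------------------------------
    t0 = time.time()
    if config.trait_csv is not None:
        table = load_trait_table(config.trait_csv, level="species",
                                 transformed=not config.apply_transform)
        if config.apply_transform:
            table = apply_transforms(table, DEFAULT_TRANSFORMS)
        rep_table = (load_trait_table(config.replicate_csv, level="replicate",
                                      aggregate=False,
                                      transformed=not config.apply_transform)
                     if config.replicate_csv else None)
        if rep_table is not None and config.apply_transform:
            rep_table = apply_transforms(rep_table, DEFAULT_TRANSFORMS)
    else:
        sim = SimConfig(seed=config.seed, n_species=config.n_species)
        table = simulate_from_sem(sim)
        rep_table = simulate_replicates(table, sim)
    n = len(table.data)
    data = table.traits
    sample_cov = table.covariance()
    _stage("data", t0, n_species=n)

    # ---- raw-trait SEM arm ---------------------------------------------
    t0 = time.time()
    full_spec = parse_model_spec(config.full_model_text)
    full_fit = fit_ml(full_spec, sample_cov, n,
                      chi2_multiplier=config.chi2_multiplier)
    trace = prune_paths(full_spec, sample_cov, n, alpha=config.prune_alpha,
                        criterion=config.prune_criterion,
                        chi2_multiplier=config.chi2_multiplier)
    best_fit = trace.final_fit
    fits = {"full": full_fit, "best": best_fit}
    if config.best_model_text:
        shipped_best = parse_model_spec(config.best_model_text)
        fits["shipped_best"] = fit_ml(shipped_best, sample_cov, n,
                                      chi2_multiplier=config.chi2_multiplier)
    p_bs: dict[str, float] = {}
    if config.bootstrap_b > 0:
        for name, f in fits.items():
            bs = bollen_stine_pvalue(f.spec, data,
                                     b=config.bootstrap_b, seed=config.seed,
                                     chi2_multiplier=config.chi2_multiplier)
            p_bs[name] = bs.p_value
    for name, f in fits.items():
        row = {"block": "raw", "model": name}
        row.update(fit_indices(f).as_dict())
        row["P_BS"] = p_bs.get(name)
        comparison_rows.append(row)
    results["raw"] = {"fits": fits, "prune_trace": trace, "p_bs": p_bs}
    std = standardized_solution(best_fit)
    std.to_csv(out / "best_model_parameters.tsv", sep="\t", index=False,
               float_format="%.6g")
    standardized_solution(full_fit).to_csv(
        out / "full_model_parameters.tsv", sep="\t", index=False,
        float_format="%.6g")
    trace.as_frame().to_json(out / "prune_trace.json", orient="records",
                             indent=1)
    _stage("sem_raw", t0, chi2_full=f"{full_fit.chi2:.2f}",
           removed=len(trace.removed_paths))

    # ---- reversal sensitivity ------------------------------------------
    if config.reverse_path is not None:
        t0 = time.time()
        src, dst = config.reverse_path
        try:
            rev = reverse_path_test(best_fit.spec, (src, dst), sample_cov, n,
                                    chi2_multiplier=config.chi2_multiplier)
            row = {"block": "raw", "model": f"reversed_{src}->{dst}"}
            row.update(fit_indices(rev).as_dict())
            comparison_rows.append(row)
            results["reversal"] = rev
        except Exception as exc:  # path may have been pruned away
            log.warning("reversal test skipped: %s", exc)
        _stage("reversal", t0)

    # ---- reduced-variable arm ------------------------------------------
    if config.drop_variable:
        t0 = time.time()
        reduced = full_spec.drop_variable(config.drop_variable)
        cols = [c for c in data.columns if c != config.drop_variable]
        sub_cov = sample_cov.loc[cols, cols]
        red_fit = fit_ml(reduced, sub_cov, n,
                         chi2_multiplier=config.chi2_multiplier)
        red_trace = prune_paths(reduced, sub_cov, n, alpha=config.prune_alpha,
                                criterion=config.prune_criterion,
                                chi2_multiplier=config.chi2_multiplier)
        row = {"block": f"no_{config.drop_variable}", "model": "full"}
        row.update(fit_indices(red_fit).as_dict())
        comparison_rows.append(row)
        row = {"block": f"no_{config.drop_variable}", "model": "best"}
        row.update(fit_indices(red_trace.final_fit).as_dict())
        comparison_rows.append(row)
        results["reduced"] = {"fit": red_fit, "trace": red_trace}
        _stage("reduced_variable", t0, dropped=config.drop_variable)

    # ---- contrasts arm --------------------------------------------------
    if config.newick is not None:
        t0 = time.time()
        phylo = read_newick(config.newick, taxa=table.species)
        cs = independent_contrasts(phylo, table, unit_lengths=True)
        pic_cov = contrasts_covariance(cs)
        n_pic = cs.n
        pic_full = fit_ml(full_spec, pic_cov, n_pic,
                          chi2_multiplier=config.chi2_multiplier)
        pic_trace = prune_paths(full_spec, pic_cov, n_pic,
                                alpha=config.prune_alpha,
                                criterion=config.prune_criterion,
                                chi2_multiplier=config.chi2_multiplier)
        for name, f in (("full", pic_full), ("best", pic_trace.final_fit)):
            row = {"block": "pic", "model": name}
            row.update(fit_indices(f).as_dict())
            comparison_rows.append(row)
        cs.contrasts.to_csv(out / "contrasts.csv", index=False,
                            float_format="%.6g")
        results["pic"] = {"contrasts": cs, "full": pic_full,
                          "trace": pic_trace}
        _stage("pic", t0, n_contrasts=n_pic)

    # ---- descriptive layer ---------------------------------------------
    t0 = time.time()
    corr = correlation_matrix(table)
    strength = network_strength(corr)
    pca = pca_summary(table)
    corr.r.to_csv(out / "correlations.tsv", sep="\t", float_format="%.6g")
    corr.tiers.to_csv(out / "correlation_significance.tsv", sep="\t")
    strength.to_csv(out / "network_strength.tsv", sep="\t",
                    float_format="%.6g")
    pca["loadings"].to_csv(out / "pca_loadings.csv", float_format="%.6g")
    pca["variance_fraction"].to_csv(out / "pca_scree.csv",
                                    float_format="%.6g")
    results["descriptive"] = {"correlations": corr, "strength": strength,
                              "pca": pca}
    if rep_table is not None:
        vc = variance_components(rep_table)
        pd.DataFrame([
            {"trait": v.trait, **v.proportions, "method": v.method}
            for v in vc
        ]).to_csv(out / "variance_components.tsv", sep="\t", index=False,
                  float_format="%.6g")
        results["variance_components"] = vc
    _stage("descriptive", t0)

    # ---- report ---------------------------------------------------------
    _comparison_tsv(comparison_rows, out / "model_comparison.tsv")
    cfg_text = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True)
    manifest = {
        "xylemsem_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "chi2_multiplier": config.chi2_multiplier,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "n_species": n,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["comparison"] = comparison_rows
    results["manifest"] = manifest
    return results
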