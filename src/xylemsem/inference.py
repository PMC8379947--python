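"""Inferential workflow around a single fit: Bollen-Stine bootstrap,
iterative path pruning with an information-criterion guard, model
comparison tables, the path-reversal sensitivity check, and reduced
model variants with a variable removed.

The chi-square test of covariance structure is anti-conservative at
small n (here 29 species).  The Bollen-Stine bootstrap addresses this
by transforming the data so its sample covariance equals the fitted
model's implied covariance, resampling rows, and refitting: the
bootstrap chi-square values form a small-sample null distribution for
the observed statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .fit import SemFit, SemFitError, fit_indices, fit_ml
from .model import ModelSpec

__all__ = [
    "BootstrapResult",
    "PruneTrace",
    "bollen_stine_transform",
    "bollen_stine_pvalue",
    "prune_paths",
    "compare_models",
    "reverse_path_test",
    "drop_variable_variant",
]


def _sym_sqrt(m: np.ndarray, inverse: bool = False) -> np.ndarray:
    vals, vecs = linalg.eigh(m)
    if vals.min() <= 0:
        raise SemFitError("matrix is not symmetric positive definite")
    d = 1.0 / np.sqrt(vals) if inverse else np.sqrt(vals)
    return (vecs * d) @ vecs.T


def bollen_stine_transform(data: np.ndarray, sigma_hat: np.ndarray) -> np.ndarray:
    """Transform rows so their sample covariance equals ``sigma_hat``.

    Z = X_c S^{-1/2} Sigma_hat^{1/2} with X_c column-centered and S the
    (ddof=1) sample covariance of X; symmetric PSD matrix roots are
    used.  The sample covariance of the result equals Sigma_hat to
    numerical precision.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < x.shape[1]:
        raise SemFitError("data must be a 2-D matrix with rows >= columns")
    xc = x - x.mean(axis=0)
    s = np.cov(x, rowvar=False, ddof=1)
    z = xc @ _sym_sqrt(s, inverse=True) @ _sym_sqrt(np.asarray(sigma_hat, float))
    achieved = np.cov(z, rowvar=False, ddof=1)
    if not np.allclose(achieved, sigma_hat, atol=1e-8):
        raise SemFitError("Bollen-Stine transform failed to reproduce Sigma_hat")
    return z


@dataclass
class BootstrapResult:
    """Bollen-Stine bootstrap distribution of the model chi-square."""

    b: int
    chi2_observed: float
    chi2_boot: np.ndarray
    n_failed: int
    seed: int

    @property
    def p_value(self) -> float:
        """Fraction of converged bootstrap chi-squares >= the observed one."""
        return float(np.mean(self.chi2_boot >= self.chi2_observed))


def bollen_stine_pvalue(
    model: ModelSpec,
    data: np.ndarray | pd.DataFrame,
    b: int = 1000,
    seed: int | None = None,
    *,
    chi2_multiplier: str = "n-1",
    max_failure_rate: float = 0.10,
) -> BootstrapResult:
    """Bollen-Stine bootstrap p-value for a model on raw data rows.

    Fits the model, transforms the data to satisfy it exactly, then
    resamples rows with replacement ``b`` times and refits.  Replicates
    that fail to converge are excluded (with a warning); more than
    ``max_failure_rate`` failures is an error.
    """
    if b < 1:
        raise ValueError("bootstrap replicate count must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    if isinstance(data, pd.DataFrame):
        data = data[list(model.observed)].to_numpy(dtype=float)
    x = np.asarray(data, dtype=float)
    n = x.shape[0]
    s = np.cov(x, rowvar=False, ddof=1)
    fit = fit_ml(model, s, n, chi2_multiplier=chi2_multiplier)
    z = bollen_stine_transform(x, fit.implied)

    rng = np.random.default_rng(seed)
    chi2s = []
    failed = 0
    for _ in range(b):
        idx = rng.integers(0, n, size=n)
        sb = np.cov(z[idx], rowvar=False, ddof=1)
        try:
            fb = fit_ml(model, sb, n, chi2_multiplier=chi2_multiplier,
                        start=fit.theta)
            chi2s.append(fb.chi2)
        except SemFitError:
            failed += 1
    if failed:
        warnings.warn(f"{failed}/{b} bootstrap replicates failed to converge")
    if failed > max_failure_rate * b:
        raise SemFitError(
            f"bootstrap unstable: {failed}/{b} replicates failed to converge"
        )
    return BootstrapResult(
        b=b, chi2_observed=fit.chi2, chi2_boot=np.asarray(chi2s),
        n_failed=failed, seed=seed,
    )


@dataclass
class PruneTrace:
    """Replayable record of backward path pruning."""

    steps: list[dict] = field(default_factory=list)
    retained_nonsignificant: list[tuple[str, str, float]] = field(default_factory=list)
    final_model: ModelSpec | None = None
    final_fit: SemFit | None = None

    @property
    def removed_paths(self) -> list[tuple[str, str]]:
        return [s["path"] for s in self.steps if s["kept_removed"]]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "src": s["path"][0], "dst": s["path"][1],
                    "p_at_removal": s["p_value"], "removed": s["kept_removed"],
                    "criterion_delta": s["criterion_delta"],
                }
                for s in self.steps
            ]
        )


def prune_paths(
    model: ModelSpec,
    sample_cov: np.ndarray | pd.DataFrame,
    n: int,
    *,
    alpha: float = 0.05,
    criterion: str = "AICc",
    criterion_margin: float = 2.0,
    chi2_multiplier: str = "n-1",
) -> PruneTrace:
    """Backward-prune weakly supported paths, one at a time.

    At each step the free path with the largest Wald p-value above
    ``alpha`` is removed and the model refitted.  The removal is rolled
    back — and the path retained, recorded as non-significant — if the
    chosen information criterion worsens (increases) by more than
    ``criterion_margin``.  Ties on p are broken toward the path declared
    later in the model text.  Stops when no removable path remains.
    """
    crit = criterion.lower()
    if crit not in ("aicc", "aic", "bic"):
        raise ValueError("criterion must be AICc, AIC, or BIC")

    def crit_value(fit: SemFit) -> float:
        return {"aicc": fit.aicc, "aic": fit.aic, "bic": fit.bic}[crit]

    return _prune_impl(model, sample_cov, n, alpha, crit_value,
                       criterion_margin, chi2_multiplier, crit)


def _prune_impl(model, sample_cov, n, alpha, crit_value, margin,
                chi2_multiplier, crit_name) -> PruneTrace:
    trace = PruneTrace()
    current = model
    fit = fit_ml(current, sample_cov, n, chi2_multiplier=chi2_multiplier)
    blocked: set[tuple[str, str]] = set()
    while True:
        pvals = fit.path_p_values()
        candidates = [
            (p, pair) for pair, p in pvals.items()
            if p > alpha and pair not in blocked
        ]
        if not candidates:
            break
        decl_order = {(s, d): i for i, (s, d, _) in enumerate(current.paths)}
        candidates.sort(key=lambda t: (t[0], decl_order[t[1]]))
        p_max, pair = candidates[-1]
        reduced = current.drop_path(*pair)
        try:
            new_fit = fit_ml(reduced, sample_cov, n,
                             chi2_multiplier=chi2_multiplier)
        except SemFitError:
            trace.steps.append({
                "path": pair, "p_value": p_max, "kept_removed": False,
                "criterion_delta": np.nan, "indices": None,
                "note": "refit failed; rolled back, pruning stopped",
            })
            blocked.add(pair)
            break
        delta = crit_value(new_fit) - crit_value(fit)
        if delta > margin:
            trace.steps.append({
                "path": pair, "p_value": p_max, "kept_removed": False,
                "criterion_delta": delta,
                "indices": fit_indices(new_fit).as_dict(),
            })
            trace.retained_nonsignificant.append((*pair, p_max))
            blocked.add(pair)
            continue
        trace.steps.append({
            "path": pair, "p_value": p_max, "kept_removed": True,
            "criterion_delta": delta,
            "indices": fit_indices(new_fit).as_dict(),
        })
        current, fit = reduced, new_fit
    # paths still in the model with p > alpha that were never removable
    seen = {t[:2] for t in trace.retained_nonsignificant}
    for pair, p in fit.path_p_values().items():
        if p > alpha and pair not in seen:
            trace.retained_nonsignificant.append((*pair, p))
    trace.final_model = current
    trace.final_fit = fit
    return trace


def compare_models(fits: list[SemFit], labels: list[str] | None = None) -> pd.DataFrame:
    """Comparison table of fit statistics, one row per model.

    Columns follow the conventional layout K, AICc, AIC, BIC, CFI, TLI,
    LL, df, chi2, P, with deltas of each information criterion against
    the best (smallest) value.  All fits must be on the same data.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0]
    for f in fits[1:]:
        if f.sample_cov.shape != ref.sample_cov.shape or not np.allclose(
            f.sample_cov, ref.sample_cov
        ) or f.n != ref.n:
            raise SemFitError("models were fitted to different data")
    if labels is None:
        labels = [f"model_{i + 1}" for i in range(len(fits))]
    rows = []
    for lab, f in zip(labels, fits):
        idx = fit_indices(f)
        row = {"model": lab}
        row.update(idx.as_dict())
        if f.n - f.k - 1 <= 1:
            row["AICc_note"] = "unstable (n - K - 1 <= 1)"
        rows.append(row)
    tab = pd.DataFrame(rows)
    for col in ("AICc", "AIC", "BIC"):
        tab[f"d{col}"] = tab[col] - tab[col].min()
    return tab


def reverse_path_test(
    model: ModelSpec,
    path: tuple[str, str],
    sample_cov: np.ndarray | pd.DataFrame,
    n: int,
    *,
    chi2_multiplier: str = "n-1",
) -> SemFit:
    """Refit the model with one directed path reversed (K, df unchanged).

    A worsening chi-square relative to the original orientation is
    evidence that the original direction is the better description.
    """
    reversed_model = model.reverse_path(*path)
    return fit_ml(reversed_model, sample_cov, n, chi2_multiplier=chi2_multiplier)


def drop_variable_variant(model: ModelSpec, variable: str) -> ModelSpec:
    """Model variant with one observed variable removed entirely
    (its paths and variance entry go with it)."""
    return model.drop_variable(variable)
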