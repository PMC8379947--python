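"""Maximum-likelihood covariance-structure fitting and fit indices.

The engine minimizes the normal-theory discrepancy

    F_ML(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

over the free parameters of a RAM-parameterized model, where S is the
sample covariance of the p observed variables.  The model test statistic
is chi2 = c * F_ML at the minimum, with multiplier c = n - 1 by default
(a c = n convention is available via ``chi2_multiplier``).  The
log-likelihood is defined on the same scale, LL = LL_sat - chi2/2 with
LL_sat = -(c/2) (ln|S| + p), so that the identities

    chi2 = 2 (LL_sat - LL),   AIC = -2 LL + 2 K,   BIC = -2 LL + K ln n

hold exactly for every converged fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .model import ModelSpec, RamMatrices, build_ram, independence_model

__all__ = [
    "SemFit",
    "FitIndexSet",
    "SemFitError",
    "HeywoodWarning",
    "implied_covariance",
    "fit_ml",
    "fit_indices",
    "standardized_solution",
    "aic_from_loglik",
    "bic_from_loglik",
    "aicc_from_aic",
    "cfi_index",
    "tli_index",
]


# -- fit-index formulas (shared by fit_indices and reporting code) ---------
def aic_from_loglik(loglik: float, k: int) -> float:
    """AIC = -2 LL + 2 K."""
    return -2.0 * loglik + 2.0 * k


def bic_from_loglik(loglik: float, k: int, n: int) -> float:
    """BIC = -2 LL + K ln n."""
    return -2.0 * loglik + k * np.log(n)


def aicc_from_aic(aic: float, k: int, n: int) -> float:
    """Small-sample correction: AICc = AIC + 2K(K+1)/(n-K-1)."""
    if n - k - 1 <= 0:
        raise SemFitError(f"AICc undefined: n={n} <= K+1={k + 1}")
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def cfi_index(chi2: float, df: int, chi2_b: float, df_b: int) -> float:
    """Comparative fit index against the independence baseline."""
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    return float(np.clip(1.0 - num / den, 0.0, 1.0)) if den > 0 else 1.0


def tli_index(chi2: float, df: int, chi2_b: float, df_b: int) -> float | None:
    """Tucker-Lewis index; None when df or df_b is zero."""
    if df <= 0 or df_b <= 0:
        return None
    rb = chi2_b / df_b
    return (rb - chi2 / df) / (rb - 1.0)

_PENALTY = 1e12


class SemFitError(RuntimeError):
    """Raised on non-convergence or an unusable model/data combination."""


class HeywoodWarning(UserWarning):
    """A free variance was estimated negative (Heywood case)."""


def implied_covariance(ram: RamMatrices, theta: np.ndarray) -> np.ndarray:
    """Model-implied covariance Sigma = F (I-A)^-1 S (I-A)^-T F^T."""
    a, s = ram.fill(np.asarray(theta, dtype=float))
    m = ram.dim
    ima = np.eye(m) - a
    try:
        b = linalg.inv(ima)
    except linalg.LinAlgError as exc:
        cyc = _find_cycle(a, ram.names)
        raise SemFitError(
            f"(I - A) singular; directed cycle with unit gain? {cyc}"
        ) from exc
    full = b @ s @ b.T
    p = ram.n_observed
    return full[:p, :p]


def _find_cycle(a: np.ndarray, names: tuple[str, ...]) -> str:
    """Name variables on some directed cycle of A, for diagnostics."""
    m = a.shape[0]
    reach = (np.abs(a) > 0).astype(int)
    closure = reach.copy()
    for _ in range(m):
        closure = (closure | (closure @ reach > 0)).astype(int)
    on_cycle = [names[i] for i in range(m) if closure[i, i]]
    return "cycle through " + ", ".join(on_cycle) if on_cycle else "no cycle found"


@dataclass
class SemFit:
    """A converged maximum-likelihood fit of one model to one sample."""

    spec: ModelSpec
    ram: RamMatrices
    theta: np.ndarray
    se: np.ndarray
    sample_cov: np.ndarray
    n: int
    chi2_multiplier: str
    fmin: float
    chi2: float
    df: int
    p_value: float
    loglik: float
    loglik_saturated: float
    k: int
    converged: bool
    gradient_norm: float
    n_iter: int
    heywood: list[str] = field(default_factory=list)
    acov: np.ndarray | None = None

    @property
    def c(self) -> float:
        return float(self.n - 1 if self.chi2_multiplier == "n-1" else self.n)

    @property
    def aic(self) -> float:
        return aic_from_loglik(self.loglik, self.k)

    @property
    def bic(self) -> float:
        return bic_from_loglik(self.loglik, self.k, self.n)

    @property
    def aicc(self) -> float:
        return aicc_from_aic(self.aic, self.k, self.n)

    @property
    def implied(self) -> np.ndarray:
        return implied_covariance(self.ram, self.theta)

    def parameter_table(self) -> pd.DataFrame:
        """Free parameters with estimates, SEs, z and p values."""
        rows = []
        for (kind, i, j), est, se in zip(
            self.spec.free_parameters(), self.theta, self.se
        ):
            z = est / se if se > 0 else np.nan
            p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append(
                {"kind": kind, "lhs": i, "rhs": j, "estimate": est,
                 "se": se, "z": z, "p_value": p}
            )
        return pd.DataFrame(rows)

    def path_p_values(self) -> dict[tuple[str, str], float]:
        """Wald p-value for each free directed path (src, dst)."""
        out = {}
        for (kind, i, j), est, se in zip(
            self.spec.free_parameters(), self.theta, self.se
        ):
            if kind == "path":
                z = est / se if se > 0 else np.inf
                out[(i, j)] = 2.0 * stats.norm.sf(abs(z))
        return out


def _fml_and_grad(
    theta: np.ndarray, ram: RamMatrices, s_samp: np.ndarray, logdet_s: float
) -> tuple[float, np.ndarray]:
    m = ram.dim
    p = ram.n_observed
    a, s = ram.fill(theta)
    ima = np.eye(m) - a
    try:
        b = linalg.inv(ima)
    except linalg.LinAlgError:
        return _PENALTY, np.zeros_like(theta)
    c_full = b @ s @ b.T
    sigma = c_full[:p, :p]
    try:
        cho = linalg.cho_factor(sigma, check_finite=False)
    except linalg.LinAlgError:
        return _PENALTY, np.zeros_like(theta)
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(cho[0])))
    sigma_inv = linalg.cho_solve(cho, np.eye(p), check_finite=False)
    f = logdet_sigma + float(np.sum(sigma_inv * s_samp)) - logdet_s - p
    # W = Sigma^-1 - Sigma^-1 S Sigma^-1, padded to latent rows with zeros
    w = sigma_inv - sigma_inv @ s_samp @ sigma_inv
    wf = np.zeros((m, m))
    wf[:p, :p] = w
    mmat = b.T @ wf @ b          # for S entries
    gmat = c_full @ wf @ b       # for A entries: dF = 2 * gmat[src, dst]
    grad = np.empty_like(theta)
    for k, (mat, i, j) in enumerate(ram.theta_map):
        if mat == "A":
            grad[k] = 2.0 * gmat[j, i]
        elif i == j:
            grad[k] = mmat[i, i]
        else:
            grad[k] = 2.0 * mmat[i, j]
    return f, grad


def _sigma_derivatives(ram: RamMatrices, theta: np.ndarray) -> list[np.ndarray]:
    """dSigma/dtheta_k restricted to observed rows/cols, one per parameter."""
    m = ram.dim
    p = ram.n_observed
    a, s = ram.fill(theta)
    b = linalg.inv(np.eye(m) - a)
    c_full = b @ s @ b.T
    outs = []
    for mat, i, j in ram.theta_map:
        if mat == "A":
            t = np.outer(b[:, i], c_full[j, :])
            d = t + t.T
        elif i == j:
            d = np.outer(b[:, i], b[:, i])
        else:
            d = np.outer(b[:, i], b[:, j]) + np.outer(b[:, j], b[:, i])
        outs.append(d[:p, :p])
    return outs


def _expected_information(
    ram: RamMatrices, theta: np.ndarray, c: float
) -> np.ndarray:
    sigma = implied_covariance(ram, theta)
    sigma_inv = linalg.inv(sigma)
    derivs = [sigma_inv @ d for d in _sigma_derivatives(ram, theta)]
    k = len(derivs)
    info = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            info[i, j] = info[j, i] = 0.5 * c * np.sum(derivs[i] * derivs[j].T)
    return info


def fit_ml(
    model: ModelSpec,
    sample_cov: np.ndarray | pd.DataFrame,
    n: int,
    *,
    chi2_multiplier: str = "n-1",
    start: np.ndarray | None = None,
    variance_scale: str = "linear",
    gtol: float = 1e-6,
    max_iter: int = 10_000,
    fix_heywood: bool = False,
) -> SemFit:
    """Fit a path model to a sample covariance matrix by maximum likelihood.

    Parameters
    ----------
    model : ModelSpec
        The path model (observed order must match ``sample_cov``).
    sample_cov : (p, p) array or DataFrame
        Sample covariance of the observed variables (ddof=1 when the
        default ``chi2_multiplier="n-1"`` is used).  A DataFrame is
        reordered to the model's observed-variable order by label.
    n : int
        Sample size (for contrasts data, the number of contrast rows).
    chi2_multiplier : {"n-1", "n"}
        The c in chi2 = c * F_ML.
    variance_scale : {"linear", "log"}
        Internal parameterization of free variances.  The linear scale
        (default) permits negative estimates and hence Heywood-case
        detection; the log scale enforces positivity.
    fix_heywood : bool
        If a free variance is estimated negative, refit with that
        variance fixed to zero (the standard small-negative-error
        remedy) instead of only warning.
    """
    if isinstance(sample_cov, pd.DataFrame):
        sample_cov = sample_cov.loc[list(model.observed), list(model.observed)].to_numpy()
    s_samp = np.asarray(sample_cov, dtype=float)
    p = model.n_observed
    if s_samp.shape != (p, p):
        raise SemFitError(f"sample covariance must be {p}x{p} for this model")
    if not np.allclose(s_samp, s_samp.T, atol=1e-10):
        raise SemFitError("sample covariance must be symmetric")
    sign, logdet_s = np.linalg.slogdet(s_samp)
    if sign <= 0:
        raise SemFitError("sample covariance is not positive definite")
    kparams = model.k
    if kparams > p * (p + 1) // 2:
        raise SemFitError(
            f"model not identified: K={kparams} exceeds {p*(p+1)//2} moments"
        )

    ram = build_ram(model)

    # Optimize on the correlation scale: rescale each observed variable to
    # unit variance (a latent inherits its scale indicator's factor).  F_ML
    # is exactly equivariant under this reparameterization, so the optimum
    # maps back exactly; conditioning improves greatly for heterogeneous
    # trait scales.
    d_obs = np.sqrt(np.diag(s_samp))
    tvec = np.empty(ram.dim)
    tvec[:p] = d_obs
    for lat, inds in model.latents.items():
        tvec[ram.index[lat]] = d_obs[ram.index[inds[0]]]
    r_samp = s_samp / np.outer(d_obs, d_obs)
    _, logdet_r = np.linalg.slogdet(r_samp)

    ram_scaled = RamMatrices(
        spec=model,
        names=ram.names,
        index=ram.index,
        a_fixed=ram.a_fixed * np.outer(1.0 / tvec, tvec),
        s_fixed=ram.s_fixed / np.outer(tvec, tvec),
        theta_map=ram.theta_map,
    )
    # per-parameter factor: theta_original = factor * theta_scaled
    factors = np.array([
        tvec[i] / tvec[j] if mat == "A" else tvec[i] * tvec[j]
        for mat, i, j in ram.theta_map
    ])

    if start is not None:
        theta0 = np.asarray(start, float) / factors
    else:
        theta0 = ram_scaled.start_values(r_samp)

    var_idx = [
        k for k, (kind, _, _) in enumerate(model.free_parameters()) if kind == "var"
    ]
    use_log = variance_scale == "log"

    def to_internal(th: np.ndarray) -> np.ndarray:
        z = th.copy()
        if use_log:
            z[var_idx] = np.log(np.maximum(z[var_idx], 1e-10))
        return z

    def to_external(z: np.ndarray) -> np.ndarray:
        th = z.copy()
        if use_log:
            th[var_idx] = np.exp(th[var_idx])
        return th

    def objective(z: np.ndarray) -> tuple[float, np.ndarray]:
        th = to_external(z)
        f, g = _fml_and_grad(th, ram_scaled, r_samp, logdet_r)
        if use_log:
            g = g.copy()
            g[var_idx] *= th[var_idx]
        return f, g

    def run_from(theta_init: np.ndarray) -> tuple[np.ndarray, float, np.ndarray, int]:
        res = optimize.minimize(
            objective,
            to_internal(theta_init),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10,
                     "maxcor": 30},
        )
        th = to_external(res.x)
        it = int(res.nit)
        # Newton polish for tight closed-form agreement
        f_val, grad = _fml_and_grad(th, ram_scaled, r_samp, logdet_r)
        for _ in range(25):
            if np.linalg.norm(grad) < 1e-10:
                break
            hess = _num_grad_jacobian(
                lambda t: _fml_and_grad(t, ram_scaled, r_samp, logdet_r)[1], th
            )
            hess = 0.5 * (hess + hess.T)
            try:
                step = np.linalg.solve(hess + 1e-12 * np.eye(len(th)), -grad)
            except np.linalg.LinAlgError:
                break
            t_ls = 1.0
            improved = False
            for _ls in range(30):
                cand = th + t_ls * step
                f_new, g_new = _fml_and_grad(cand, ram_scaled, r_samp, logdet_r)
                if f_new <= f_val + 1e-14 and f_new < _PENALTY:
                    th, f_val, grad = cand, f_new, g_new
                    improved = True
                    break
                t_ls *= 0.5
            if not improved:
                break
            it += 1
        return th, f_val, grad, it

    # fallback starts: flipped free loadings, then seeded perturbations
    # (a loading crossing zero with a pinned error variance is a barrier)
    load_idx = [
        k for k, (kind, _, _) in enumerate(model.free_parameters())
        if kind == "loading"
    ]
    starts = [theta0]
    if load_idx:
        alt = theta0.copy()
        alt[load_idx] *= -1.0
        starts.append(alt)
    rng_starts = np.random.default_rng(0)
    for _ in range(3):
        alt = theta0 + rng_starts.normal(0.0, 0.3, size=len(theta0))
        alt[var_idx] = np.abs(alt[var_idx]) + 0.05
        starts.append(alt)

    best = None
    n_iter = 0
    last_gnorm, last_f = np.inf, np.inf
    for theta_init in starts:
        th, f_val, grad, it = run_from(theta_init)
        n_iter += it
        last_gnorm, last_f = float(np.linalg.norm(grad)), f_val
        if last_gnorm < gtol and f_val < _PENALTY:
            best = (th, f_val, last_gnorm)
            break  # first converged start wins (deterministic)
    if best is None:
        raise SemFitError(
            f"optimizer did not converge from {len(starts)} starts "
            f"(last gradient norm {last_gnorm:.3e}, F={last_f:.6g}) "
            f"after {n_iter} total iterations"
        )
    theta_scaled, f_val, gnorm = best
    theta = theta_scaled * factors

    heywood = [
        model.free_parameters()[k][1]
        for k in var_idx
        if theta[k] < 0
    ]
    if heywood:
        if fix_heywood:
            fixed = dict(model.variances)
            for v in heywood:
                fixed[v] = 0.0
            from dataclasses import replace as _replace

            warnings.warn(
                f"negative variance estimate for {heywood}; refitting with "
                "these error variances fixed to 0",
                HeywoodWarning,
            )
            return fit_ml(
                _replace(model, variances=fixed),
                s_samp,
                n,
                chi2_multiplier=chi2_multiplier,
                variance_scale=variance_scale,
                gtol=gtol,
                max_iter=max_iter,
                fix_heywood=False,
            )
        warnings.warn(
            f"Heywood case: negative variance estimate for {heywood}", HeywoodWarning
        )

    c = float(n - 1 if chi2_multiplier == "n-1" else n)
    fmin = max(f_val, 0.0)
    chi2 = c * fmin
    df = model.df
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    ll_sat = -0.5 * c * (logdet_s + p)
    ll = ll_sat - 0.5 * chi2

    try:
        # information on the well-conditioned correlation scale, then
        # transformed back (acov is equivariant under the rescaling)
        info = _expected_information(ram_scaled, theta_scaled, c)
        cond = np.linalg.cond(info)
        if cond > 1e12:
            warnings.warn(
                f"expected information nearly singular (cond {cond:.2e}); "
                "SEs from pseudo-inverse"
            )
            acov_s = np.linalg.pinv(info, hermitian=True)
        else:
            acov_s = linalg.inv(info)
        acov = acov_s * np.outer(factors, factors)
        se = np.sqrt(np.maximum(np.diag(acov), 0.0))
    except (linalg.LinAlgError, SemFitError):
        acov = None
        se = np.full_like(theta, np.nan)
        warnings.warn("information matrix unavailable; SEs set to NaN")

    return SemFit(
        spec=model,
        ram=ram,
        theta=theta,
        se=se,
        sample_cov=s_samp,
        n=int(n),
        chi2_multiplier=chi2_multiplier,
        fmin=fmin,
        chi2=float(chi2),
        df=int(df),
        p_value=p_value,
        loglik=float(ll),
        loglik_saturated=float(ll_sat),
        k=kparams,
        converged=True,
        gradient_norm=gnorm,
        n_iter=n_iter,
        heywood=heywood,
        acov=acov,
    )


def _num_grad_jacobian(gradfun, theta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    k = len(theta)
    jac = np.empty((k, k))
    for i in range(k):
        h = eps * max(1.0, abs(theta[i]))
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        jac[:, i] = (gradfun(tp) - gradfun(tm)) / (2 * h)
    return jac


@dataclass
class FitIndexSet:
    """chi2 test plus incremental and information-theoretic indices."""

    chi2: float
    df: int
    p_value: float
    chi2_baseline: float
    df_baseline: int
    cfi: float
    tli: float | None
    aic: float
    aicc: float
    bic: float
    loglik: float
    k: int
    n: int

    def as_dict(self) -> dict:
        return {
            "K": self.k, "AICc": self.aicc, "AIC": self.aic, "BIC": self.bic,
            "CFI": self.cfi, "TLI": self.tli, "LL": self.loglik,
            "df": self.df, "chi2": self.chi2, "P": self.p_value,
        }


def fit_indices(fit: SemFit, baseline: SemFit | None = None) -> FitIndexSet:
    """Compute CFI/TLI against the independence baseline plus AIC/AICc/BIC.

    The baseline is the independence model (free variances only) on the
    same sample covariance; it is fitted automatically when not given.
    """
    if baseline is None:
        base_spec = independence_model(fit.spec.observed)
        baseline = fit_ml(
            base_spec, fit.sample_cov, fit.n, chi2_multiplier=fit.chi2_multiplier
        )
    if tuple(baseline.spec.observed) != tuple(fit.spec.observed):
        raise SemFitError("baseline must share the fitted model's observed set")

    chi2, df = fit.chi2, fit.df
    chi2_b, df_b = baseline.chi2, baseline.df
    return FitIndexSet(
        chi2=chi2, df=df, p_value=fit.p_value,
        chi2_baseline=chi2_b, df_baseline=df_b,
        cfi=cfi_index(chi2, df, chi2_b, df_b),
        tli=tli_index(chi2, df, chi2_b, df_b),
        aic=fit.aic, aicc=fit.aicc, bic=fit.bic,
        loglik=fit.loglik, k=fit.k, n=fit.n,
    )


def standardized_solution(fit: SemFit) -> pd.DataFrame:
    """Standardized coefficients, delta-method SEs, and R-squared.

    Each directed effect (and loading) is rescaled by
    SD(source)/SD(target) using model-implied variances; residual
    covariances by 1/(SD_a SD_b).  R-squared for each endogenous
    variable is 1 - residual variance / implied variance.
    """
    ram, theta = fit.ram, fit.theta

    def _std_vector(th: np.ndarray) -> np.ndarray:
        a, s = ram.fill(th)
        m = ram.dim
        b = linalg.inv(np.eye(m) - a)
        v = np.diag(b @ s @ b.T)
        if np.any(v <= 0):
            raise SemFitError("zero or negative implied variance")
        sd = np.sqrt(v)
        out = np.empty(len(th))
        for k, (mat, i, j) in enumerate(ram.theta_map):
            if mat == "A":  # effect of j on i
                out[k] = th[k] * sd[j] / sd[i]
            elif i == j:
                out[k] = th[k] / v[i]  # standardized residual variance
            else:
                out[k] = th[k] / (sd[i] * sd[j])
        return out

    std = _std_vector(theta)
    if fit.acov is not None:
        jac = np.empty((len(theta), len(theta)))
        for i in range(len(theta)):
            h = 1e-6 * max(1.0, abs(theta[i]))
            tp = theta.copy(); tp[i] += h
            tm = theta.copy(); tm[i] -= h
            jac[:, i] = (_std_vector(tp) - _std_vector(tm)) / (2 * h)
        std_se = np.sqrt(np.maximum(np.diag(jac @ fit.acov @ jac.T), 0.0))
    else:
        std_se = np.full_like(std, np.nan)

    tab = fit.parameter_table()
    tab["std_estimate"] = std
    tab["std_se"] = std_se
    tab["r_squared"] = np.nan

    # R^2 for endogenous variables (any incoming directed effect)
    a, s = ram.fill(theta)
    m = ram.dim
    b = linalg.inv(np.eye(m) - a)
    v = np.diag(b @ s @ b.T)
    endogenous = [i for i in range(m) if np.any(a[i, :] != 0)]
    r2 = {ram.names[i]: 1.0 - s[i, i] / v[i] for i in endogenous}
    for idx, row in tab.iterrows():
        if row["kind"] == "var" and row["lhs"] in r2:
            tab.loc[idx, "r_squared"] = r2[row["lhs"]]
    tab.attrs["r_squared"] = r2
    return tab
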