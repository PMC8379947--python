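# Methods

## Model and estimation

`xylemsem` fits covariance-structure models in RAM form. All variables
(observed and latent) index a directed-effects matrix A (paths and
loadings), a symmetric residual matrix S, and a selector F of observed
rows; the implied covariance is `F (I-A)^-1 S (I-A)^-T F^T`. Because the
shipped xylem model contains a feedback loop (capacitance → P_min →
density → capacitance), the inverse is used as-is rather than a
triangular substitution; the loop's implied covariance equals the limit
of iterated substitution whenever the loop gain is below 1 (tested
against a brute-force series), and fits report a warning-worthy
situation only through the singular-(I−A) diagnostic.

Estimation minimizes the normal-theory discrepancy
`F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p`. Internally the problem
is reparameterized to the correlation scale — each observed variable is
scaled to unit sample variance and each latent inherits its scale
indicator's factor. F_ML is exactly equivariant under this rescaling, so
the optimum maps back exactly; the payoff is conditioning that does not
depend on trait units (water potentials in MPa vs area proportions). The
optimizer is L-BFGS-B with an analytic gradient, followed by Newton
polishing to a gradient norm below 1e-10 so that closed-form cases
(saturated models, just-identified regressions) are met to 1e-8. Start
values: sample variances for free variances, 0 for paths, 1 for free
loadings. If the first start fails, the free loadings are sign-flipped
and a few seeded perturbed starts are tried — a free loading that must
cross zero while its indicator's error variance is pinned at zero walks
into a singular implied covariance, and a flipped start walks around it.

Free variances are estimated on the linear scale, so a negative
(Heywood) estimate is visible rather than hidden; the engine warns, and
`fix_heywood=True` applies the standard remedy of refitting with the
offending error variance fixed at zero. The shipped xylem models already
fix the fiber error variance to zero for exactly this reason. A log-
scale option (`variance_scale="log"`) enforces positivity when that is
preferred.

Standard errors come from the expected information
`(c/2) tr(Sigma^-1 dSigma_i Sigma^-1 dSigma_j)` computed on the
correlation scale and transformed back; standardized coefficients are
rescaled by model-implied standard deviations with delta-method SEs.
R-squared for an endogenous variable is one minus its residual variance
over its implied variance (well-defined for the nonrecursive block too).

## Test statistic and index conventions

`chi2 = c * F_ML` with c = n − 1 by default; c = n is a config switch
(`chi2_multiplier`), since both conventions circulate in SEM software
and the printed statistics of a given study pin the choice only when the
raw data are available. The log-likelihood is defined on the same scale,
`LL = LL_sat − chi2/2` with `LL_sat = −(c/2)(ln|S| + p)`, so the
identities `AIC = −2LL + 2K`, `BIC = −2LL + K ln n`, and
`chi2 = 2(LL_sat − LL)` hold exactly for every converged fit — the same
identities that make a published fit-statistic table internally
consistent row by row. CFI and TLI use the independence baseline
(df_b = p(p−1)/2, fitted by the same engine), AICc adds
`2K(K+1)/(n−K−1)` and is flagged unstable when n − K − 1 ≤ 1.

## Shipped models

The full model has 14 directed paths, a three-indicator cellular
trade-off latent (fiber scale loading fixed at 1, fiber error fixed at
0), one free residual covariance, and free residual variances — K = 26
against 45 moments (df = 19). The pruned model removes six paths (all
effects on efficiency except the safety-efficiency path, the two extra
effects on embolism resistance, and cellular trade-off → density),
giving K = 20, df = 25. The identity of the correlated-error pair is not
derivable from the main-text source; the shipped `cov(vessel,
parenchyma)` line is a placeholder chosen to keep K consistent and is
explicitly marked user-replaceable in `xylem_models.py`.

## Inference procedures

**Bollen–Stine bootstrap.** The data matrix is transformed by
`Z = X_c S^{-1/2} Sigma_hat^{1/2}` (symmetric PSD roots), which makes
the sample covariance of Z equal the fitted model's implied covariance
to machine precision — asserted on every call. Rows of Z are resampled
with replacement B times (default B = 1000; a seed is mandatory) and the
model refitted from the original solution; the p-value is the fraction
of bootstrap chi-squares at or above the observed one. Non-converged
replicates are excluded with a warning; more than 10% failures is an
error. The calibration test in the suite checks that these p-values are
uniform under a correctly specified model at n = 29; it runs on a small
three-variable chain (100 simulations, B = 99) because the same check
on the nine-trait model would cost two orders of magnitude more fitting
for the same statistical content.

**Pruning.** Backward elimination: remove the free path with the
largest Wald p above alpha (default 0.05), refit, and roll the removal
back if the chosen criterion (AICc by default; AIC/BIC available)
worsens by more than 2 — the conventional "difference > |2|" rule. Ties
on p are broken toward the path declared later in the model text, making
traces deterministic. Rolled-back paths are recorded as retained-despite-
nonsignificance. The trace never increases K and the final path set is a
subset of the initial one (asserted in tests).

**Reversal and reduced variants.** `reverse_path_test` flips one path's
direction (K and df unchanged) and refits — a materially worse
chi-square supports the original orientation. `drop_variable_variant`
removes an observed variable with its paths and variance entry;
removing a latent's indicator is refused below two indicators.

## Phylogenetic contrasts

Felsenstein's pruning algorithm: contrast `(x_i − x_j)/sqrt(b_i + b_j)`,
ancestral value the 1/b-weighted mean, ancestral branch extended by
`b_i b_j/(b_i + b_j)`. Unit branch lengths are the default convention
(every original branch set to 1 before the recursion). Polytomies are
resolved arbitrarily but deterministically with zero-length internal
branches (strict mode errors instead); zero-length cherries degrade to
an equal-branch limit. Contrast covariance is computed through the
origin with divisor n (contrasts have expected mean zero); a mean-
centered version exists for sensitivity. The effective sample size for
contrast-level fits is the contrast count, tips − 1 — this is also what
makes a 29-species AICc arithmetic move from n = 29 to n = 28 between
the raw and contrast blocks of a comparison table. The recursion is
cross-checked in the suite against `ape::pic` on a six-tip tree.

## Descriptive layer

Pearson correlations with t-distribution p-values (n − 2 df; through-
origin mode with n − 1 df for contrasts) and the conventional
significance tiers (0.001/0.01/0.05/0.10). Strength centrality is the
sum of |r| to all other traits over all edges — matching the idea of
ranking a trait by how strongly it correlates with everything else — and
a significant-edges-only variant is a flag. PCA is an
eigendecomposition of the correlation matrix (covariance optional) with
the sign convention that each component's largest-magnitude loading is
positive. Variance partitioning fits the two-level nested random-effects
model (site, species within site, residual) by REML via statsmodels
MixedLM, with a method-of-moments nested-ANOVA estimator as the
balanced-design route; the two agree closely on balanced data and the
MoM route is what the Monte-Carlo calibration loops use, since it is
orders of magnitude faster at identical answers there. Negative
component estimates are truncated at zero; a single site makes the site
component structurally zero, flagged.

## Synthetic data

The generator draws species means multivariate-normal from the
covariance implied by a population path model through the same RAM
identity the engine uses (asserted identical to 1e-12). The default
population is the 14-path xylem topology with standardized-scale
coefficients of magnitude 0.2–0.7, residual variances 0.5, and a small
vessel-parenchyma error covariance — moderate, realistic effect sizes
for interspecific trait networks; trait means are plausible
transformed-scale values for chaparral shrubs and are cosmetic (the
covariance carries the model). Defaults mirror the emulated study
design: 29 species, 4 sites, 6 replicate stems per species. Replicate
tables add site effects and intraspecific noise additively on the
transformed scale. Trees are pure-birth (Yule) topologies with
multivariate Brownian tip traits at a specified per-unit-time
covariance. Every generator is a pure function of (config, seed).

What the generator does not emulate: non-normal trait distributions,
missing cells, unbalanced replication, measurement error distinct from
intraspecific variation, and non-Brownian evolution. Tests passing on
these data therefore demonstrate the correctness and calibration of the
machinery under the model's own assumptions, not robustness of the
scientific conclusions to violations of them.

## Problem sizes and numerical choices

Monte-Carlo studies in the suite and acceptance script use: parameter
recovery with 200 replicates at n = 2000 (bias within 3 Monte-Carlo SEs,
95% Wald coverage within [0.91, 0.98] per parameter); true-zero-path
pruning over 100 seeded runs at n = 500 (≥ 90% removal); balanced
variance-component recovery over 200 seeds of a 10 × 10 × 6 design
(mean within 10%); bootstrap-calibration with 100 simulations at B = 99.
These sizes give binomial/Monte-Carlo error comfortably inside the
asserted tolerances while keeping the default test run quick.
Convergence is declared below gradient norm 1e-6 (achieved ~1e-10 after
polishing); non-PD implied covariances during line search are handled by
a large finite penalty; sample covariances must be symmetric positive
definite on input.

## Known limitations

No mean structures, multi-group models, robust/categorical estimators,
or modification indices. Pruning is backward-only (no forward
selection, no model averaging). PGLS and branch-length estimation are
out of scope for the contrasts arm. The Bollen–Stine p-values are
stochastic quantities: reproducible under a fixed seed, but not numeric
targets. AICc model ranking at K close to n is dominated by the
correction term and is flagged rather than suppressed.
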