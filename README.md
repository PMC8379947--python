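# xylemsem

Structural equation modeling of xylem trait trade-offs.

Plant xylem must transport water, support the stem mechanically, and
store water and carbohydrates. These functions are carried by different
cell types (vessels, fibers, parenchyma), so trade-offs among them are
rooted in how cross-sectional area is allocated — and the minimum
seasonal water potential a species experiences (P_min) places a
mechanical strain that touches nearly every trait. `xylemsem` implements
the complete multivariate inference pipeline for testing such hypotheses
on species-level trait tables: latent-variable path models fitted by
maximum likelihood, small-sample bootstrap model tests, information-
criterion model selection, a phylogenetic-contrast arm, and the
descriptive trait-network layer. A synthetic-data generator makes every
stage testable without field data.

## The model

A path model over nine traits — P_min, embolism resistance (P75),
xylem-specific conductivity (K_s), capacitance, starch content, xylem
density, and the fiber/vessel/parenchyma area proportions — is held in
RAM form and its implied covariance is

    Sigma(theta) = F (I - A)^-1 S (I - A)^-T F^T

where A collects directed effects and factor loadings, S residual
(co)variances, and F selects the observed rows. The "cellular trade-off"
latent is measured by the three cell-type proportions (fiber carries the
scale; its error variance is fixed to zero, the standard remedy for a
small negative error estimate). The model is nonrecursive: capacitance →
P_min → density → capacitance forms a feedback loop, which the matrix
inverse handles directly. Parameters minimize the normal-theory
discrepancy

    F_ML = ln|Sigma| + tr(S_sample Sigma^-1) - ln|S_sample| - p

with chi2 = (n-1) F_ML at the minimum (an n convention is available),
CFI/TLI against the independence baseline, AIC = -2LL + 2K,
BIC = -2LL + K ln n, and the small-sample AICc = AIC + 2K(K+1)/(n-K-1).
Around a single fit the package provides the Bollen–Stine bootstrap
(data transformed to satisfy the fitted model exactly, then resampled),
backward path pruning with an information-criterion guard, path-reversal
sensitivity tests, and model variants with a variable removed.
Felsenstein independent contrasts (unit branch lengths, covariance
through the origin, effective n = tips − 1) feed the same machinery for
the phylogenetic arm.

## Worked example

```sh
python examples/fit_path_model.py
```

```
K = 26 free parameters, df = 19
chi2 = 15.29, P = 0.704
CFI = 1.000, TLI = 1.065
AIC = 34.64, AICc = 736.64, BIC = 70.19
```

The 14-path model has K = 26 free parameters against 45 observed
moments (df = 19). On this synthetic 29-species draw the chi-square is
non-significant (P = 0.704): the hypothesized structure is statistically
indistinguishable from the saturated model. The huge AICc reflects the
small-sample penalty at n = 29 with K = 26 — exactly why pruning
matters:

```sh
python examples/prune_and_compare.py
```

```
 model  K    AICc    AIC    BIC  CFI   TLI  df   chi2     P
  full 26 736.642 34.642 70.191  1.0 1.065  19 15.292 0.704
pruned 18  95.397 26.997 51.608  1.0 1.042  27 23.647 0.650
```

Pruning non-significant paths drops AICc by > 600 while the chi-square
test stays comfortably non-significant — the pruned model fits as well
and is far more parsimonious. The other examples cover the bootstrap
test (`bootstrap_test.py`), the contrasts arm
(`phylogenetic_contrasts.py`), and the descriptive layer
(`describe_trait_network.py`). A thin CLI wraps the same calls
(`xylemsem --help`; verbs: `validate`, `report`, `fit`, `prune`,
`bootstrap`, `pic`, `describe`, `simulate`).

## Layout

- `src/xylemsem/model.py` — model-text grammar, `ModelSpec`, RAM matrices
- `src/xylemsem/fit.py` — ML fitting, standard errors, standardized
  solution, fit indices
- `src/xylemsem/inference.py` — bootstrap, pruning, comparison, reversal
- `src/xylemsem/phylo.py` — Newick input, independent contrasts
- `src/xylemsem/descriptive.py` — correlations, strength, PCA, variance
  components
- `src/xylemsem/simulate.py` — synthetic species tables, replicate
  tables, trees with Brownian traits, recovery reports
- `src/xylemsem/traits.py` — trait table I/O, transforms, derived traits
- `src/xylemsem/xylem_models.py` — the shipped full and pruned models
- `src/xylemsem/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — modeling choices, defaults, and limitations
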