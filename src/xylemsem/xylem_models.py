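"""Shipped path models for the nine xylem traits.

Variable names
--------------
pmin          minimum seasonal (midday) water potential, |MPa| after transform
p75           embolism resistance (water potential at 75% loss of K_h), |MPa|
ks            xylem-specific conductivity (transport efficiency)
capacitance   water storage: slope of RWC vs water potential
starch        xylem starch content (% dry mass)
density       xylem density (tissue strength proxy)
fiber, vessel, parenchyma
              cross-sectional area proportions of the three cell types

``CT`` is the latent "cellular trade-off" axis measured by the three
cell-type proportions.  Fiber carries the latent's scale (loading fixed
to 1) and its error variance is fixed to zero — estimating it freely
yields a small negative (Heywood) value on these traits.  Tissue
strength enters as the observed xylem density, not as a latent.

The model is nonrecursive: capacitance -> pmin -> density ->
capacitance forms a feedback loop, so the implied covariance uses the
full (I-A)^-1 RAM identity.

One residual covariance is free in both models so that the full model
has K = 26 (df = 19) and the pruned model K = 20 (df = 25) on the
9-variable moment count of 45.  The shipped pair (vessel ~~ parenchyma
indicator errors) is a placeholder: the published source for the pair is
supplementary material, and users with that information should replace
the ``cov(...)`` line.
"""

from .model import ModelSpec, parse_model_spec

__all__ = [
    "FULL_MODEL_TEXT",
    "BEST_MODEL_TEXT",
    "PRUNED_PATHS",
    "full_model",
    "best_model",
    "TRAIT_NAMES",
]

TRAIT_NAMES = (
    "pmin", "p75", "ks", "capacitance", "starch",
    "density", "fiber", "vessel", "parenchyma",
)

FULL_MODEL_TEXT = """\
# cellular trade-off latent: fiber sets the scale, fiber error fixed to zero
CT ~ fiber + vessel + parenchyma
var(fiber) = 0

# structural paths (14 directed effects)
pmin <- capacitance
p75 <- pmin + density + CT
ks <- pmin + p75 + density + CT
CT <- pmin
density <- pmin + CT
starch <- pmin + CT
capacitance <- density

# placeholder correlated-error pair; replace with the study's pair if known
cov(vessel, parenchyma) = free
"""

# The six paths dropped from the full model: all effects on efficiency other
# than the safety-efficiency path, both extra effects on embolism resistance,
# and the cellular-trade-off -> strength path.
PRUNED_PATHS = (
    ("CT", "ks"),
    ("pmin", "ks"),
    ("density", "ks"),
    ("CT", "p75"),
    ("density", "p75"),
    ("CT", "density"),
)

BEST_MODEL_TEXT = """\
CT ~ fiber + vessel + parenchyma
var(fiber) = 0

# pruned structural paths (8 directed effects)
pmin <- capacitance
p75 <- pmin
ks <- p75
CT <- pmin
density <- pmin
starch <- pmin + CT
capacitance <- density

cov(vessel, parenchyma) = free
"""


def full_model() -> ModelSpec:
    """The hypothesized 14-path model (K = 26, df = 19)."""
    return parse_model_spec(FULL_MODEL_TEXT)


def best_model() -> ModelSpec:
    """The full model minus the six weakly supported paths (K = 20, df = 25)."""
    return parse_model_spec(BEST_MODEL_TEXT)
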