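"""Descriptive layer: correlation network, hub traits, PCA, and
variance partitioning.

Strength centrality (sum of |r| to all other traits) identifies "hub"
traits; the PCA scree says how many axes carry the multivariate
structure; nested variance components split each trait's variation into
site, species-within-site, and within-species (intraspecific) shares.
"""

from xylemsem import (
    SimConfig,
    correlation_matrix,
    network_strength,
    pca_summary,
    simulate_from_sem,
    simulate_replicates,
    variance_components,
)

cfg = SimConfig(seed=1)
table = simulate_from_sem(cfg)

corr = correlation_matrix(table)
strength = network_strength(corr)
print("strength ranking (hub traits first):")
print(strength.round(2).to_string())

pca = pca_summary(table)
frac = pca["variance_fraction"]
print(f"\nPC1 + PC2 explain {100 * (frac['PC1'] + frac['PC2']):.1f}% "
      "of standardized trait variance")

reps = simulate_replicates(table, cfg)
print("\nvariance partitioning (proportions):")
for vc in variance_components(reps, traits=["density", "ks"], method="anova"):
    p = vc.proportions
    print(f"  {vc.trait}: site {p['site']:.2f}, species {p['species_within_site']:.2f}, "
          f"intraspecific {p['intraspecific']:.2f}")
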