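"""Cophylogeny testing with PACo and Parafit.

Cospeciating OTU clades are planted so that their subtree mirrors a host
clade; both tests should find the host and microbe phylogenies more
congruent (through the association matrix) than the quasiswap /
column-permutation nulls allow.
"""

import phylosym as ps
from phylosym.pipeline import species_association
from phylosym.predictors import patristic_distance

config = ps.SimulationConfig(
    n_species=40, extra_sample_mean=0.0, n_heritable=0, n_diet_guild=0,
    n_cospeciating=18, n_consortium=0, n_noise=42,
    noise_p_range=(0.05, 0.3), depth=1000, seed=6)
ds = ps.simulate_dataset(config)

filtered = ps.filter_by_prevalence(ds.table, 0.05)
association = species_association(filtered.presence().astype(int),
                                  ds.metadata)
species_tree = ds.host_tree.shear(list(association.index))
host_d = patristic_distance(species_tree)
microbe_d = patristic_distance(ds.microbe_tree.shear(list(association.columns)))

paco = ps.paco(host_d, microbe_d, association, n_perm=999, seed=7)
parafit = ps.parafit(host_d, microbe_d, association, n_perm=999, seed=7)

print(f"association matrix: {association.shape[0]} hosts x "
      f"{association.shape[1]} OTUs, {int(association.to_numpy().sum())} links")
print(f"PACo: m2 = {paco.m2:.4g}, p = {paco.p:.4f}")
print(f"Parafit: statistic = {parafit.statistic:.4g}, p = {parafit.p:.4f}")

cospec = paco.residuals.index.get_level_values("symbiont").str.startswith("cospec")
print(f"median Procrustes residual, cospeciating links: "
      f"{paco.residuals[cospec].median():.1f}")
print(f"median Procrustes residual, other links:        "
      f"{paco.residuals[~cospec].median():.1f}")

# Small p-values mean the host-microbe association carries phylogenetic
# congruence; cospeciating links should show smaller residuals (better
# Procrustes fit) than background links.
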