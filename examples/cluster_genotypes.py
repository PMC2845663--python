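"""Nonparametric clustering of multilocus genotypes with gap-statistic K.

Builds allele-sharing distances between non-redundant MLGs, contrasts
within-stand and between-stand distances, clusters the genotypes and asks
the gap statistic how many clusters the region supports.
"""

import numpy as np

from standscape import clustering, core, simulate

cfg = simulate.SimConfig(
    n_stands=10, capacity=12, n_markers=250, founders_per_stand=2,
    t=0.02, generations=10, migration_rate=0.1, seed=4,
)
dataset = simulate.simulate(cfg)
table = dataset.table
mlgs = core.identify_mlgs(table)
nr_calls, labels, stand_ids = clustering.nonredundant_mlg_table(table, mlgs)
print(f"{nr_calls.shape[0]} non-redundant genotypes from "
      f"{len(set(stand_ids))} stands")

d = clustering.allele_sharing_matrix(nr_calls)
within, between, comp = clustering.within_between_distributions(d, stand_ids)
print(f"mean distance within stands {comp.means[0]:.3f} "
      f"vs between stands {comp.means[1]:.3f} "
      f"(rank-sum p = {comp.p_value:.2g})")

dend = clustering.cluster_genotypes(d, labels)
print(f"\ndendrogram (newick, truncated): {dend.to_newick()[:90]}...")

gap = clustering.gap_statistic(nr_calls, k_max=6, b_reference=50, seed=0)
print(f"gap statistic chooses K = {gap.k_hat}")
print("gap(K):", np.round(gap.gaps, 2))
print("\nGenotypes from the same stand are far more similar than genotypes")
print("from different stands - strong local differentiation under selfing.")
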