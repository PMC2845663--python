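"""Between-stand spatial structure: Mantel test, Moran's I correlogram,
D_G distogram and the aggregation index.

Simulates a region where nearby stands exchange rare migrants, then asks at
what distance genotypes stop resembling their neighbors.
"""

import numpy as np
from scipy.spatial.distance import pdist, squareform

from standscape import clustering, simulate, spatial

cfg = simulate.SimConfig(
    n_stands=15, capacity=12, n_markers=120, founders_per_stand=3,
    t=0.02, generations=12, migration_rate=0.3, region_extent=8000.0,
    seed=11,
)
dataset = simulate.simulate(cfg)
table = dataset.table
# plant coordinates: stand location plus the plant's within-stand position
coord = {s.stand_id: (s.x, s.y) for s in dataset.stands}
coords = np.array(
    [
        np.add(coord[table.meta["stand_id"].iloc[i]],
               dataset.positions[table.sample_ids[i]])
        for i in range(table.n_samples)
    ]
)

d_gen = clustering.allele_sharing_matrix(table.calls)
d_geo = squareform(pdist(coords))
mantel = spatial.mantel_test(d_gen, d_geo, n_perms=499, seed=0)
print(f"Mantel r = {mantel.r:.3f}, one-sided p = {mantel.p_value:.3f} "
      f"({mantel.n_permutations} permutations)")

spec = spatial.DistanceClassSpec(n_classes=10, class_width_km=1.0)
cor = spatial.morans_i_correlogram(table.calls, coords, spec,
                                   n_perms=199, seed=0)
dg = spatial.dg_distogram(table.calls, coords, spec, n_perms=199, seed=0)
print()
print(f"{'class km':>9} {'pairs':>6} {'I':>7} {'sig':>4} {'D_G':>6}")
for c in range(spec.n_classes):
    if np.isnan(cor.values[c]):
        continue
    print(f"<= {cor.class_upper_km[c]:4.1f}  {cor.n_pairs[c]:>6} "
          f"{cor.values[c]:7.3f} {'*' if cor.significant[c] else ' ':>4} "
          f"{dg.values[c]:6.3f}")

agg = spatial.aggregation_index(coords, area=cfg.region_extent**2,
                                n_sims=199, seed=0)
print()
print(f"aggregation index R = {agg.r:.3f} (p = {agg.p_value:.3f}); "
      "R < 1 means plants of like genotype clump in space")
print("Positive Moran's I (and depressed D_G) in the shortest classes that")
print("exceeds the permutation envelope (*) is fine-scale spatial structure.")
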