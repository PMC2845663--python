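"""Footprints of outcrossing and recombination in dense SNP genotypes.

Four scans on simulated data with known truth: heterozygous stretches
(recent outcrossing), F1 parent assignment, pairwise identity/divergence
mosaic blocks, and reconstruction of a natural recombinant-inbred stand.
"""

import numpy as np

from standscape import core, mosaic, simulate

# --- a stand with a pulse of outcrossing in the final season -------------
cfg = simulate.SimConfig(
    n_stands=1, capacity=20, n_markers=200, founders_per_stand=4,
    t=0.0, t_schedule=[0] * 7 + [0.3], generations=8,
    mating_kernel_sigma=np.inf, seed=2,
)
dataset = simulate.simulate(cfg)
table = dataset.table
mlgs = core.identify_mlgs(table)
candidates = {m: g for m, g in mlgs.canonical.items() if not np.any(g == 1)}

print("heterozygous stretches and F1 calls")
for i, sid in enumerate(table.sample_ids):
    stretches, frac = mosaic.detect_het_stretches(
        table.calls[i], table.marker_map, sample_id=sid
    )
    if not stretches:
        continue
    call = mosaic.assign_f1_parents(table.calls[i], candidates, child_id=sid)
    print(f"  {sid}: {len(stretches)} stretch(es), het fraction {frac:.2f}, "
          f"verdict {call.verdict} "
          f"({call.parent_a} x {call.parent_b}, "
          f"het at {call.fraction_heterozygous:.0%} of "
          f"{call.n_differentiating} differentiating markers)")

# --- mosaic blocks between two recombinant relatives ---------------------
ril_table, truth = simulate.make_ril_stand(n_lines=4, n_markers=120,
                                           n_meioses=2, seed=5)
mm = truth["marker_map"]
prof = mosaic.pairwise_profile(ril_table.calls[2], ril_table.calls[3], mm,
                               "ril1", "ril2")
blocks = mosaic.segment_blocks(prof, min_run=3)
print("\nmosaic blocks between two recombinant lines (ril1 vs ril2)")
for b in blocks:
    print(f"  chr{b.chromosome} markers {b.first_index}-{b.last_index} "
          f"({b.bp_start/1e6:.1f}-{b.bp_end/1e6:.1f} Mb): {b.state}")

# --- natural-RIL reconstruction ------------------------------------------
stand_mlgs = {sid: ril_table.calls[i] for i, sid in enumerate(ril_table.sample_ids)}
rec = mosaic.reconstruct_ril(stand_mlgs, mm)
print(f"\nRIL reconstruction: founders {rec.founder_a} x {rec.founder_b}, "
      f"{rec.total_unexplained} unexplained markers")
for sid in sorted(rec.breakpoints):
    print(f"  {sid}: {rec.breakpoints[sid]} breakpoint(s)")
print("\nAlternating identity/divergence blocks and fully-explained paintings")
print("are the signature of past outcrossing followed by selfing.")
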