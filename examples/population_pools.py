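"""A cell population splits into pools with different L1 levels.

Simulates a scaled-down population (150 cells) near the bifurcation
(k_r = 190), where stochastic extinction of Alu is common.  Cells split
into pool 1 (both elements active, L1 near 500 copies), pool 2 (Alu
extinct, L1 near V*(200-k_r) = 5000 copies) and pool 3 (all replication
stopped), visible in the Kaplan-Meier survival curves and the bimodal
distribution of time-averaged L1.
"""

import warnings

import numpy as np

import retrodyn as rd
from retrodyn.stats import kaplan_meier, summarize_pools, time_averaged_distribution

params = rd.default_parameters("ribosome").with_updates(k_r=190.0)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    ens = rd.simulate_population(params, 150, 500, 100, [250, 250, 100], 11)

print(f"retained {ens.n_cells}/{ens.n_requested} cells "
      f"({ens.n_excluded} lost all active elements in the 100-generation buffer)")

F_L = kaplan_meier(ens, "L1")
F_S = kaplan_meier(ens, "Alu")
for g in (101, 200, 300, 400, 500):
    print(f"  generation {g}: F_L1 = {F_L.at(g):.3f}   F_Alu = {F_S.at(g):.3f}")
print("Active Alu disappears from almost every cell while L1 survives:")
print("the gap between the two curves is the growing pool 2.")

avg = time_averaged_distribution(ens, (101, 400), "L")
near_500 = int((np.abs(avg - 500) < 125).sum())
near_5000 = int((np.abs(avg - 5000) < 1250).sum())
print(f"\ntime-averaged L over generations 101-400 ({avg.size} cells):")
print(f"  {near_500} cells within 25% of the coexistence attractor (500 copies)")
print(f"  {near_5000} cells within 25% of the Alu-free attractor (5000 copies)")
print("  the rest are in transit between the two attractors")

pools = summarize_pools(ens, (101, 500))
print("\nper-pool summary (mean copies / coefficient of variation):")
for _, row in pools.iterrows():
    if row.n_cells:
        print(f"  pool {row.pool} {row.species}: mean={row['mean']:8.1f} "
              f"cv={row.cv:.3f}  ({row.n_cells} cells)")
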