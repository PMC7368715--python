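"""Rank reference genes on a qPCR Ct panel with the four stability algorithms.

Simulates the package's reference design (12 genes x 39 samples, technical
triplicates collapsed by mean, one planted noisy gene) and runs geNorm,
NormFinder (grouped by cohort), BestKeeper and the comparative delta-Ct
method.  Lower values always mean more stable.
"""

import pandas as pd

from refstab import (
    ct_to_quantity,
    default_ct_spec,
    genorm,
    run_all,
    simulate_ct,
)

sim = simulate_ct(default_ct_spec(seed=3))
print(f"panel: {sim.ct.shape[0]} genes x {sim.ct.shape[1]} samples, "
      f"{sim.ct.replicate_depth} technical replicates collapsed")

series = run_all(sim.ct, sim.design, "cohort")
table = pd.DataFrame({s.algorithm: s.values for s in series})
table["truth_sd"] = sim.truth["noise_sd"]
print(table.round(3).sort_values("deltaCt"))

# geNorm also reports how many reference genes a normalization factor needs:
g = genorm(ct_to_quantity(sim.ct))
print("\ngeNorm pairwise variation (V_n < 0.15 means n genes suffice):")
print(g.pairwise_variation.head(4).round(3))

# Genes are listed most-stable first; the planted 1.0-cycle-SD gene (largest
# truth_sd) lands at the bottom of every column.
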