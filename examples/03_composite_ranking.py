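"""Aggregate several stability algorithms into one composite ranking.

The four algorithms report on incommensurate scales, so each column is
min-max standardized to [0, 1] and averaged into a final score FS (lower =
more stable).  A geometric-mean-of-ranks score (the RefFinder convention)
is shown side by side: rank-based aggregation flattens the real spacing
between genes, which is exactly what the composite score avoids.
"""

from refstab import comparison_table, comprfinder, default_ct_spec, run_all, simulate_ct

sim = simulate_ct(default_ct_spec(seed=3))
series = run_all(sim.ct, sim.design, "cohort")

result = comprfinder(series)
print("standardized columns span [0,1]:")
print(result.standardized.round(3).head(4))
print("\nfinal scores (FS = mean of standardized values):")
print(comparison_table(series).round(3))

# FS 0 would be a gene that is the most stable under every algorithm; the
# planted noisy gene scores near 1. The reffinder columns show where the
# two aggregation conventions disagree.
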