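# refstab

Reference-gene (housekeeping-gene) selection and validation for qPCR,
from transcriptome-wide screening to composite stability ranking.

Relative quantification by qRT-PCR divides every target-gene measurement by
a reference-gene signal, so an unstable reference silently distorts every
result built on it. `refstab` implements the complete selection workflow
used in livestock and other non-model-organism studies:

1. **Screening** — from an RNA-seq FPKM matrix, score every gene by mean
   expression, coefficient of variation (CV% = 100·SD/mean), maximum fold
   change (MFC = max/min), and the dispersion measure DPM derived from the
   per-sample specificity measure SPM_i = x_i²/Σx_j² (DPM = SD(SPM)·√n,
   0 for a uniform gene, 1 for a one-hot gene). Candidates are the
   intersection of the four thresholded sets (defaults: FPKM ≥ 10,
   CV ≤ 20%, DPM < 0.2, MFC < 2.5).
2. **Stability ranking** — four published algorithms on Ct panels, all
   reimplemented from their definitions and checked against naive-loop
   oracles: geNorm (M value = mean SD of pairwise log₂ quantity ratios,
   with stepwise exclusion and the V_n/V_{n+1} pairwise variations),
   NormFinder (model-based intra/intergroup variance decomposition),
   BestKeeper (mean absolute deviation of raw Ct about the central Ct,
   plus correlation with the per-sample geometric-mean index), and the
   comparative ΔCt method (mean pairwise ΔCt SD).
3. **Composite ranking** — each algorithm's column is min–max standardized,
   A'_i = (A_i − A_min)/(A_max − A_min), and averaged into a final score
   FS_i = ΣA'_i/n (lower = more stable). Unlike geometric-mean-of-ranks
   aggregation (also provided for comparison), the composite score
   preserves the real spacing between genes and is invariant to each
   algorithm's arbitrary scale.
4. **Normalization & validation** — multi-gene normalization factors
   (geometric mean Ct), 2^−ΔCt relative expression, paired stage tests,
   correlation between competing normalization schemes, and amplification
   efficiency from dilution-series standard curves
   (E% = 100·(10^(−1/slope) − 1)).
5. **Synthetic data** — seeded Ct/FPKM generators with planted stability
   structure, so every stage is benchmarked against known ground truth.

## Worked example

```python
import pandas as pd
from refstab import simulate_ct, default_ct_spec, run_all, comprfinder

sim = simulate_ct(default_ct_spec(seed=3))          # 12 genes x 39 samples
series = run_all(sim.ct, sim.design, "cohort")      # the four algorithms
table = pd.DataFrame({s.algorithm: s.values for s in series})
table["truth_sd"] = sim.truth["noise_sd"]           # planted noise, cycles
print(table.round(3))
print(comprfinder(series).final_score.round(3))
```

prints (abridged):

```
       geNorm  NormFinder  BestKeeper  deltaCt  truth_sd
HKG01   0.292       0.024       0.084    0.292      0.10
HKG02   0.305       0.042       0.098    0.305      0.12
...
HKG11   0.411       0.087       0.232    0.411      0.30
HKG12   0.952       0.296       0.714    0.952      1.00

FS: HKG01 0.000, HKG02 0.031, ..., HKG11 0.206, HKG12 1.000
```

Each column is one algorithm's stability value (lower = more stable);
`truth_sd` is the planted per-gene noise SD in cycles. The planted
1.0-cycle gene (HKG12) is ranked last by every algorithm and takes the
worst composite score FS = 1.0, while the quietest gene anchors FS = 0.
With default base E = 2 the geNorm full-panel M and the ΔCt-method value
coincide exactly — SDs of log₂ quantity ratios are SDs of Ct differences —
which is a useful cross-check, not an error.

The `examples/` directory holds one narrative script per capability
(screening, stability ranking, composite aggregation, normalization and
validation); each prints its numbers with a closing note on how to read
them. A thin CLI mirrors the library:
`refstab screen|stability|aggregate|normalize|validate|simulate|run`.

## Data availability

The value-level reproduction tests expect the originating study's
goat-skin 12-gene Ct panel (per-sample mean Ct of the 12 candidate
reference genes over 39 skin samples, not redistributable here) as wide
TSV at `data/supplementary/goat_skin_ct_panel.tsv`, plus a
sample/factor/level table at `data/supplementary/goat_skin_groups.tsv`
whose `group` factor assigns every sample its experimental group. The
underlying RNA-seq dataset is public but is not needed for any test.
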