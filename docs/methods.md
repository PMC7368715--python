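# Methods

This note records the models implemented, the numerical choices made where
the published descriptions are ambiguous, what the synthetic-data generator
does and does not emulate, and the known limitations. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Screening metrics

For a gene with FPKM vector x over n ≥ 2 samples:

- mean FPKM, and CV% = 100 · s/mean with the *sample* SD (n−1 denominator);
  the n−1 choice is ours — descriptions of the workflow do not specify the
  denominator, and with n around 39 the difference is ~1%.
- MFC = max(x)/min(x). When min(x) = 0 the fold change is undefined and the
  gene is excluded from the MFC criterion rather than treated as infinite;
  under the default prefilter (drop genes with any zero sample) the case
  cannot arise anyway.
- SPM_i = x_i²/Σ_j x_j² (a unit vector of squared shares, Σ SPM_i = 1), and
  DPM = sample-SD(SPM) · √n. This maps a constant nonzero gene to exactly 0
  and a one-hot gene to exactly 1 for every n ≥ 2, which is the property
  the screening thresholds rely on; the implementation keeps a hook for
  alternative normalizations should a different dispersion convention be
  needed.
- Threshold strictness follows the conventional phrasing: FPKM and CV
  inclusive (≥ 10, ≤ 20%), DPM and MFC strict (< 0.2, < 2.5). An optional
  percentile rule (e.g. the 80th percentile of mean FPKM) can replace the
  absolute FPKM cut-off; the absolute rule is the default.
- Zero policy: the default `any-zero` drops genes with a zero in any
  sample, because a credible housekeeping gene is never off; `all-zero`
  retains them and is provided because real pipelines differ.

All four metrics are invariant under positive scaling of a gene's vector;
the intersection step is plain set intersection, so tightening a threshold
can only shrink the candidate set (both properties are tested).

## Relative quantities

Ct panels enter geNorm and NormFinder as anchored relative quantities
Q = E^(Ct_min,gene − Ct) with E = 2 by default (per-gene efficiencies from
dilution series may be substituted; values outside [1.6, 2.1] are
rejected as implausible per-cycle amplification). The anchor makes
max Q = 1 per gene and cancels in every ratio, so geNorm results are
invariant to per-gene Ct offsets. With E = 2 for all genes, the SD of a
log₂ quantity ratio equals the SD of the corresponding Ct difference, so
the full-panel geNorm M equals the ΔCt-method value exactly; the two
algorithms still differ in their rankings' tails because geNorm recomputes
M after each exclusion.

## geNorm

V_jk = SD over samples of log₂(Q_j/Q_k) (n−1 denominator throughout);
M_j = mean over k ≠ j. The highest-M gene is excluded (ties broken by gene
id, descending, for determinism) and M recomputed until two genes remain.
Ranking follows the exclusion order; because geNorm cannot discriminate
the final pair, those two genes are ordered by their M at the three-gene
stage so downstream rank aggregation receives distinct ranks 1 and 2.
NF_n is the per-sample geometric mean of the top-n genes' quantities and
V_n = SD over samples of log₂(NF_n/NF_{n+1}) for n = 2..G−1; V_n < 0.15 is
the customary "n genes suffice" cut-off.

## NormFinder

On y = log₂ Q, per group g with n_g samples and k ≥ 3 genes:

- two-way residuals r_igj = y_igj − ȳ_ig· − ȳ_·gj + ȳ_··g give
  s_ig = Σ_j r²/(n_g−1);
- solving E[s_i] = (1−2/k)σ_i² + (1/k²)Σσ_l² yields the bias-corrected
  intragroup variances σ̂²_ig = k/(k−2) · (s_ig − Σ_l s_lg/(k(k−1))),
  truncated at 0 (truncations are flagged in the output);
- intergroup deviations d_ig = (ȳ_ig· − ȳ_i··) centred to sum to zero over
  genes within each group; their dispersion γ² is estimated by moments
  (variance of d̂ minus the mean sampling variance σ̂²/n_g, truncated at
  0) and each deviation shrunk by γ²/(γ² + σ̂²_ig/n_g);
- stability = mean over groups of |d̃_ig| + √(σ̂²_ig/n_g); lower = more
  stable. Ungrouped panels get the bias-corrected model variance of each
  gene's deviation from the per-sample mean profile.

Published NormFinder front-ends differ in scaling and options, so
agreement with any particular implementation is expected at rank level,
not value level; the tests check exact (1e-9) agreement with an
independent naive-loop transcription of the estimators above.

## BestKeeper

Descriptive statistics on raw Ct. The stability value is the mean absolute
deviation of Ct about the central Ct, in cycles; centring is the
arithmetic mean by default with geometric-mean centring selectable, since
published descriptions admit both readings and they differ only in the
third decimal on realistic panels (both are tested against hand-computed
values). CV% = 100 · MAD/arithmetic mean. The BestKeeper index is the
per-sample geometric mean of all genes' Ct; each gene's Pearson r against
the index carries a two-sided p from the t transform. MAD ≤ sample SD
always (tested), so BestKeeper values are systematically smaller than
ΔCt-method values on the same data.

## Comparative ΔCt method

stability_j = mean over partners k ≠ j of SD over samples of
(Ct_j − Ct_k). Per-sample Ct offsets (loading differences) cancel in the
pairwise differences (tested). Under independent per-gene noise the
expected pair SD is √(σ_j² + σ_k²); the seeded benchmark checks
convergence at 200 samples.

## Composite final score

Given n ≥ 2 algorithms' columns, all oriented lower-is-stable:
Δ_A = A_max − A_min, A'_i = (A_i − A_min)/Δ_A, FS_i = mean of the
standardized values; genes ranked by ascending FS with lexicographic
tie-break. Decisions the published description leaves open:

- constant column (Δ_A = 0): all standardized values set to 0 and the
  column flagged — a non-discriminating algorithm should not separate
  genes;
- a gene missing from some series is dropped from the aggregation with a
  warning (strict mode raises instead), since the FS average assumes
  complete rows;
- n is however many series are supplied, not hard-coded to four.

Min–max standardization is invariant under strictly increasing affine
transforms of a column, so FS and the ranking are unaffected by each
algorithm's scale (property-tested). The geometric-mean-of-ranks
comparator converts each column to average ranks (ties averaged) before
taking the geometric mean; when all columns order genes identically the
two conventions give the same final ordering (tested).

## Normalization and validation

- NF per sample is the geometric mean of the member genes' Ct
  (`nf_mode="ct-geomean"`, the default, matching the workflow's stated
  convention). The alternative `quantity-geomean` takes the geometric mean
  of 2^−Ct, i.e. the arithmetic mean Ct. Only the latter is *exactly*
  invariant under a global Ct offset; in the usual 20–30-cycle range the
  two differ by well under 0.1 cycle (AM–GM gap), and the test suite
  asserts exact invariance for the quantity mode and sub-percent
  near-invariance for the Ct mode.
- Relative expression = 2^−(Ct_target − NF); adding one cycle to the
  target halves every value (tested).
- Stage comparisons use the classical paired t-test on relative expression
  of the same subjects across two levels, two-sided, with significance
  stars at 0.05 (*) and 0.01 (**); identical pairs return t = 0, p = 1 by
  convention. No multiple-testing correction is applied, matching the
  validation practice the workflow mirrors.
- Scheme correlation pools all targets × samples into one vector per
  scheme (per-target correlation available) and reports Pearson r with
  two-sided p; unadjusted.
- Efficiency: least-squares slope of Ct on log₁₀ input;
  E% = 100·(10^(−1/slope) − 1); slope ≥ 0 is rejected as non-amplifying.
  ≥ 3 points required.

## Missing data

I/O preserves missing Ct cells as explicit NaN (never zero) and reports
them; the stability layer drops samples listwise within the analysed
subset and never imputes. No replicate-level QC (e.g. discarding a
discordant technical replicate) is applied before averaging — the
replicate mean is taken as-is.

## Synthetic-data generator

Ct panels: Ct = baseline + per-level additive shifts + N(0, σ_g), with
technical replicates jittered by N(0, 0.05 cycles) and collapsed by mean.
Gaussian noise in Ct space is log-normal noise in expression space, the
standard qPCR error model. The default design mirrors a multi-factor
livestock panel: 12 genes with baselines spread over 21–29 cycles, 39
samples shared by four overlapping factors (4/3/4/5 levels × 3 samples;
blocks wrap around the pool the way real studies reuse animals across
groupings), plus a disjoint `cohort` factor (blocks of 12/9/12/6) used as
the grouping for pooled NormFinder runs. Eleven genes carry σ between
0.10 and 0.30 cycles — the plausible range for credible reference genes —
and one planted poor reference has σ = 1.0; no level shifts by default, so
the benchmark isolates noise-driven instability. FPKM matrices plant
housekeeping-like genes (log-normal, σ_log = 0.08 ≈ 8% CV), variable genes
(σ_log = 0.6 ≈ 66% CV) and all-zero genes.

What the generator does **not** emulate: inter-gene noise correlation
(shared RT/loading effects), heteroscedastic noise at high Ct, plate and
batch effects, and regulated genes under the default spec (available via
per-level shifts). Passing the recovery benchmarks therefore shows the
estimators separate noise levels under the assumed model, not that they
are robust to correlated technical artefacts in real panels.

## Problem sizes and benchmarks

The recovery benchmark uses 50 seeded replicates of the 12 × 39 design
(the composite ranking must place the planted σ = 1.0 gene last in ≥ 95%
of replicates) and a 2-gene × 200-sample panel for the ΔCt closed-form
calibration (within 10% of √(σ₁²+σ₂²)); both sizes give stable pass/fail
behaviour across seeds while keeping the whole suite in seconds. Oracle
equivalence is checked to 1e-9 on fixtures up to 6 genes × 8 samples
against naive-loop reimplementations that share no code with the library.

## Known limitations

- Value-level reproduction of the originating goat-skin panel requires its
  supplementary Ct table, which is not redistributable with the package;
  the two tests that need it fail with an explanatory message until the
  user supplies the files (paths in the README). No synthetic surrogate is
  asserted against published values.
- NormFinder values are comparable across genes within a run, not across
  software implementations.
- geNorm's final-pair ordering is a convention (three-gene-stage M), not a
  statement that the algorithm distinguishes the last two genes.
- The Ct bound (0, 45] and efficiency bound [1.6, 2.1] are pragmatic
  instrument-range guards, not statistical statements.
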