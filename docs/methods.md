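# Methods

This note documents the statistical models, defaults and design choices
behind `pahtox`, and what the synthetic-data generator does and does not
emulate.

## Phenotype screen: LEL calling and binning

Incidence data are chemical × endpoint × concentration tables of affected
counts out of tested embryos. The lowest effect level (LEL) for a series is
the smallest tested concentration whose count exceeds background under the
one-sided exact binomial test `P(X ≥ x | X ~ Bin(n, p₀))` at α = 0.05.

* **Background rate p₀.** Pooled from the series' dose-0 (vehicle) rows
  when present. When the pooled controls show zero affected animals the
  rate is floored at `0.5/(n_control+1)`: testing against p₀ = 0 would flag
  any single event, and screening practice implies a nonzero background
  threshold even when none is observed. An explicitly supplied `p₀` must
  lie in (0, 1).
* **Severity encoding.** Affected endpoints score
  `s = 1 + log₁₀(cmax/LEL)` — an LEL at the top tested dose scores 1 and
  each decade of additional potency adds one unit; inactive endpoints score
  0. This makes "smaller LEL ⇒ larger score" monotone and puts all
  endpoints on a common potency scale. Cyp1a tissue-localization flags
  (vasculature, liver, skin, neuromasts, yolk) are appended as 0/1 columns
  with weight 1.0 (one severity unit; configurable) — no weighting scheme
  is canonical, so parity with one severity decade is the neutral choice.
* **Binning.** Ward linkage on Euclidean distances of the encoded matrix,
  cut at k = 8. Linkage and metric are exposed; Ward/Euclidean is the
  default because the severity encoding is an interval scale where
  variance-minimizing clusters are meaningful. Bins are renumbered so that
  bin 1 has the highest mean encoded severity, with ties broken by the
  lexicographically smallest member chemical — this makes labels canonical
  and permutation-invariant. Behavioral and morphological endpoints are
  treated uniformly by the severity encoding.

## Dose–response

The four-parameter log-logistic curve
`f(x) = c + (d−c)/(1 + exp(b(ln x − ln e)))` is fitted by (optionally
count-weighted) least squares on per-dose affected fractions — not by
binomial maximum likelihood — matching standard dose-response practice for
screen summaries. Fitting details: inflection dose optimized on the log
scale; box constraints 0 ≤ c, d ≤ 1 (c < d checked on the solution); a
multi-start grid with slopes b ∈ {±0.5, ±1, ±2, ±4} and e over every tested
dose, asymptotes initialized at the observed min/max; the five best-scoring
starts are polished (tolerances 1e-8), guaranteeing the returned objective
is no worse than any grid start. The exponent is clamped at ±60 so
perfectly steep curves saturate instead of overflowing; a solution that
exhausts the optimizer's budget is accepted only when its residual is
already essentially zero (steep exact fits have an unbounded slope
direction). Constant-response inputs are reported as unidentifiable, never
silently fitted.

ECp is **relative** to the fitted (c, d) span:
`EC_p = e·exp(ln((100−p)/p)/b)`, the convention of standard dose-response
software; estimates outside the tested dose range carry an `extrapolated`
flag. A practical caveat quantified by the recovery suite: when the EC₈₀
lies at or beyond the top tested dose the upper asymptote and slope are
weakly identified and per-replicate EC₈₀ errors of 15–25% (median) are
intrinsic to the least-squares estimator at screen-scale replication
(n = 32/dose); an independent optimizer (R `minpack.lm`) reproduces the
same error level on matched simulations.

## Expression analysis

* **Normalization** is median-of-ratios: reference genes are rows with no
  zero count; `factor_s = median_g counts_gs / geomean_g`. Factors are
  defined up to a common scale.
* **The DE test is a documented surrogate**, not a negative-binomial Wald
  reimplementation: `log2fc = log₂((mean_t+1)/(mean_c+1))` on normalized
  counts, p-values from per-gene Welch (unequal-variance) tests on
  log₂(normalized+1), BH step-up adjustment. The pipeline's downstream
  logic consumes only the (log2FC, p, padj) table, and on the generator's
  log-scale planted effects the surrogate is unbiased. It is less powerful
  than a count-model test at 3–4 replicates; DEG counts are therefore
  conservative relative to what a dispersion-shrinking engine would report.
* **Day matching.** Each treatment is compared only to the vehicle control
  collected on its own day, which cancels the simulated (and real)
  collection-day batch shift.
* **DEG filter:** |log2FC| ≥ log₂(1.5) and padj < 0.05, partitioned into
  elevated/reduced. The absolute-value rule is used because reduced DEGs
  are part of the reported responses.
* **Outlier replicates.** Samples are embedded by classical (Torgerson)
  2-D MDS of Euclidean distances between log₂(normalized+1) profiles. A
  replicate is a candidate when its nearest neighbour in the plane belongs
  to another condition, but that alone is not evidence of a bad replicate:
  in this design many conditions are transcriptionally equivalent (quiet
  treatments sit on top of the controls), and nearest-neighbour identity
  within a merged cloud is arbitrary. A candidate is flagged only when it
  is also detached from its own replicates — nearest same-condition
  distance above 3× the study-wide median. Drops require ≥ 3 replicates in
  the condition and are capped at one per condition, mirroring the scale of
  removal such screens actually perform.
* **Condition profiles.** Per-condition arithmetic means of normalized
  expression over retained replicates (18 rows: 16 treatments + 2
  controls). The coefficient of variation is computed across these 18
  condition means (sample sd, n−1), not across all 72 samples — the means
  are what enter the network, so responsiveness should be measured on them.
  Genes with non-positive mean are excluded; ties break by gene id; the
  top 500 are kept.

## Condition-similarity network

* **MI estimator:** plug-in (maximum-likelihood) mutual information of the
  joint histogram after per-vector equal-frequency discretization with
  `bins = floor(sqrt(n_genes))` (22 at 500 genes). Discretization is
  deterministic: stable rank with ties split by original index. A fully
  constant vector occupies a single level and is defined to carry zero
  information (MI = 0) — the one case where tie-splitting would be
  misleading.
* **Z-scores.** Two first-class modes, reported with a mode tag. Mode
  `clr` (default) is the canonical Context Likelihood of Relatedness
  transform with per-node backgrounds: `z_i = max(0, (MI_ij − μ_i)/σ_i)`
  from row i's off-diagonal entries and `Z_ij = sqrt(z_i² + z_j²)`. Mode
  `global` standardizes all off-diagonal MI values to mean 0, sd 1 — the
  verbal "standard deviations above the average of all scores" description
  of the method. Standard deviations use the n−1 denominator. An all-equal
  MI matrix yields an all-zero Z matrix with a warning.
* **Connectors:** strictly Z > threshold (default 1.0) — a pair at exactly
  1.0 is not connected.
* **Cluster extraction:** average-linkage clustering of condition profiles
  under correlation distance (1 − Pearson r), cut at k = 2, on the raw
  (unscaled) top-CV condition means. The cluster containing the vehicle
  controls is labeled A; controls split across clusters is surfaced as a
  `control-split` error, never silently resolved. Controls participate as
  network nodes.

## Biomarker analyses

*cyp1a* elevation uses strict inequalities (log₂FC > 1 AND padj < 0.05),
matching how such thresholds are printed. Concordance with cluster B is the
fraction of treatments where "cluster B" and "marker elevated" agree, with
a two-sided Fisher exact test on the 2×2 table. DEG overlap is exact set
algebra (shared-by-all, per-treatment unique, pairwise counts). The CUR
analysis takes per-chemical means of the replicated concentration-uptake
ratios, log-transforms in base 10 (base affects only scale, not r²),
restricts to chemicals with log K_OW < 5.5 (highly hydrophobic PAHs sorb to
plates and break the nominal-dose assumption) and reports the squared
Pearson correlation with DEG counts plus the Pearson t-test two-sided
p-value. The CUR standard deviation is computed and reported but not used
in the correlation.

## Synthetic-data generator

The generator defines the study conditions the test suites run under.

* **Randomness** is organized as one stream per chemical / gene / sample,
  derived from (seed, stream-kind, index), so enlarging a simulation never
  reshuffles existing draws and a fixed seed fixes every byte of output.
* **Phenotype screen** (defaults: 64 chemicals, doses 0.1–50 µM, 32
  embryos/dose): chemicals are assigned round-robin to eight endpoint-
  potency templates that follow the hazard ladder — bin 1 broadly and
  potently active through bin 8 inactive — with steep (b = −6) curves so
  LELs are sharply defined; per-bin Cyp1a tissue flags. Affected counts are
  binomial with probability `clip(LL4(dose), background, 1)`. The default
  background rate is 0 (clean-plate idealization): with any nonzero
  spontaneous rate the exact test occasionally emits false LEL calls at the
  lowest doses, and those severity outliers are larger than the planted
  between-template separation, so planted-structure recovery would measure
  false-positive luck rather than the clustering. Nonzero backgrounds are
  fully supported and exercised by the LEL tests.
* **Expression study** (defaults: 2,000 genes; 16 treatments — six B-like —
  plus one vehicle control per collection day; 4 replicates = 72 samples;
  days assigned round-robin and recorded, since the real day split is not
  public): counts are negative-binomial with variance μ + φμ². Baselines
  are log-normal (median 100, σ = 1.2); the planted genes (battery and
  private DEGs) use baseline median 500, σ = 0.5 — xenobiotic-response
  inductions are measured on robustly expressed genes. Dispersion follows
  the standard mean-dependent trend φ = 0.005 + 2/baseline with gene-wise
  gamma scatter (mean 1); flat dispersion independent of expression would
  be unrealistic for high-count genes. The 100-gene battery (containing the
  *cyp1a* marker) is elevated log₂FC = 2 in B-like treatments; each
  treatment gets 20 private DEGs at the same magnitude with random sign; a
  random 5% of genes shift by log₂FC = 0.5 in day-2 samples. The day shift
  is deliberately subordinate to the battery module: a batch effect as
  large as the treatment signal would split the B cluster's connectors by
  collection day, contradicting the two-cluster structure the design
  plants. Library sizes are log-normal (σ = 0.15).
* **Body burden** (defaults: six chemicals spanning the log K_OW range
  around the 5.5 cutoff, 3 nominal concentrations × 3 replicates = 9 CUR
  draws per chemical): CUR draws are `true_CUR × lognormal(0, σ = 0.2)`.
  True CURs sit in a realistic 1–5 range; no CUR–DEG correlation is
  planted, so the reported r² is whatever the simulated pipeline produces.
* **What the generator does not emulate:** read-level data (counts only),
  gene–gene correlation beyond the planted modules, mean–variance trends in
  the phenotype screen (per-well independence is assumed), behavioral
  time-series (behavioral endpoints enter only as incidence series), and
  dose-dependent transcriptomic response (one exposure level per
  treatment). Passing recovery tests therefore demonstrates the pipeline's
  correctness on data satisfying its model assumptions, not performance on
  real sequencing data with correlated noise, unmodeled batch structure or
  count artifacts.

## Problem sizes used by the test and acceptance suites

Unit suites run on reduced designs (800 genes; 16-chemical screens);
recovery suites use the full default design (2,000 genes × 18 conditions ×
4 replicates; 64-chemical screens), 100-replicate EC₈₀ simulations, 500
random LEL tables, 1,000 BH vectors and ≥ 10,000 MI oracle pairs — sizes at
which every Monte-Carlo bound in the tests is stable across seeds.

## Known limitations

* The DE surrogate's power at 3–4 replicates is the binding constraint on
  marker calls; padj values near 1e-3–1e-2 for genuinely induced genes are
  expected, where a count-model engine would report far smaller ones.
* EC₈₀ estimates whose true value lies beyond the top tested dose are
  extrapolations with median relative errors of ~15–25% at screen-scale
  replication (see the dose–response section); single-fit EC₈₀ values
  should be treated as order-of-magnitude anchors, which is how the
  pipeline uses them.
* The equal-frequency MI estimator is biased upward for short profiles;
  this cancels in the CLR transform's background correction but raw MI
  values should not be compared across different profile lengths or bin
  counts.
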