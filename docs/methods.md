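# Methods

This note documents the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
make results reproducible.

## Study design

The pipeline assumes sorted T-cell subsets from several donors with one
expression array and one 450K-style methylation array per (subset, donor)
sample.  The canonical design — six subsets (naive CD4, CM Th1, CD28⁺ EM
Th1, cytotoxic CD4, naive CD8, cytotoxic CD8) × five donors, donor-paired
across subsets — is what the synthetic generator produces by default and
what the paired differential-methylation test requires.

## Expression preprocessing

**Quantile normalization.**  The reference distribution is the row-wise
mean of the column-sorted matrix; every value is replaced by the
reference value at its within-column rank.  Tied values receive the mean
of the reference values at the rank positions the tie occupies, so the
transform is well defined on discrete data and idempotent on tie-free
data (tested to 1e-12).

**Variance filter.**  Probes are kept when their across-sample variance
(unbiased, n−1 denominator, computed on log2 values) is *strictly*
greater than the threshold (default 0.01) — a literal reading of
"variance > 0.01".  The filter is monotone in the threshold.

**Bootstrap clustering.**  Samples are clustered on d = 1 − Pearson r of
their probe profiles with Ward.D2 linkage.  `scipy`'s `linkage(…,
"ward")` on a precomputed dissimilarity implements exactly the
Lance–Williams update on squared dissimilarities that defines Ward.D2;
the test suite verifies the topology against an independent brute-force
agglomerator.  Node support is the plain bootstrap probability (BP): the
fraction of probe-resamples (with replacement, original size) whose tree
contains the identical sample cluster.  Approximately-unbiased (AU)
multiscale-bootstrap p-values are deliberately not implemented; BP is
sufficient for support-style statements and is what the property tests
assert.

**PCA.**  SVD of the probe-centered matrix with samples as observations;
scores are U·S, explained variance ratios are s²/Σs².  No scaling beyond
centering, matching standard expression-array practice on log2 data.

## Min/max signature derivation

A probe is specific for the test subset when its minimum over test
replicates strictly exceeds its maximum over reference replicates; ties
fail.  Before the rule is applied, probes whose maximal/minimal
expression ratio across *all* samples of the study is below 1.2 are
discarded as unregulated.  Because the input is log2, the ratio is
interpreted on the linear scale: keep probes with log2 range ≥ log2 1.2 ≈
0.263.  (A ratio of the log2 values themselves is dimensionally
meaningless, but that alternative reading is available via
`ratio_scale="log2-input"`.)  Surviving probes are flattened to gene
symbols; a gene enters the signature if *any* of its probes is specific.
The derivation uses a single reference subset; an empty result is an
empty GeneSet, not an error.

## Permutation GSEA

The enrichment score is the classic weighted Kolmogorov–Smirnov walk:
with a ranked list of N identifiers and a set of k members, hits add
|s|^p normalized by the sum of |s|^p over members, misses subtract
1/(N−k), and ES is the maximum signed deviation of the running sum.  The
weight exponent defaults to p = 1 (classic weighted GSEA); p = 0 gives
the unweighted KS statistic.  Exact positive/negative magnitude ties of
the extreme deviation resolve to the positive side — a documented
convention needed for bitwise reproducibility (such ties have positive
probability at p = 0).  If all member weights are zero (all-zero scores
inside the set), hits fall back to uniform increments 1/k.

The null is a **gene-set permutation**: for each set of size k,
`n_perm` (default 1000) random k-subsets of the ranked universe are
scored.  With 4–5 replicates per class a phenotype permutation null
would be hopelessly coarse (≤ 126 distinct relabelings), so identifier
permutation is also the statistically sensible choice at this design
size.  Permutation ES values are computed by a closed-form O(k)
evaluation over hit positions (the running sum is piecewise linear, so
its extremes occur adjacent to hits); the test suite proves this equal
to the full walk, and the walk itself is checked against an independent
oracle and against an external reference implementation.

Nominal p is the same-sign tail fraction of the null.  NES divides ES by
the mean magnitude of same-sign null ES.  FDR follows the standard
permutation-GSEA construction: each set's null ES values are normalized
by their side's mean to give a pooled null NES distribution, and
FDR(NES\*) = [fraction of pooled null NES at least as extreme, same
sign] / [fraction of observed NES at least as extreme, same sign],
capped at 1.  FDR < 0.25 is the conventional significance rule.  The
permutation stream of each set is an independent generator keyed on
(seed, set index), so results do not depend on which other sets are
evaluated or in what order.

Multi-probe genes are collapsed before two-class ranking, by default to
the most variable probe (alternatives: mean, highest-mean); the
two-class metric is the difference of class means, i.e. the log2 fold
change for log2 data.  Ranking ties break by identifier.

## 450K methylation pipeline

β = M/(U+M) per probe and sample; M-value = log2 β/(1−β) with β clipped
to [1e-6, 1−1e-6] so M stays finite.  Probe filtering removes probes
failing detection p < 0.05 in *any* sample (strict default; `all` and
`fraction` rules are exposed) and cross-reactive probes, while probes
overlapping SNPs are retained — genotype is constant within a donor, so
within-donor comparisons are immune to that confounder.

**Peak-based type-I/II correction.**  Per sample and design type, the
unmethylated and methylated modes of the M-value distribution are
located by Gaussian KDE (Silverman bandwidth, 801-point grid on ±10;
local maxima under 5% of the main peak ignored).  Type-II M-values are
linearly rescaled so their two modes coincide with the type-I modes, and
mapped back to β.  The map is affine with positive slope in M-space,
hence monotone, and the logistic return keeps β inside (0, 1).  A sample
whose type-I or type-II distribution is not bimodal is left uncorrected
with a warning.  On synthetic data with 25% type-II compression the
corrected mode offset is < 0.01 β; with no bias the correction is
near-identity (max |Δβ| < 0.04, the residual of mode re-estimation).

**Differential methylation.**  For donor-paired subsets: a two-sided
paired t-test on M-values across donor pairs (pairing key = donor
label; unpaired donors are an error naming them; ≥ 3 pairs required)
plus Δβ = median β(test) − median β(reference).  Δβ is stored signed —
the integration stage ranks on it — while the call uses its absolute
value: a CpG is differentially methylated when p < 1e-4 **and**
|Δβ| > 0.1.  Zero-variance difference vectors yield t = 0, p = 1 rather
than NaN.

**Promoter definition.**  TSS1500, TSS200, 5'UTR and 1st exon.

## Cross-omics integration

An expression GeneSet is translated to the union of its genes' promoter
probes (all-regions mode available); unmapped genes are reported, never
silently dropped, and a set with no mapped gene is an error.  Probes are
ranked by signed Δβ of medians (test − reference, descending; by design
the ranking statistic is the effect size, not the t statistic) and the
probe set is scored by pre-ranked GSEA.  Hypomethylation of the
signature in the test subset therefore appears as negative enrichment.
Because a single probe set gives the FDR construction nothing to pool
over, the real set is evaluated alongside size-matched decoy probe sets
sampled from the ranked universe (default 100), mirroring the practice
of padding a small collection with a public catalog for robust FDR
estimation.  By default the ranking universe is all retained probes and
the promoter restriction applies to the set side; `rank_promoter_only`
restricts the universe too.

## Assay calculators

* **ΔΔCp**: ΔCp = Cp(target) − Cp(reference gene, default EEF1A1) per
  (donor, subset) after averaging technical replicates; ΔΔCp subtracts
  the same donor's calibrator-subset ΔCp; log2 FC = −ΔΔCp.  Summaries
  are median ± IQR across donors.  Adding a constant to every Cp of a
  sample (input-amount shift) cancels exactly.
* **ChIP %input**: adjusted input Cp = Cp(input) − log2(1/f) for input
  fraction f (default 1%); %input = 100·2^(adjusted − Cp(IP)).  The
  reported value is %input(target)/%input(pan-H3) — the ratio form of
  "normalized for the H3 ΔCp"; a subtractive mode (100·2^(Cp_H3 −
  Cp_IP)) is exposed since the phrasing admits both, and the two differ
  only by the constant H3 recovery scale.
* **% lysis**: caspase-3⁺ targets with effectors minus the no-effector
  control, floored at 0 with a warning (the assay cannot lyse a negative
  number of cells).
* **Single-cell co-expression**: a gene is positive above a
  limit-of-detection threshold (default: any expression > 0 on the
  fixture's scale).  Per subset: anchor⁺/total, and per partner
  (anchor⁺ ∧ partner⁺)/anchor⁺, reported as undefined (NaN), not 0, when
  no anchor-positive cell exists.  Well QC (housekeeping floor + Tukey
  IQR fence) is provided with configurable parameters, since published
  single-cell qPCR QC thresholds are rarely stated exactly.
* **Pyrosequencing**: per-CpG median ± IQR across donors over the 34
  PRF1-promoter sites, and per-region medians of the per-CpG medians
  with the region map distal = sites 1–15, intermediate = 16–28,
  proximal = 29–34.

## Synthetic-data generator

`make_study` draws: log2 expression = per-probe baseline N(8, 1.5²) +
N(0, 0.25²) noise, with `expr_effect` = 2.0 log2 units added to
signature genes (default 40 per cytotoxic subset, disjoint between
subsets) in their subset's samples; methylation baselines from a bimodal
mixture (modes 0.1 and 0.85, matching real 450K marginals), per-sample β
from Beta(μc, (1−μ)c) with concentration c = 60, a per-(probe, donor)
random offset on the M scale (sd 0.5) shared across that donor's subsets
— the inter-individual variability that motivates donor pairing, which
cancels exactly in the paired test — and `meth_effect` = −0.3 Δβ applied
to the promoter probes of the planted genes in the planted subset (their
baselines start at the methylated mode so the shift has room).  Type-II
probes (72%) are compressed toward β = 0.5 by 15% before output;
raw M/U signals, detection p-values, cross-reactive and SNP flags are
emitted so the filtering and correction stages have real work.  Every
planted gene is guaranteed ≥ 1 promoter probe.  The full output is a
deterministic function of the spec, including its seed.

What it does **not** emulate: probe-level genomic annotation beyond the
fields the pipeline consumes, spatial correlation of neighbouring CpGs,
array batch effects, cell-type admixture, and realistic gene–probe
multiplicities (5% of genes get a second expression probe).  Passing
tests on this generator therefore demonstrate the correctness and
calibration of the *algorithms* under the declared generative model, not
robustness to every artefact of real arrays.

## Problem sizes and error-rate checks

The acceptance script and tests use these scales (chosen to make the
Monte-Carlo standard errors small relative to the asserted margins):

* ES oracle: exhaustive 4-gene universes (10 score draws × 14 subsets ×
  p ∈ {0,1}) plus 500 random instances with N ≤ 200; agreement to 1e-12.
* Null calibration: 200 independent random sets of size 20 against a
  fixed 500-identifier ranking, 200 permutations each; KS uniformity of
  nominal p and the FDR < 0.25 call rate against 0.25 + 2·SE.
* DM type-I: 2 × 100,000 null probes, 5 donor pairs; positive rate at
  p < 1e-4 against 5e-4 + 3·SE.
* DM power: 5 studies × ~70 planted probes at Δβ = −0.3, 5 pairs,
  per-sample β-sd 0.03 (concentration 274 at the hypomethylated level).
  Measured power is ≈ 0.65.  This is a property of the design, not the
  implementation: with 4 degrees of freedom the two-sided critical t at
  p = 1e-4 is 15.54, and independent per-sample β noise of sd 0.03 at
  levels 0.85 → 0.55 yields a noncentrality of only ≈ 12–13.  Per-sample
  β-sd ≤ 0.015, ≥ 8 donor pairs, or a p threshold of 1e-3 would be
  needed for ≥ 95% single-probe power; the set-level integration route
  is how the pipeline achieves sensitivity at this sample size.
* End-to-end recovery: 20 seeds × (600 expression probes, 1500
  methylation probes, 30 planted genes); min/max recall, zero-noise
  false-gene count, and the hypomethylation-side FDR < 0.25 success
  count over seeds.

## Known limitations

* The FDR estimator inherits the conservatism/anti-conservatism
  trade-offs of the original permutation-GSEA construction at very small
  collection sizes; the decoy mechanism in the integration stage exists
  precisely to stabilize it.
* Peak correction assumes both design types are bimodal per sample;
  heavily skewed subsets of probes (e.g. a promoter-only panel) should
  be corrected before subsetting.
* Bootstrap support values are plain BP and are known to be biased
  downward for small true clades relative to AU p-values.
* The min/max rule is intentionally conservative and noise-sensitive at
  larger replicate counts (min falls, max rises); the regulation
  pre-filter controls its false-positive side but recall depends on
  effect size vs replicate noise.
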