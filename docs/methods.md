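# Methods

## The count model

Hairpin counts are modeled as negative binomial with a common dispersion:
for hairpin *h* in sample *s*, y<sub>hs</sub> ~ NB(μ<sub>hs</sub>, φ)
with Var = μ + φμ². φ = 0 degenerates to Poisson everywhere in the
package. The screen design is two groups (T2 baseline, T14 outcome) of
biological replicates per pool; the only parameter of interest is the
ratio of group means per hairpin.

### Library-size equalization

Columns are linearly rescaled so each sums to the geometric mean of the
column sums ("pseudo-counts"). This is a declared simplification of the
quantile-based equalization used by classic count-model packages; the two
coincide exactly when depths are already equal, which is how the
cross-check tests are constructed. Pseudo-counts are rounded to the
nearest integer wherever a discrete NB quantity is needed (conditional
likelihood, exact-test group sums).

### Common dispersion

φ is estimated by maximizing, over φ ∈ [10⁻⁸, 20], the summed
conditional log-likelihood of each hairpin's within-group counts given
their group sum. For n iid NB(μ, φ) counts with sum z the conditional
law is Dirichlet-multinomial with shape r = 1/φ per entry,

P(y | z) = [∏ᵢ C(yᵢ + r − 1, yᵢ)] / C(z + n r − 1, z),

which is free of μ — conditioning removes the per-hairpin means, and
between-group differences never enter, so planted (or real) fold-changes
do not bias φ̂. Groups with fewer than two samples contribute nothing;
estimation errors out if no group has two. The 1-D bounded maximization
uses absolute tolerance 10⁻⁸; a monotone-decreasing likelihood (data
underdispersed relative to Poisson) returns the lower bound. Agreement
with an independent dense grid search and with edgeR's
`estimateCommonDisp` is part of the test suite.

### Exact conditional test

A group sum of n iid NB(μ, φ) is NB(nμ, φ/n). Writing A, B for the
rounded T2/T14 pseudo-count sums and S = A + B, the null conditional law
of A given S is negative hypergeometric,

P(a | S) ∝ Γ(a + r₁)/Γ(a + 1) · Γ(S − a + r₂)/Γ(S − a + 1),
 r_g = n_g/φ,

again free of μ; at φ = 0 it is Binomial(S, n₁/(n₁+n₂)). The two-sided
p-value follows the minimum-likelihood convention: the sum of P(a) over
all splits with P(a) ≤ P(A), ties included. Probabilities are computed
in log space by direct enumeration over 0..S (log-gamma differences,
normalized by logsumexp); splits within 10⁻⁸ of the observed
log-probability count as ties, which keeps the tie set stable under
floating-point noise. Enumeration is capped at S ≤ 10⁷ — beyond the
desk scale of this package — and errors with advice to downsample. The
cap was set so that the deepest hairpins arising at the simulator's
default depth (10⁶ reads/sample with log-normal abundance spread) still
enumerate directly; a 5×10⁶-point enumeration takes ~0.2 s.

Reported statistics per hairpin:

- logFC = log₂((B/n₂ + c) / (A/n₁ + c)) with prior count c = 0.5 per
  group mean (configurable), keeping logFC finite at zero counts;
- logCPM = log₂((S + 2c) / (L(n₁+n₂)) · 10⁶) with L the common
  (geometric-mean) library size — the log-CPM of the average
  pseudo-count;
- S = 0 rows get p = 1 and logFC = 0 by convention.

Unequal replicate numbers are handled by the group-sum aggregation
itself (r_g = n_g/φ); no per-sample weights are needed.

### FDR and hit classification

Benjamini–Hochberg step-up (via statsmodels) within each pool by
default, since each pool is an independent experiment; a global mode is
available. Hits: FDR ≤ 0.01 (inclusive — this reproduces the published
80-row table, whose largest FDR is 9.91×10⁻³) and linear fold-change
strictly beyond 1.5× in either direction; a significant hairpin inside
the fold band is reported as `significant_only`. Unique-gene counts
uppercase symbols because published tables mix casing styles.

## Sample QC

`mds_qc` computes a leading-fold-change distance between samples — the
root-mean-square of the top-k (default 500) largest absolute per-hairpin
log₂ CPM differences, 0.5 added before logging — and embeds samples by
classical (Torgerson) scaling. Outlier flags (any coordinate beyond 5
MADs from the axis median) are advisory: the original practice was
visual inspection, and removal remains the analyst's call.

## Screen design arithmetic and limiting dilution

`expected_representation(n_cells, sphere_rate, infection_rate,
pool_size)` is the product n·s·i/p — the expected number of
sphere-forming transduced cells carrying each hairpin; at the screen's
stated inputs (2×10⁶ cells, 0.85%, 40%, 88) it is 77.3.

`limiting_dilution_frequency` fits the single-hit Poisson model
Pr(outgrowth | dose d) = 1 − exp(−f·d) by maximum likelihood (bounded
1-D optimization on log f, tolerance 10⁻¹³), with a 95% CI from
likelihood-ratio inversion at the χ²₁ 0.95 quantile. Boundary cases: all
transplants negative gives f̂ = 0 with lower bound 0 and a finite upper
bound; all positive leaves f unbounded and raises.

## Expression filter

CPM divides by the column sum (optionally scaled by TMM factors); log
mode uses a prior of 0.25 reads at average depth, scaled per sample in
proportion to library size, with the library inflated by twice the
scaled prior — keeping log-CPM finite and cross-depth comparable. TMM
factors are the weighted trimmed mean of M-values against a reference
column (trim 30% of M, 5% of A, inverse-asymptotic-variance weights,
reference chosen as the column whose depth-normalized upper quartile is
closest to the mean), normalized to multiply to 1; the implementation is
checked against an independently coded step-by-step oracle and against
edgeR's `calcNormFactors`. Expressed calls use average linear CPM
strictly greater than 0.5, averaging replicates before thresholding.
`cross_reference` partitions hit genes into
expressed-in-primary-populations (noting how many of those are also in
spheres), sphere-only, and nowhere; genes absent from the expression
table raise rather than being dropped. Probe collapse keeps the probe
with the highest mean expression per gene, ties broken by
lexicographically smallest probe id (a declared convention; the original
procedure is silent on ties).

## The simulator

`simulate_truth` draws, from one seeded generator:

- baseline per-pool abundances: log-normal with σ = 1.0 on the log scale,
  normalized within pool. σ = 1.0 emulates a strongly uneven library
  (~25-fold 90% range across hairpins), the wide end of what pooled
  libraries show after transduction and bottlenecking;
- an optional Poisson founder count per hairpin (`bottleneck_mean`,
  77 by default when enabled — the expected per-hairpin representation
  of the screen design) multiplying the baseline before normalization;
- planted hits: each hairpin is a hit with probability `hit_fraction`
  (default 0.10), direction fair-coin, fold drawn uniformly from the
  enriched (default exactly 3) or depleted (default exactly 1/3) range;
- per-sample depths: log-normal around `mean_libsize` (default 10⁶
  reads) with σ = 0.2, emulating uneven lanes.

`simulate_counts` scales baseline (T2) or fold-adjusted-and-renormalized
(T14) proportions by the sample depth and draws NB counts. The T14
renormalization reflects compositional sequencing: a fixed read budget,
so strong hits displace everything else. `emit_fastq` materializes
exactly the counted reads with random filler and optional per-base
substitution errors (a substituted base never resamples itself);
qualities are a constant 'I' since the counter ignores them.

What the simulator does *not* emulate: PCR amplification bias and
duplicate structure, position-dependent or indel errors, index
hopping/cross-contamination, hairpin-specific knockdown variability, or
correlated replicate effects. Passing recovery tests therefore
demonstrate correctness of the statistical chain under its own model
assumptions, not robustness to these real-data artifacts.

## Validation scale and known limitations

Test simulations use 88–5,000 hairpins and depths of 10⁵–10⁶
reads/sample; the null-calibration and dispersion-recovery checks run at
2,000–5,000 hairpins, 3 vs 3, and the end-to-end recovery check runs 50
screens of one 88-hairpin pool each — sizes chosen to exercise the full
chain at the screen's own scale while keeping the suite fast.

At the end-to-end reference conditions (10% hits at fold 3 or 1/3,
φ = 0.1, 10⁶ reads/sample, 3 vs 3, per-pool BH at 0.01), measured
sensitivity is ≈ 0.76 with mean false-discovery proportion ≈ 0.01:
misses concentrate in below-average-abundance hairpins, and head-to-head
comparison shows hit-for-hit agreement with edgeR's classic exact-test
pipeline on identical matrices — the ceiling is the information in the
counts, not the implementation. Wider baseline spread (larger σ) lowers
sensitivity; tighter libraries do better.

Other limitations: counting is strictly positional and exact-match
(fuzzy matching, UMIs and paired-end layouts are out of scope);
library-size equalization is linear, not quantile-based; and the
expression filter validates on synthetic truth tables — reproducing the
published Venn counts would require the original RNA-seq series.
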