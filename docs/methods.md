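# Methods

This note documents the statistical procedures implemented in `ifxpanel`,
the conventions chosen where the field leaves room, the synthetic-cohort
model used for validation, and the limitations of both.

## Abundance preparation

Feature counts are collapsed to genus by summation; features without a
genus assignment pool under `unassigned_<family>` so that no reads are
discarded by aggregation. Quality filtering removes, in order:

1. blocklisted lineages (default cyanobacteria and chloroplasts, matched
   case-insensitively against every rank and the genus label) — blocklist
   removal precedes abundance ranking so a highly abundant contaminant
   cannot displace a real genus from the top-N set;
2. taxa whose pooled relative abundance (taxon total / grand total) is
   strictly below 0.01 % — the boundary taxon at exactly 0.01 % is kept;
   "across all samples" is read as the pooled grand-total fraction rather
   than a per-sample criterion;
3. everything beyond the top 3000 taxa by mean per-sample relative
   abundance.

TSS divides each count by its sample total; the Hellinger transform takes
entrywise square roots of TSS values. The two representations carry a
`transform_tag` and the Hellinger step refuses anything but a TSS input, so
the fixed order cannot be violated or applied twice silently.

## Rarefaction and alpha diversity

Rarefaction draws reads without replacement (multivariate hypergeometric),
the standard semantics for subsampling physical reads. Samples below the
target depth (default 12 180) are dropped with a logged warning rather than
aborting the run: cohorts of interest normally sit well above the target
and a sporadic shallow sample should not kill a batch analysis. Shannon
entropy is computed in natural log; only evenness ratios are compared, so
the base is a free choice. Pielou evenness for richness ≤ 1 is defined as
0 (the ratio H/ln S is otherwise undefined), keeping the statistic bounded
and monotone.

The core-microbiome Venn partition calls a genus present in a group when it
is detected (relative abundance > 0) in at least `presence_fraction`
(default 0.5) of the group's samples. Published Venn figures of this kind
rarely state their presence rule; here it is explicit and configurable, and
the regions are exact membership combinations, hence disjoint by
construction.

## ΔΔCt differential expression

ΔCt subtracts the per-sample mean of the housekeeping set from each assay
gene's Ct. The default housekeeping set is {ACTB, B2M, GAPDH, HPRT1,
RPLP0}; HGDC — a genomic-DNA contamination control printed on the same
array format — is accepted but opt-in, because a contamination control is
not a reference gene. Undetermined wells are imputed at the Ct ceiling
(default 35 cycles) and flagged; genes with more than half their wells
imputed in either contrast group are reported but marked low-confidence.

For a contrast, ΔΔCt = mean ΔCt(A) − mean ΔCt(B), fold change = 2^(−ΔΔCt),
and fold regulation is the signed convention used by PCR-array analysis
software (FC when ≥ 1, else −1/FC). p-values come from a two-sample t-test
on per-sample ΔCt values; Welch's form is the default because group
variances are rarely equal in small clinical strata, with the
pooled-variance form available. Raw p at 0.05 is the default selection
criterion (matching how such array analyses are usually reported);
BH-adjusted values are always computed alongside. Fold thresholds are
inclusive (≥), p thresholds strict (<).

Degenerate genes (identical values in both groups) get p = 1; zero
within-group variance with differing means gets p = 0, treating the shift
as deterministic.

## Differential abundance

One-way fixed-effects ANOVA per genus, on Hellinger-transformed abundances
by default — the square root stabilises the variance of proportions, which
matters at these sample sizes — with plain TSS available since either
representation is defensible. Two alpha presets are exposed: 0.01 for the
well-powered healthy-vs-disease contrast, 0.05 for the small
treatment/response strata. BH correction is reported but not applied by
default. A genus with zero total variance is assigned F = 0, p = 1.

## The concordance panel rule

Expression enters the integration step as 1/Ct: low Ct means high
expression, so the reciprocal is a monotone-increasing proxy that needs no
calibration. Spearman's ρ (midrank ties, pairwise deletion of incomplete
pairs) is computed per (genus, gene) within each response stratum at
baseline. Correlations with |ρ| ≥ 0.8 (inclusive) are classified strong;
the literature this rule comes from never quantifies "strong", so the
threshold is explicit, configurable, and recorded with every output.

A gene joins the paired biomarker panel when

1. it is strongly correlated (either sign) with **all** responder-enriched
   genera, evaluated in the responder stratum;
2. it is strongly correlated with at least k of the m
   non-responder-enriched genera (default 3 of 4), where a gene counts
   toward a genus if it appears in either stratum's sign list for that
   genus — this reading reproduces both worked-example union counts (19
   and 20) from the packaged fixture;
3. its baseline differential-expression direction is recorded (the
   pipeline feeds the ≥ 15-fold panel-eligible selection here).

Genes meeting (1) and (2) but lacking a direction are retained in the rule
trace as excluded-for-missing-direction rather than silently dropped. The
full per-gene trace (which genera hit, counts, directions) ships with every
panel. Mixed correlation signs across genera are allowed — the published
panels mix signs — and the sign pattern is preserved in the trace.

The packaged fixture transcribes the published per-genus sign lists of a
mucosal Crohn's cohort. Two published statements about that cohort are in
tension: the count of 20 genes is reproducible as the union over the four
non-responder-enriched genera, while the set correlating with ≥ 3 of the 4
genera is smaller (16 in the fixture). Both quantities are exposed
(`consensus_genes` returns counts, the k-threshold set and the union); the
package does not attempt to resolve the discrepancy. Likewise, the
published final panel includes one gene whose printed responder-stratum
correlations do not satisfy criterion (1) as stated; panel assembly
therefore always requires an explicit `de_directions` input and never
hard-codes a published gene list.

## Synthetic cohorts

`generate_cohort` draws, per sample, genus counts as
multinomial(depth, softmax(η)) with η = base log-abundance profile +
group-specific log-fold shifts + N(0, σ_g²) noise; depth is a discretised
log-normal (default median 60 000, σ = 0.4, matching the scale of typical
mucosal 16S runs). A logistic-normal → multinomial composition was chosen
over Dirichlet-multinomial because it lets a latent factor enter one
coordinate directly. Ct values are a per-gene baseline (25 cycles) +
group-specific cycle shifts + N(0, σ_e²); housekeeping genes are
N(20, 0.2).

Taxa–gene couplings share per-(stratum, factor) standard-normal latent
factors z_s. For a target rank correlation ρ, both the genus log-abundance
loading and the gene Ct loading are set to t·(their noise scale) with
t = sqrt(|ρ|/(1−|ρ|)); each side then correlates t/√(1+t²) with z and the
product of the two attenuations equals |ρ|, so the realized Spearman
correlation approximates the planted strength (the Monte-Carlo check in the
test suite confirms a realized median ≈ 0.9 for a planted 0.9 at n = 20).
The gene enters Ct as −c·z so that higher planted abundance co-occurs with
higher 1/Ct for positive strengths. Genus loadings carry an explicit sign
so mixed sign patterns (one genus positive with a gene, another negative)
are expressible; couplings implying contradictory loadings on one factor
are rejected at design validation.

Two regimes constrain the calibration and drove the chosen defaults:

* **compositional closure** — if several genera sharing a factor with the
  same sign jointly dominate a sample, TSS cancels their common variation;
  the reference-like design therefore plants its genera at mid-rank base
  abundances (a few percent after the group boost);
* **counting noise** — a genus drawing only a handful of reads at the low
  end of its latent swing acquires rank ties that attenuate Spearman ρ;
  the per-genus log noise (0.15 in the reference-like design) and loading
  magnitudes keep planted genera above ~50 reads in the relevant strata.

`reference_cohort_design` mirrors the reference cohort's structure: baseline CD
responder/non-responder strata (default n = 5 each, the reference size),
post-treatment counterparts and nine healthy controls; two genera planted
up in responders and four in non-responders (2.0 log-fold); six genes
planted up and one down in responders (6-cycle ΔCt shifts, ~64-fold, all
clearing the 15-fold panel filter with margin); couplings of strength 0.98
linking each panel gene to both responder genera and three of the four
non-responder genera in the responder stratum, plus a small
non-responder-stratum axis. Distractors are included by design: two weakly
DE genes below the panel fold cutoff and one coupled-but-not-DE gene that
exercises the excluded-for-missing-direction path. The planted magnitudes
are free parameters of the generator — the source narrative reports sign
lists, not effect sizes — calibrated once so that the planted structure is
recoverable at the validation sample size (n = 20 per stratum) and then
frozen.

The pipeline feeds the consensus rule the most significant 2 + 4 genera per
direction, matching the reference study's structure; raw ANOVA p orders the
candidates, which is robust here because planted effects sit many orders of
magnitude below the null p floor.

What passing the synthetic suite does **not** show: robustness to
taxonomic misclassification, chimeras or batch effects (not simulated), to
zero-inflation beyond what the multinomial induces, to housekeeping-gene
instability, or to couplings mediated by anything other than a shared
latent factor. Real-cohort Venn counts, DE counts and alpha-diversity
contrasts depend on the (undeposited) data and are reference context, not
reproduction targets.

## Numerical conventions

* Thresholds: removal at the abundance filter uses strict `<`; fold and
  correlation thresholds are inclusive `≥`; p thresholds are strict `<`.
* Spearman with fewer than 3 complete pairs or a constant vector returns
  NaN and classifies as "none", with a warning.
* Sample identifiers are case-sensitive and matched exactly across all
  inputs before any stage runs.
* Problem sizes used by the validation suite: 100 genera / 40 genes per
  synthetic cohort; 200 cohorts for null calibration (n = 5 per group);
  50 cohorts for panel recovery (n = 20 per stratum); 500 draws for the
  rarefaction goodness-of-fit check.
* All randomness flows through `numpy.random.default_rng` seeds recorded in
  the run manifest; the simulation uses the run seed and rarefaction uses
  run seed + 1.
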