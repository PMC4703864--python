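# Methods

This note documents the statistical procedures implemented in `episig`,
the generative model behind the cohort simulator, the numerical choices
made where the design was open, and the limits of what the simulation-based
tests demonstrate.

## Discovery procedure

**Probe exclusion.** Three rules, applied to the input beta matrix with its
manifest-style annotation: (i) SNP-affected probes — any of the three SNP
flags (interrogated C/G, single-base extension, within 10 bp) combined with
minor-allele frequency ≥ `maf_threshold` (default 0.01; 0.05 supported as a
lenient alternative). A flagged probe whose MAF is unknown is removed: the
conservative reading, since an unverifiable polymorphism cannot be ruled
out. (ii) Cross-reactive probes, consumed as a boolean flag (the underlying
multi-mapping alignment is upstream of this package). (iii) Probes with any
missing beta or any detection *p* > `detection_p_max` (default 0.01) in any
sample. A single bad entry removes the whole probe — the strictest reading,
with the side benefit that the downstream rank tests never see group sizes
perturbed by missingness. The removal order (SNP → cross-reactive →
detection) only affects report bookkeeping; the retained set is
order-independent, and the filter is idempotent and monotone in both
thresholds (property-tested).

**Family-robust trials.** Related cases violate the independence assumption
of a rank test. The design therefore forms one testing trial per
combination of a single representative from each case family together with
all non-familial cases, against the full (shared) control set: one family
of three ⇒ 3 trials; two families of two ⇒ 4 trials; no families ⇒ 1
trial. A "family" of one is treated as non-familial with a warning.

**Per-CpG test.** Two-sided Mann–Whitney *U* with midranks for ties. With
both groups ≥ 8 samples the *p*-value uses the normal approximation with
tie and continuity corrections (the standard choice at discovery-cohort
sizes, where exact enumeration is infeasible). Below that, the exact null
is enumerated over all C(n₁+n₂, n₁) assignments of the pooled midranks —
unlike textbook exact tables this remains valid under ties — with the
two-sided *p* defined by distance of *U* from its null mean n₁n₂/2 (the
enumeration distribution is symmetric). The exact branch is verified
against an independent brute-force permutation oracle on every design shape
with n₁+n₂ ≤ 12. In the far tail the normal approximation is conservative
(rank statistics have bounded support), so Bonferroni control is not
undermined.

**Multiple testing and retention.** Bonferroni: q = min(1, m·p), with m =
the number of probes actually tested in that trial (recorded in the
signature for provenance). A CpG enters the signature iff q < `alpha`
(0.05) in every trial, |mean_case − mean_control| ≥ `effect_size_min`
(0.20, beta scale) in every trial, and the difference has one sign across
trials. Sign consistency is enforced because each signature CpG carries a
single direction label; a CpG flipping direction between family
representatives would have no coherent direction. Direction `loss` means
cases are hypomethylated.

**Classifier.** Reference profiles are per-CpG medians (midpoint convention
for even counts) over discovery cases and over controls — medians, not
means, for outlier robustness. The score of a sample is the difference of
Pearson correlations of its signature-CpG vector with the two profiles,
computed on untransformed betas; the call is by sign. Ties at exactly the
threshold are called `not_SS` with a warning — conservative for a
diagnostic claim. Samples missing signature CpGs are scored by pairwise
deletion provided coverage ≥ 90% (`min_coverage`); below that scoring is
refused rather than silently degraded, since the decision geometry of a
correlation over a shrinking subset is not characterized.

**Validation utilities.** Sensitivity/specificity from the confusion matrix
of calls against sheet labels. Unsupervised clustering uses the Pearson
distance 1 − r over signature CpGs with average linkage by default
(complete and Ward-on-Euclidean are available), cut at k = 2; the
separation flag records whether the cut matches the case/control labels up
to label swap. Confounder checks are nonparametric and report raw
*p*-values: cohort composition by chi-square (sex; Pearson form without
Yates correction, which is the convention that reproduces published cohort
tables of this layout) and Wilcoxon rank-sum (age); within controls,
score-vs-sex (Wilcoxon), score-vs-age (Spearman), score-vs-batch
(Kruskal–Wallis). Cell-type composition has no dedicated module: externally
estimated cell fractions can be passed as generic numeric covariates and
are tested like age — a stand-in, labelled as such, not a deconvolution.

**Feature enrichment.** Signature CpGs are a subset of the filtered
background, so per-category enrichment uses the hypergeometric law; the
two-sided *p* follows the minimum-likelihood convention (as in R's
`fisher.test`), verified against binomial-coefficient enumeration.
Benjamini–Hochberg is applied across categories within a scheme and
reported alongside raw *p*. Boolean schemes (enhancer, DHS) are reported as
flagged/not-flagged; multi-valued manifest entries (';'-separated gene
groups) count a probe once per distinct category, so those percentages
intentionally need not sum to 100.

## The cohort simulator

The generator emulates the statistical structure of a blood 450K
case/control study; it makes every downstream stage testable and defines
the conditions under which the package's claims are verified.

* **Baselines.** Per-CpG means from a bimodal mixture (Beta(5, 45) and
  Beta(45, 5), equal weight) — the familiar two-hump array distribution
  concentrated near 0.1 and 0.9.
* **Noise.** Per-sample betas ~ Beta(μκ, (1−μ)κ): mean μ, precision κ,
  variance μ(1−μ)/(κ+1). Beta noise (not truncated Gaussian) keeps values
  in (0, 1) without boundary artifacts. Default κ = 80 gives s.d. ≈ 0.055
  at mid-range μ, typical of blood-array replicate scatter; κ is a free
  modelling parameter, not an estimated quantity.
* **Signal.** `n_signal` CpGs (default 1,000 of 10,000) shifted in cases;
  a fraction `frac_loss` (default 0.993) lose methylation. Loss CpGs draw
  their baseline from the methylated component and gain CpGs from the
  unmethylated one — methylation loss happens at normally methylated
  sites — so the full shift fits inside the mean clip [0.02, 0.98].
  Per-CpG shift magnitudes are δ·(0.75 + Gamma(shape 2, scale 0.125)),
  i.e. mean exactly `delta_beta` (default 0.25), minimum 0.75δ, right tail
  to ≈ 2δ. The spread matters twice: a near-constant shift would make the
  case profile an affine translation of the control profile over an
  almost-all-loss signature — invisible to a Pearson classifier — and
  would leave case samples no more correlated with one another than with
  controls, so cases could not cluster as a distinct group. Measured
  effect sizes above an absolute-difference filter are in reality spread
  and right-skewed, which this distribution mimics.
* **Families.** The default design includes one case family of three with
  within-family correlation ρ = 0.3 (a moderate relatedness effect; no
  published estimate pins this for blood methylation at signature CpGs).
  Implementation is a two-stage beta draw: family mean ~ Beta(mean μ,
  precision κ₁), member values ~ Beta(mean family-mean, precision κ₂),
  with κ₁ = (κ+1)/ρ − 1 and κ₂ = κ/(1−ρ). These closed forms preserve the
  marginal variance μ(1−μ)/(κ+1) exactly and give member–member
  correlation exactly ρ (law of total variance).
* **Batches and tissue.** Additive logit-scale mean shifts (default two
  batches, ±0.025 logit) keep betas bounded. Validation cohorts get a
  batch label disjoint from discovery; an optional logit offset emulates a
  crude tissue effect (e.g. fibroblast-like cohorts with higher κ).
* **Detection failures.** Entries fail (detection *p* drawn above 0.01)
  independently at `missing_rate` (default 0.001, the order observed on
  well-behaved arrays); betas at failed entries remain present so the
  filter — not the generator — decides their fate.
* **Demographics.** Case ages from a wide gamma (mean 10.1, s.d. 9.6
  years), control ages narrower (mean 10.8, s.d. 4.8); sex frequencies
  slightly male-skewed in cases. These mirror a pediatric overgrowth
  referral cohort and give the confounder checks realistic material.
* **Reproducibility.** One seed drives named `SeedSequence` substreams
  (truth, annotation, discovery samples, validation cohorts), so any
  cohort regenerates bit-identically.

**What the simulation does not model.** Infinium I/II chemistry
differences, probe-type normalization, genomic autocorrelation of
methylation, LD structure behind SNP flags, cell-type composition shifts,
age-related drift at specific CpGs, and any association between annotation
categories and signal status (annotation flags are independent of signal,
so enrichment on simulated data is expected to be flat — the enrichment
module's correctness is instead established by its enumeration oracle).
Consequently, passing tests demonstrate the pipeline's statistical
machinery and its operating characteristics under a faithful abstraction of
the study design — not performance on real arrays, where normalization
quality and population structure add failure modes this model excludes.

## Problem sizes and numerical choices

Simulated studies use 10,000 CpGs (1,000 signal) with 19 + 53 discovery
samples and 200 + 19 validation samples — large enough that Bonferroni
thresholds, effect filters and score distributions behave as at array
scale, while a full discovery-to-validation cycle runs in seconds.
Parameter-recovery checks use Δβ = 0.30 and κ = 150 (recall ≥ 0.95,
precision ≥ 0.99); null checks (no signal) require an empty signature in
≥ 19 of 20 seeds, the family-wise rate Bonferroni guarantees. Betas are
64-bit floats serialized at 6 decimals (array precision is far coarser);
exact-test *p*-values are floored at the smallest positive double;
correlations are clipped to [−1, 1] against rounding; degenerate inputs
(constant vectors, empty groups, single-level covariates) raise or skip
with a warning rather than returning NaNs.

## Known limitations

* Bonferroni with m = probes-tested is deliberately stringent; no FDR
  alternative is offered on the primary path.
* The three-trial construction enumerates representative combinations, so
  many large families would multiply trials combinatorially; cohorts seen
  in this setting have at most a handful.
* The score threshold (0) is fixed by the sign convention, not calibrated;
  scores are similarity differences, not probabilities.
* Average linkage cut at k = 2 can isolate a single outlying sample in
  borderline geometries; the linkage is configurable, and the cluster tree
  itself (Newick export) should be inspected rather than trusted blindly
  through the binary separation flag.
* The GEO series-matrix reader handles the minimal dialect (header lines
  starting with `!`, one table block) sufficient for deposited beta
  matrices; it is not a general SOFT parser.
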