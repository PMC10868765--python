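# Methods

`nrf2screen` implements a tumor-cohort analysis that asks whether somatic
alteration of SWI/SNF chromatin-remodeler subunits is associated with
transcriptional activity of the KEAP1–NRF2 axis. This note records the
models, rules and numerical choices the package makes, and what its
synthetic validation does and does not demonstrate.

## Alteration calling

Two predicates convert genomic evidence (MAF-like variant records plus
discretized Gistic copy-number scores) into per-sample alteration calls, and
they are deliberately kept separate:

* **Symmetric rule** (`call_any_alteration`): a sample is altered in a gene
  if it carries a deep deletion (Gistic −2), a focal amplification (Gistic
  +2) or a nonsynonymous variant in that gene. Used for frequency tables and
  the cohort-level co-occurrence test, where the direction of the event is
  not interpreted.
* **Polarity-aware NRF2-activity rule** (`call_nrf2_active`): KEAP1 and CUL3
  encode components of the E3 ligase that degrades NRF2, so only their loss
  counts (deep deletion or nonsynonymous variant); NFE2L2 encodes the
  oncogenic transcription factor itself, so only amplification or missense
  (stabilizing) variants count. NFE2L2 nonsense and frameshift variants are
  *not* activating evidence under this rule — the literal reading of the
  class list — even though one could argue some truncating alleles escape
  degradation. Samples labeled by this rule seed the signature derivation.

The default nonsynonymous class list is `Missense_Mutation`,
`Nonsense_Mutation`, `Frame_Shift_Del`, `Frame_Shift_Ins`; splice-site and
in-frame indel classes are excluded by default but configurable, since MAF
class vocabularies vary. Shallow copy-number events (±1) never count.

**Group construction.** For a gene of interest *g* in the SWI/SNF panel
(default ARID1A, ARID1B, ARID2, PBRM1), the mutant group contains samples
altered in *g* and in nothing else (no other panel subunit, not
NRF2-pathway-active); the control group contains samples altered in nothing;
everything else is excluded with a per-sample reason. This removes the two
dominant confounders of the contrast: co-mutation of another remodeler
subunit and direct pathway activation. A mutant group below
`min_group_size` (default 5 — small enough to keep rare subunits testable,
large enough for a two-group statistic) flags the contrast rather than
failing. The sentinel gene `NRF2_PATHWAY` builds the positive-control
contrast: pathway-active samples without subunit mutations vs clean
controls.

## Expression preprocessing

Counts are filtered (keep a gene if CPM ≥ 1 in ≥ 20% of samples; the pooled
log-CPM skewness is logged as a diagnostic of the resulting distribution),
normalized by trimmed mean of M-values and converted to log2 CPM with a
prior count of 0.5. The TMM implementation uses the standard constants
(M-trim 0.30, A-trim 0.05, inverse asymptotic-variance weights, reference
column chosen by the upper-quartile heuristic, factors rescaled to
geometric mean 1); it reproduces edgeR's factors to five decimals on
composition-biased test matrices.

Differential expression is a two-group moderated t on log-CPM: gene-wise
pooled variances are shrunk toward a prior (d0, s0²) fitted by
method-of-moments on log variances (the inverse-trigamma construction), and
the statistic is referred to Student's t with dg + d0 degrees of freedom,
with Benjamini–Hochberg control across genes. Per-observation precision
weights (the voom construction) are *not* applied; moderation acts on
log-CPM directly, trend-free. The downstream consumers of these tables —
p-value ranks, top-k panels, signed fold changes — are robust to that
simplification, and a `weights` hook is left in the interface. Proteomic
abundance matrices bypass filtering/TMM and are median-centered per sample
before the same moderated t.

Setting `d0_policy=0` disables moderation exactly (ordinary pooled t);
`d0_policy=inf` uses the common prior variance for every gene.

## Signature derivation

The NRF2-activity signature is derived per cohort and then intersected:

1. Preliminary active/inactive labels from `call_nrf2_active`.
2. Moderated-t differential expression between the preliminary groups; the
   top 100 genes by p-value (either direction) become the classifier panel.
3. A nearest-centroid classifier on that panel: per-gene z-standardization
   fitted on the training samples, class centroids = mean standardized
   vectors, Euclidean distance, exact ties assigned to the inactive class.
4. High-confidence filtering: a sample is retained iff the classifier
   agrees with its mutation-defined label *and* its distance to the
   assigned centroid, measured along the inter-centroid axis, is at most
   τ·D (D = inter-centroid distance). One filtering round by default;
   `n_iter` exposes more.
5. Differential expression is refit on the retained samples.
6. Across cohorts: genes with BH-adjusted p < 0.05 and positive
   (active-up) fold change in *every* cohort are ranked by the largest of
   their per-cohort adjusted p-values (the worst cohort decides), and the
   top 100 form the signature.

**The confidence radius τ.** The source procedure states a radius of
"0.25% of the inter-centroid distance". Taken literally in the 100-gene
panel space that radius retains essentially no sample of any realistically
noisy cohort, so two readings are supported and neither is chosen silently:
distance is measured along the inter-centroid axis (which makes both scales
meaningful), the literal τ = 0.0025 is available in config, and the default
is τ = 0.25 — the reading under which the filter removes the ambiguous
mid-plane samples while keeping both classes populated.

Cross-validation is stratified k-fold and leakage-free: panel selection,
standardization, centroid fitting and confidence filtering are all repeated
inside each training fold. A paired test in the suite demonstrates the
alternative (panel chosen on the full data) inflates null accuracy.

## GSEA

Genes are ranked by the signal-to-noise ratio between mutant and control
groups, (μ₁ − μ₂)/(σ₁* + σ₂*), each σ floored at 0.2·|μ| (0.2 when μ = 0);
positive scores mean higher expression in mutants. The enrichment score is
the signed maximum deviation of the weighted running sum (hit steps
∝ |score|^p with p = 1, miss steps 1/(N − n_hits)); exact ± ties of the two
extrema resolve to the positive one, with a 1e-12 tolerance so summation
order cannot flip the sign of a symmetric profile.

Significance uses a gene-permutation null: ES of `n_perm` (default 10,000)
uniformly drawn same-size gene sets, shared across sets of equal size for a
given seed (so duplicated sets get identical statistics). NES divides ES by
the mean |ES| of same-sign null draws; the permutation p-value is the
plain Monte-Carlo estimate with the +1 correction, so its floor is
1/(n_same_sign + 1) — a deliberate simplification relative to adaptive
multilevel p-value refinement, adequate because the screen thresholds at
adjusted p < 0.05 rather than ranking extreme tail probabilities.
Phenotype permutation is not offered: it would require re-running the
differential expression per permutation and answers a different null.
A set with no same-sign null draws yields a flagged missing NES, never a
crash; p-values are never exactly 0.

## Co-occurrence statistics

Cohorts are stratified by their NRF2-pathway alteration frequency (cut at
5%); samples are pooled within stratum, and the SWI/SNF alteration
proportions of the two strata are compared with a pooled two-proportion
z-test, two-sided, no continuity correction (z² equals the uncorrected
Pearson chi-square on the corresponding 2×2 table). Pooling raw sample
counts (rather than averaging cohort frequencies) is the default because
the headline "23% vs 14%" framing of such screens reads as pooled
proportions; unweighted cohort means are available behind a flag, without a
test. The report always records its own composition (which cohorts fell in
which stratum, pooled counts).

## Synthetic cohorts

`simulate_cohort` draws read counts from a negative binomial with a common
dispersion φ (variance μ + φμ²):

    mean_gs = libsize_s · 2^(baseline_g + active_s·effect_g + subunit effects)

Defaults (the reference conditions used throughout the tests): 2,000 genes,
120 samples, 30% NRF2-active, 100 planted target genes with per-gene
effects ~ Normal(2, 0.5) log2 units, φ = 0.2, library sizes log-normal
around 5·10⁶ reads, per-gene baselines Normal(−11, 1.5) in log2 relative
abundance. Each active sample receives one pathway-consistent genomic
event (KEAP1/CUL3 nonsynonymous variant, CUL3 deep deletion, or NFE2L2
missense/amplification), so the alteration rules recover the planted labels
exactly when no confounders are simulated. Every sample also carries one
silent passenger variant so that all three evidence files list all samples
and harmonization is lossless.

Each SWI/SNF subunit has a mutation rate, an odds ratio of co-occurrence
with the active state (realized by solving the 2×2 margins for
P(mutant|active) and P(mutant|inactive)), and a direct log2 effect
(polarity × magnitude) on the planted target genes. The default subunits
are *neutral* (odds ratio 1, no effect) — directional structure is planted
explicitly, e.g. `hnsc_like_subunit_configs()` plants the head-neck-like
pattern (ARID1A: odds ratio 6 and +1 log2 on the targets; ARID1B: −1 log2)
used by the end-to-end screen tests. The screen tests use 500-sample
cohorts, matching the scale of a large tumor cohort, because confound
filtering shrinks the clean ARID1A-mutant group to a handful of samples at
smaller n. `simulate_multi_cohort` derives per-cohort seeds from the
master seed and controls how many planted genes are shared across cohorts
versus cohort-private.

**What the generator does not emulate:** mutation signatures, copy-number
segment structure, tumor purity, batch effects, gene–gene correlation, and
per-gene dispersion (a common φ is used; a per-gene extension would be the
first thing to add for more realistic power estimates). Passing tests
therefore show that the pipeline's logic and statistics behave as designed
under its own model assumptions — not that real TCGA/CPTAC effect sizes
would be recovered at these sample sizes.

A note on one validation design choice: chance accuracy for a classifier
evaluated on label-shuffled data equals 0.5 only for balanced classes (with
imbalance, a degenerate majority-leaning classifier scores above 0.5), so
the permutation-null check of the cross-validation runs on a 50%-active
cohort, where 0.5 is the exact chance level regardless of the classifier's
marginal predictions.

## Degenerate inputs and tie-breaks (summary)

* Duplicate gene rows in count input: summed (config: max/first).
* Fractional counts: rounded half-to-even with a warning.
* Sample identifiers: TCGA-looking barcodes truncated to 15 characters
  before intersection, keep-first for multi-sample patients; exact match
  otherwise.
* Zero-variance panel genes: dropped from the centroid model with warning.
* Centroid distance ties: inactive class.
* ES extremum magnitude ties: positive, tolerance 1e-12.
* Ranked-list score ties: score descending, then symbol lexicographic.
* Gene sets below 5 members after intersection with the universe: flagged,
  skipped.
* p-value floor: 1/(n_same_sign_null + 1); no p is ever 0.

## Known limitations

* limma-trend-style moderation without voom weights (see above).
* Gene-permutation null only; no phenotype permutation, no single-sample
  enrichment.
* No batch correction, covariate designs, gene-length normalization, or
  gene-symbol alias resolution.
* The two-proportion test ignores cohort as a clustering level; with few,
  large, heterogeneous cohorts a stratified or mixed-effects treatment
  would be more conservative.
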