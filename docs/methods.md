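# Methods

This note documents the models behind `serumrna`: what the synthetic-data
generator emulates (and deliberately does not), the statistical procedures,
their tunable parameters, numerical choices, and known limitations.

## Synthetic reference set

`build_default_reference(seed)` generates a miniature but structurally
faithful parental-RNA universe: nuclear rRNAs (18S 1,880 nt, 28S 2,930 nt,
5S, 5.8S) plus a 45S precursor assembled as
5′ETS–18S–ITS1–5.8S–ITS2–28S–3′ETS with random spacers; mitochondrial 12S
and 16S rRNAs; the four YRNA genes at canonical lengths (RNY1 112, RNY3
102, RNY4 96, RNY5 83 nt); 20 cytoplasmic tRNA isodecoders labelled
amino-acid/anticodon (covering Gly-GCC, Ala-TGC, the Leu and Lys
isoacceptors, and others prominent in serum tsRNA work) and 5 mitochondrial
tRNAs, all 66–77 nt bodies; 50 mature miRNAs (19–25 nt); 20 piRNAs
(26–32 nt); six other ncRNAs (sn/sno/linc/antisense stand-ins); and a
22-nt cel-miR-39-like spike-in.

Sequences are uniform-random over ACGT with **15-mer-uniqueness rejection
sampling**: every 15-mer occurs exactly once across the whole set, except
inside the deliberate 45S ⊃ {18S, 5.8S, 28S} nesting (spacer and junction
windows are checked explicitly).  Since all reads are ≥ 15 nt, any read has
at most one true source, so annotation accuracy against generator truth is
100% at exact matching and every recovery test is sharp.  This is the one
respect in which the reference is *easier* than a real transcriptome:
real tRNA isodecoders and rRNA repeats share sequence, so real-data
accuracy is bounded by genuine ambiguity that the bundled reference
removes by design.  The multi-mapping machinery (equal count splitting
across tied parents) is nevertheless implemented and unit-tested on
constructed ambiguous references.

CCA handling: `append_cca` unconditionally appends the
post-transcriptional CCA tail to a tRNA (mature coordinates count the
appended copy, even for genomically CCA-ending genes); appending twice is
an error.  All tRNA matching and tsRNA coordinates use the appended
sequence.

## Fragment mixture (healthy serum)

`default_mixture_config()` encodes the published healthy-serum landscape as
generator truth, so that annotation becomes parameter recovery:

| parameter | default | meaning |
|---|---|---|
| class proportions | rsRNA .6286, ysRNA .1497, piRNA .09, other .0586, tsRNA .0422, miRNA .0309 | library share per fragment class |
| rsRNA parent weights | 28S .88, 18S .10, rest .02 split over 5S/5.8S/45S/mt-12S/mt-16S | within-class parent mix |
| rsRNA peak model | 18S: 674–692, 897–919, 1194–1223, 1838–1862; 28S: 1336–1355, 1963–1982, 2895–2920 (equal weights, 90% in-peak) | positional expression peaks, 1-based inclusive |
| tsRNA positional model | cyto (5′ .70, inner .20, 3′ .05, 3′CCA .05); mito (.10, .70, .12, .08); 90% cytoplasmic | cleavage-subtype mix per tRNA |
| ysRNA | gene weights RNY4 .55, RNY1 .20, RNY3 .15, RNY5 .10; 5′ fraction .90 | gene and end composition |
| length distributions | discretized normals on [15, 45] nt: rsRNA N(33, 5²), tsRNA N(32, 4²), ysRNA N(30, 2²), other N(28, 6²); miRNA/piRNA/spike-in reads are full-length |

Peak fragments are drawn *entirely inside* their interval (length truncated
to the interval width); background fragments are uniform over the parent.
Consequences: (i) called peaks recover the planted intervals with Jaccard
≈ 1, and (ii) the realized rsRNA length mode sits at the width of the
narrow 28S peaks (20 nt) rather than the nominal 33 nt — a known, accepted
artifact of confining fragments to fixed intervals.  tsRNA subtype
sampling respects the classification rule below, with 5′ starts in
positions 1–3, inner fragments in [4, L−3], 3′ ends within 3 nt of the body
end, and 3′CCA ends inside the appended tail.

Not modelled: sequencing error (beyond what a 1-mismatch annotation mode
can absorb), UMIs and deduplication, adapter remnants, RNA modifications
that stall reverse transcription, and real secondary-structure-driven
cleavage preferences.  Passing tests therefore demonstrate correctness of
the *procedures*, not robustness to these real-data artifacts.

## Annotation engine

Reads are length-filtered to [15, 45] nt, collapsed to distinct sequences
(non-ACGT reads dropped with a warning), and matched ungapped, full-length,
forward-strand via a 15-mer seed index with verification.  Reverse-strand
matching is off: fragments derive from mature single-stranded parents.
The first category in the priority order with a hit claims the read; the
default order (miRNA → rRNA → YRNA → tRNA → mt-tRNA → piRNA → other →
spike-in) puts mature miRNAs first so they are never absorbed by longer
transcripts that might embed them.  Ties across parents within the winning
category split the count equally; rRNA hits are first collapsed to the most
specific mature subunit (45S counts only spacer-derived reads), so no read
is ever double-counted across the nesting.  `max_mismatch=1` is available
behind a flag (seeds from every exact 15-mer window; a single mismatch in a
read shorter than ~30 nt can evade all windows, which is accepted and
documented), with exact matching the default — short serum fragments plus
an unambiguous reference make mismatch tolerance unnecessary here.

Counting features are the field's reporting units: mature miRNA ids; tsRNA
= tRNA × reported cleavage group; rsRNA = parent × peak bin (`rsRNA-18S#3`
style, a fragment belongs to a peak when ≥ half of it overlaps the
interval, else background); ysRNA = gene × 5′/3′ (5′ = start ≤ 3).
Proportions are over annotated reads only; RPM = count × 10⁶ / annotated
total.  Fractional tie-split counts stay fractional internally and are
rounded half-even only at matrix export.

## tsRNA subtype rule

On the CCA-appended mature tRNA of body length L, a fragment [s, e] is
classified with boundary tolerance δ = 3 nt (configurable):
5′ if s ≤ δ; else 3′CCA if e ≥ L+1; else 3′ if e ≥ L−δ+1; else inner.
The partition is exhaustive and mutually exclusive (property-tested).  The
choice δ = 3 absorbs ragged cleavage ends while keeping the inner class
meaningful; reporting combines 3′ and 3′CCA, matching how serum tsRNA
classes are usually tabulated.

## Peak caller

`detect_peaks` thresholds the coverage profile at `threshold_frac` (0.25)
of its maximum, merges runs separated by fewer than `merge_gap` (10) nt,
and discards peaks narrower than `min_width` (10) nt.  Calls are invariant
to positive rescaling of the profile.  The defaults were chosen so the
planted serum profiles yield exactly four 18S and three 28S peaks; they are
ordinary plateau-calling defaults, not fitted quantities, and are exposed
as arguments.

## Differential expression

Normalization is TMM: per-sample factors from the precision-weighted mean
of per-feature log2 ratios against a reference sample (the one with the
most typical upper quartile), trimming 30% of M-values and 5% of A-values,
rescaled to geometric mean 1.  The common dispersion is a moment estimate:
per feature, φ_f = (v − m)/m² on counts rescaled to the geometric-mean
effective library size, pooled within groups; the common φ is the median of
the positive φ_f (0 if none).  This deliberately replaces the
quantile-adjusted CML estimator of the established count-model packages
with a transparent moment version; agreement is asserted against the
Poisson-limit oracle and simulation truth, not against any package's
output.

The exact test conditions on the total: counts are scaled to the common
effective size and summed per group; conditional on t = s_A + s_B, the
group-A sum follows a distribution with log-weights
`lgamma(s + n_A/φ) − lgamma(s+1) + lgamma(t − s + n_B/φ) − lgamma(t−s+1)`
(free of the NB success probability), which reduces to
Binomial(t, n_A/(n_A+n_B)) at φ = 0.  The two-sided p sums the
probabilities of all outcomes no more likely than the observed one (with a
1e-10 relative tie tolerance); p ∈ (0, 1], and a zero-total feature returns
(1, 0) by convention.  log₂FC is computed on mean RPM with pseudocount 1,
so zero groups give finite fold changes.  Significance is the field's
conventional rule — p ≤ 0.05 and |log₂FC| ≥ 1, uncorrected — with a
Benjamini–Hochberg column emitted for information only.

Numerical notes: the conditional enumeration is vectorised over s = 0..t
(t up to a few hundred thousand at the bundled depths); scale changes in a
single sample are absorbed by normalization up to the depth-dependence of
TMM precision weights (~1e-3 on proportions) and the discreteness shift of
the geometric-mean reference total (~one outcome's probability mass on p).

## Cohort simulator

Counts are simulated at the feature level (exact control of DE truth) and
expanded to reads on demand through the same fragment samplers, so
annotating an expanded library reproduces the count matrix exactly.  Per
sample, feature counts are NB with mean = library size × baseline
proportion (× 2^log2FC for planted effects in AML samples) and dispersion
φ; every library carries exactly `spike_in_count` spike-in reads.
Defaults for unpaired cohorts: 30 AML + 12 control discovery, 20 + 10
validation, libraries 40–60k reads, φ = 0.05.  The planted AML effect set
is a clean 6-feature 5′-tsRNA panel at log₂FC = +2 (anticodons Ala-TGC,
Gly-CCC, Gly-GCC, Leu-CAG, Leu-CAA, Lys-TTT) plus 14 miRNAs at ±1.2–1.3 —
many moderate miRNA markers versus few strong tsRNA markers, the structure
the marker-selection comparison is meant to exhibit.

Paired design: when `paired_bms` is set, each subject receives a latent
per-feature log-normal vector a ~ N(0, σ²) with σ = 1.2 (≈3.3-fold
subject-to-subject variation); the PBS sample uses a and the BMS sample
uses w·a + √(1−w²)·b with independent b, where w is
`bms_shared_signal_fraction`.  The latent is mean-corrected (−σ²/2) so
expectations match the baseline.  Subject-level noise is applied only in
the paired design — unpaired replicates carry exactly the NB dispersion, so
the φ = 0 Poisson limit is exact.  Paired libraries default to 200–300k
reads with residual φ = 0.02: the variance budget keeps latent signal to
residual noise at ≥ 19:1 (φ + mean_f e^{σ²}/(lib·p_f) ≤ σ²/19), so the
shared-signal knob maps onto pooled correlation over its whole range
(r ≈ 0 at w = 0, r ≥ 0.95 at w = 1).

## Marker selection and classification

A feature enters a category panel only if it (1) is significantly DE in
the discovery cohort, (2) has mean RPM > 10 across discovery samples, and
(3) is significant at α = 0.05 in a univariate logistic regression of
group on log₂(RPM+1).  The logistic model is fitted by IRLS (≤ 50
iterations, tolerance 1e-8); complete separation (|slope| > 20 or
divergence) is flagged and treated as maximally significant — a perfectly
separating marker is the best possible candidate, so flagged features are
retained with the flag propagated.  The significance filter uses the
**likelihood-ratio** p rather than the Wald p: the Wald statistic is
non-monotone near separation (Hauck–Donner effect) and would silently
discard exactly the strongest markers (a near-separating planted marker
can draw Wald p ≈ 0.3 with slope ≈ 10); both p-values are computed and
reported.

Panels are evaluated with a bootstrap-aggregated tree ensemble
(scikit-learn's random forest: 500 trees, √(panel size) candidate features
per split, OOB scoring; the contract — bagging, sqrt-splits, OOB votes —
is what the tests pin down, not a particular implementation's trees).
Discovery-side performance uses OOB scores (a sample is scored only by
trees not trained on it); validation cohorts are disjoint by construction
(overlapping sample ids are an error) and validation labels can influence
neither selection nor training (tested by mutation).  AUC is the
Mann–Whitney form, P(score_case > score_control) + ½P(tie), computed by
ranks.  An empty panel (e.g. in a no-effect simulation) yields a
chance-level report (AUC 0.5) rather than an error.

## Compartment concordance

Paired profiles are compared on log₁₀(RPM+1); features detected in fewer
than half of the paired samples are dropped to avoid zero-inflation
artifacts.  Two correlations are reported.  The per-subject r on raw log
expression matches what a paired scatter plot shows, but it is inflated by
the feature-abundance baseline that both compartments share by
construction (rsRNA ≫ miRNA spans orders of magnitude), so it cannot
distinguish shared subject-level biology from shared reference anatomy.
The headline pooled r therefore centers each feature within each
compartment before pooling (feature, subject) deviations: it is ≈ 0 when
compartments are independent and → 1 as they share their full latent
profile, and it is the quantity tested against the generator's
shared-signal fraction.  Both views, plus the uncentered pooled r, appear
in the output tables.

## Problem sizes

Composition/characterization analyses use 100,000 reads; DE and signature
stages use 42 + 30 simulated libraries of 40–60k reads; concordance uses 12
paired subjects at 200–300k reads; the null calibration of the exact test
uses 5,000 features.  These sizes make every stage run in seconds on one
CPU while keeping Monte-Carlo error well inside the recovery tolerances
(e.g. class-share standard error ≈ 0.15 pp at n = 100,000).

## Known limitations

- The k-mer-unique reference removes the multi-mapping ambiguity that
  dominates real tRNA/rRNA fragment annotation; real-data accuracy will be
  lower for reasons the synthetic tests cannot surface.
- The common-dispersion moment estimator is biased upward under pure
  Poisson data (median of positive estimates) — negligible at bundled
  depths but visible at very low counts.
- The 1-mismatch mode can miss short reads whose mismatch hits every
  15-mer window.
- No gapped or spliced alignment and no genome-wide fallback: reads
  missing from the curated sets are reported unannotated.
- Peak calling is a plateau rule on depth; it does not deconvolve
  overlapping peaks and its defaults assume peaks well above background.
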