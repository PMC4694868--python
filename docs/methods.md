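# Methods

This note documents the models, conventions, and numerical choices behind
`ertarget`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Peak comparison

Peaks are upstream peak-caller output: intervals with a summit, a
tag/pileup intensity, a raw p-value, and a false-discovery rate on the
percent scale. Peak calling itself is out of scope; the package starts
from called peaks.

**Coordinates.** All internal coordinates are 0-based half-open. BED input
is read natively; the MACS-style tab-delimited dialect has 1-based
inclusive starts and summits, which are decremented on read. When a
dialect carries no summit, the interval midpoint is used.

**Significance filter.** Peaks with FDR ≤ 0.5% (inclusive) are kept per
condition. The FDR field is treated as a generic percentage; whether an
upstream caller reports an empirical FDR or a q-value does not change the
filter's semantics.

**Normalization.** Intensities are scaled linearly by
`scale_to / library_size` (counts-per-common-depth). This is the minimal
depth correction for comparing two libraries; no background or
composition correction is attempted. A peak set refuses to be normalized
twice, so a ratio can never silently mix scales.

**Overlap.** Two sites are *common* when `min(endA, endB) − max(startA,
startB) ≥ 1`; abutting half-open intervals are unique. A peak overlapping
several opposite-condition peaks contributes one pair per partner but is
counted once in totals, so common + unique counts always partition each
set. The implementation uses an interval tree; tests assert exact
agreement with an all-pairs enumeration.

**Resistant-associated sites.** Common pairs keep the resistant-side peak
when the normalized intensity ratio resistant/responsive is ≥ 0.9
(inclusive): the resistant condition retains at least 90% of the
responsive-condition signal. Resistant-unique sites have no denominator;
they are included by default on the reading that a site present only in
resistant cells trivially exceeds any fraction of an absent signal. The
`include_unique` flag exposes the stricter common-only behaviour.

**TSS annotation.** Distances are measured summit-to-TSS, signed
strand-aware (upstream of the gene is negative), and the ±20 kb window is
inclusive. The summit is the anchor because it estimates the binding
point; interval edges depend on peak-width heuristics of the caller.
Nearest-TSS ties (for the distance histogram) break to the
lexicographically smaller gene id for determinism.

**ERE scanner.** Consensus-with-mismatches only, both strands, `N` in the
subject never matches. The default consensus is the canonical 13-bp
palindromic core GGTCANNNTGACC; the scanner accepts any IUPAC string, and
reverse-strand hits are reported at forward coordinates. No PWM scoring
and no de-novo discovery.

## Expression integration

Differential expression between the resistant and responsive cell lines
uses Welch's unequal-variance t-test on log2 values with
Benjamini–Hochberg adjustment across all genes (the standard reading of
"FDR adjusted"). Fold change is `2^(mean_A − mean_B)` with the resistant
condition in the numerator.

A gene becomes a candidate when any of its annotated sites is
resistant-associated and its expression passes both filters. Boundary
semantics mirror the stated cutoffs: fold change inclusive (≥ 1.2),
adjusted p strict (< 0.05). The fold-change filter is two-sided by
default (`max(fc, 1/fc) ≥ 1.2`) because both up- and down-regulated
targets are biologically relevant; a one-sided flag exists. Candidate
provenance records supporting peak count and the best intensity ratio.

The pipeline order is fixed: FDR filter → normalize → overlap → ratio →
annotate → expression filter. Genes need a surviving peak only in this
funnel sense; no requirement is imposed that the same site pass the FDR
filter in both conditions beyond what the overlap stage implies.

## Survival statistics

**Cox score.** The ranking statistic is the univariate partial-likelihood
score statistic at β = 0 with Breslow tie handling, `s = U/√I` (risk sets
`R_i = {j : t_j ≥ t_i}`). It is implemented with suffix cumulative sums
over time-sorted patients, vectorized over genes (O(G·n log n) rather
than the O(G·n²) double loop); tests require agreement with the double
loop to 1e-10 and with numerical derivatives of the Breslow partial
log-likelihood. Under the null, s is asymptotically N(0, 1), which is why
a fixed cutoff such as 2.39 (two-tailed tail mass ≈ 0.0169) is usable for
gene selection. Expression is z-scored per gene before scoring (flag to
disable) so the cutoff is comparable across genes; the cutoff applies to
|s| and both signs are reported, a negative score marking a protective
gene. Constant genes return a flagged score of 0; cohorts without events
are an error.

**Stratification.** Single genes: median split, values equal to the
median go to the low group (deterministic; the common "≤ median"
convention). Gene panels: k-means with k = 2 on per-gene standardized
expression, 20 restarts under a caller-supplied seed; the cluster with
the lower Kaplan-Meier survival at the last event time shared by both
clusters is labelled high-risk (the log-rank p does not depend on the
labelling). The clustering function takes the survival columns for this
labelling step.

**Comparison.** Kaplan-Meier product-limit curves are evaluated at
distinct event times; all-censored data yield the constant curve 1. The
two-group log-rank statistic is the squared sum of hypergeometric
deviations over event times divided by the summed variances, referred to
chi-square with 1 df; zero total variance (every event alone in its risk
set) gives p = 1 by convention. P-values are two-sided and reported
nominally — no multiplicity correction across genes or subgroups, because
the analysis reports per-comparison evidence, not a family-wise claim.

**Subgroups.** ER/HER2 subgrouping keeps patients matching every
constrained axis; unknown status on a constrained axis excludes the
patient (an unknown cannot be asserted to match). OS and DFS are the same
computation on different time/event columns; the endpoint is metadata and
never inferred.

## Synthetic data

The generator gives every stage inputs with known planted truth;
downstream recovery tests read the truth tables rather than re-deriving
them.

- **Genome**: genes uniform per chromosome with ≥ 50 kb spacing (sorted
  uniforms plus fixed offsets, so the gap is guaranteed by construction),
  strands Bernoulli(1/2). Defaults: 500 genes on three 30-Mb chromosomes.
- **Peaks**: common sites occupy identical intervals in both conditions
  (the ≥ 1 bp rule then classifies them common by construction); all
  intervals are mutually disjoint so the planted common/unique counts are
  recovered exactly. A configurable fraction of summits is drawn
  Normal(TSS, σ = 1 kb); the rest are uniform background. Responsive-side
  intensities are log-normal; resistant-side intensities are the
  responsive value times a planted or random ratio. A configurable
  fraction of peaks draws an FDR above the 0.5% cutoff.
- **Discovery fixture**: 10 genes planted to pass every filter (TSS-proximal
  common peak, ratio 2.0, passing FDR, expression shift) among 40 decoys
  failing exactly one filter each — FDR, ratio (0.5), annotation window
  (summit 25 kb out), or expression (no shift). Background peaks are kept
  21 kb clear of all chosen genes so a decoy cannot pass through an
  accidental second site.
- **Cell-line expression**: log2 scale, per-gene baseline Normal(7, 1),
  within-condition noise σ = 0.1 with 5 replicates per group; planted
  genes shift the resistant condition by log2(3.4) ≈ 1.77 — the fold
  difference of the flagship resistant-condition target. At these
  settings the planted Welch t is ≈ 28, so planted genes pass the
  expression filter by construction rather than by margin.
- **Cohort**: expression stored as standard-normal log values; event times
  exponential with hazard `h0·exp(Σ β_g z_g)` over planted genes
  (`h0 = 0.1`); censoring is an independent exponential whose rate is set
  from the target censored fraction f via `c = h0·f/(1−f)` (exact under
  the null, approximate under planted effects; the empirical fraction
  stays within a few points of f for the βs used). Defaults mirror a
  TCGA-like cohort: n = 570, ER+ prevalence 570/779, HER2 +/−/unknown
  counts 88/318/164 among ER+ patients. Receptor statuses are allocated
  with exact largest-remainder counts and then seed-shuffled — not
  sampled multinomially — so planted subgroup sizes are recovered
  exactly; statuses are independent of survival by default.

All randomness derives from a single integer seed through named
`SeedSequence` streams (stream names hashed with CRC-32, not Python's
salted `hash`), so a seed fully determines every output including fixture
bytes.

**What the synthetic tests do not show.** The generator makes no attempt
to model read-level noise, peak-width/shape biases, probe effects,
microarray normalization, batch effects, copy-number confounding,
non-proportional hazards, or informative censoring. Passing tests
demonstrate that the pipeline's logic and statistics are correct under
their stated assumptions, not that the biological findings transfer to
any real cohort. Real-data headline figures (counts of genes surviving
each filter, cohort p-values) depend on unpublished primary data and
external patient cohorts and are out of scope.

## Problem sizes and tolerances

Oracle-equivalence tests run 20 random instances per operation at n up to
500 (exact agreement for classifications, ≤ 1e-10 for floating
statistics). Null calibration uses 1000 log-rank replicates at n = 200
and 5000 null genes for the Cox tail; parameter recovery uses 100 cohorts
of n = 400 at ~30% censoring with one β = −0.5/SD gene among 500. The
full suite runs in well under a minute; the acceptance script in a few
seconds.

Known numerical edge cases: zero-variance genes in both expression groups
map to p = 1 (equal means) or the smallest representable double (distinct
means, off-scale evidence); log-rank and chi-square p-values are clamped
away from exact 0 so the (0, 1] invariant holds; survival times are
floored at 1e-9 to preserve positivity.
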