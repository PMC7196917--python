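# Methods

## Overview

`lofpipe` classifies tumor samples by whether their transcriptome shows
coordinated downregulation of a loss-of-function (LoF) marker gene set —
the expression signature left behind when a transcription factor such as
HNF1A stops working — and integrates that phenotype call with mutation
status, transcription-factor/chromatin binding, motif content, and
immunohistochemistry scores. Every stage can be exercised on synthetic
cohorts with known ground truth, so the whole pipeline is testable without
any external download.

## Per-sample ranking and phenotype classification

Each sample s of a linear-scale expression matrix x (genes × samples) is
ranked against the cohort by

    score(g) = log2((x[g, s] + c) / (median_t x[g, t] + c)),

with pseudocount c = 1 by default (the pseudocount avoids infinities on
zero counts; the source analyses do not state one, so it is an explicit,
configurable choice). Ties in the descending score order are broken by
gene id, making the ranking fully deterministic.

The LoF gene set is then scored by preranked GSEA (below). The sample is
labeled

* **LoF** if NES < 0 and nominal p < α (default α = 0.05),
* **Control1** if NES < 0 and p ≥ α,
* **Control2** if NES ≥ 0.

NES = 0 (including the undefined-NES fallback when no same-sign null value
exists) is assigned to Control2 and p = α exactly to Control1, so the
three labels always partition a cohort; the published rule covers only the
strict inequalities and these boundary conventions extend it totally.

## Preranked GSEA

The enrichment score is the weighted Kolmogorov–Smirnov-like running sum:
walking down the ranked list, set members advance the sum by
|score|^w / Σ_set |score|^w (w = 1, "weighted") and non-members retreat it
by 1/(N − N_hit); ES is the extremum of largest absolute deviation, signed,
with the positive side taken on an exact tie. The leading edge collects
set members at or before the extremum (at or after, for negative ES).

A single-sample ranked list admits no phenotype-label permutation, so the
null is built from uniformly random gene sets of the same size ("gene-tag"
permutation), each scored by the same statistic. NES divides ES by the
mean |ES| of same-sign null draws; the nominal p is the same-sign tail
with add-one smoothing, p = (b + 1)/(m + 1), which can never return 0.
FDR q values follow the sign-stratified pooled-NES procedure: within each
sign, q = (fraction of pooled permuted |NES| ≥ |NES*|) / (fraction of
observed |NES| ≥ |NES*|), clipped to 1 and monotonized from the most
extreme set downward. Per-set null seeds derive from the user seed plus a
CRC-32 of the set name, so results are reproducible and invariant to the
order gene sets are supplied in. 10,000 permutations is the default for
standalone GSEA; the cohort classifier defaults to 1,000 per sample, which
resolves p down to ~10⁻³ — ample for an α of 0.05 — at an acceptable cost
for hundred-sample cohorts.

Set members absent from the ranked list are dropped (the count is
reported). Permutation ES values are computed in vectorized batches of
2,048 to bound peak memory.

## Mutation rules and association

A mutation record (type, functional-impact annotation) is a putative LoF
mutation if it is a small deletion/insertion or single-base substitution
of "high" functional impact, or a structural variant annotated as
loss-of-function; other mutations are "unknown"; absence is wildtype.
The phenotype-mutation association is the two-sided Fisher exact test on
{LoF class vs all others} × {LoF mutant vs not}; unknown-consequence
mutations count as "not", because the association concerns putative
loss-of-function alleles only.

## Extreme-decile contrast

Samples are split into the bottom and top deciles of one gene's expression
with group size ⌈n/10⌉ — the only rule consistent with 33-sample groups
out of a 328-sample cohort — with boundary ties resolved by sample id.
Per gene the contrast is log2((mean_low + c)/(mean_high + c)) (mean-based;
median-based would be an equally defensible choice but one had to be
fixed). Query sets are compared to a control set by Kruskal–Wallis over
the per-gene contrasts, and per-set concordance is the fraction of member
genes individually different between the groups (two-sided Mann–Whitney,
nominal p < 0.05) in the expected direction.

## Regulatory-genomics layer

Coordinates are BED convention (0-based, half-open) throughout. The
distance between a peak [s, e) and a TSS at p is max(0, s − p, p − e); a
peak is an active **promoter** iff that gap is ≤ 1,000 bases for some TSS
(measured from the peak edge; summit-based distance is a valid alternative
the sources leave open), all remaining active peaks are **enhancers**.
Closest-gene assignment minimizes that gap, breaking exact ties by
leftmost gene start and then gene id; it is validated against an all-pairs
brute-force minimizer.

Binding-vs-expression enrichment is the Fisher exact test on bound/unbound
× in-class/out-of-class over an expressed-gene background
(log2 basemean > 2.5, strict); the odds ratio is ad/bc with the Haldane
0.5 correction on zero cells, flagged. Functional binding sites are TF
peaks whose assigned gene is significantly downregulated (q < 0.05 and
log2FC < 0).

Signal aggregation divides a ±flank window around each region's midpoint
(⌊(start+end)/2⌋) into fixed bins (10 bp default) and takes the
length-weighted mean of the coverage track per bin via an exact
antiderivative of the step function, so total signal is conserved to
floating-point precision. Bins extending beyond chromosome bounds take
value 0 and are flagged rather than dropped, keeping the matrix
rectangular. Per-region fold changes first scale both tracks to equal
genome-wide totals (removing depth differences), then report
log2((mean_a·s_a + c)/(mean_b·s_b + c)), c = 0.1.

Differential binding uses a deliberately simple exact surrogate for
negative-binomial machinery: replicate counts are pooled per condition and
each region's condition-A count is tested against the library-size-expected
A fraction by a two-sided exact binomial test, with Benjamini–Hochberg
adjustment and significance at q < 0.05. This captures strong, consistent
differences but, lacking a dispersion model, is anti-conservative when
biological replicate variability exceeds counting noise; its tests are
property-based (null behavior, antisymmetry, extreme-region detection)
rather than tied to any published region count.

## Motif scanning and enrichment

PWMs (JASPAR format via Biopython) are converted to log-odds matrices
against their own background distribution, with probabilities floored at
1e-4 before the log. Both strands of the central ±250 bp of each region
are scanned; a position is a hit when its score reaches a threshold
fraction (default 0.8) of the maximal attainable score — external scanners
delegate thresholds similarly, and the fraction is configurable. Positions
containing N never score. Region-level enrichment is the one-tailed
binomial upper tail of the motif-positive region count against a
background probability, supplied directly or estimated by scanning
background regions; the "union" coverage of several motifs is the fraction
of regions hit by any of them.

## Immunoreactive score

IRS = staining intensity (0–3) × proportion score (0–4), range 0–12.
Proportion bins: [0,1) → 0, [1,10) → 1, [10,50] → 2, (50,80] → 3,
(80,100] → 4; the published bins overlap at exactly 50%, which is assigned
to the lower bin here, and the nominal 9→10% gap is closed by the
half-open bins. Cases average their cores' IRS; the group bins are
extended continuously for fractional means ([0,2) negative, [2,4) weak,
[4,9) moderate, [9,12] strong). Grade association drops undetermined (Gx)
cases and applies the Pearson chi-square test without Yates correction;
zero-margin columns are removed (flagged) before computing degrees of
freedom.

## Statistical primitives

The two-sided Fisher p follows the probability-mass rule (sum of
fixed-margin tables no more probable than the observed one, with 1e-7
relative slack against floating-point ties), matching standard statistical
environments. The Mann–Whitney test is exact (full null distribution) when
both groups have ≤ 8 tie-free observations and the tie/continuity-corrected
normal approximation otherwise; Kruskal–Wallis carries the tie correction
with a χ²(k−1) approximation. Benjamini–Hochberg is step-up with enforced
monotonicity, input order preserved. All primitives are wrappers around
scipy fixing these conventions; the test suite checks each against an
independent enumeration or direct-formula oracle.

## Synthetic-data generators

The generators are first-class, tested code that defines the study
conditions for every downstream check.

**Cohort** (`gen_cohort`): per-gene baseline log2 means uniform on
(3, 10); sample values Normal(baseline − effect·1[LoF ∧ gene ∈ set],
noise_sd) in log2 space, then exponentiated. Defaults: 120 samples, 1,000
genes, LoF fraction 0.2 (⌈·⌋ rounded count, membership drawn by seed),
set size 100, effect 1.0 log2, noise SD 0.5, mutation penetrance 0.19 in
LoF samples vs background rate 0.02 — the rates implied by the published
19%-vs-2% association. This is the simplest model with the structure the
classifier assumes; it has no tumor purity, library-size, dropout or
gene-gene correlation structure, so passing recovery tests demonstrates
that the statistical machinery is correct, not that real cohorts are this
easy.

**Landscape** (`gen_regulatory_landscape`): genes on a regular grid of a
10-Mb synthetic chromosome "chrS"; TF peaks at a random gene subset,
placed within ±500 bp of the TSS (promoter-like) or 2–4 kb away
(enhancer-like) per the promoter fraction — geometry chosen so closest-gene
assignment provably recovers the planted bound set; active-chromatin peaks
cover TF peaks plus extra unbound-gene peaks. Downregulation probabilities
for bound/unbound genes solve the configured odds ratio and overall down
fraction exactly (Brent root-finding on the mixture constraint). Coverage
is emitted as 10-bp fixed-step bedGraph over peak neighborhoods with
track A doubled at functional peaks.

**Motif regions** (`gen_motif_sequences`): background bases i.i.d. from
the PWM's background; with the given insertion probability one instance,
sampled position-wise from the PWM, is planted at a uniform offset and
random strand. **TMA** (`gen_tma_cases`): grades G2/G3/Gx at 0.50/0.45/0.05;
core intensity is a rounded, clipped Gaussian whose mean rises by the
grade effect in G3 cases; percent-positive increases with intensity.

All generators are byte-deterministic for a fixed config and seed, and
their GroundTruth records only reference generated identifiers.

## Problem sizes in the test suite

The suite exercises the classifier at 120-sample cohorts with 1,000
permutations per sample (recovery), a 200-sample null cohort
(calibration), 100 landscape replicates (odds-ratio CI coverage), 50,000
permutations against the exhaustive 56-subset enumeration at N = 8, an
exhaustive Fisher check over all ~40,000 2×2 tables with total ≤ 30, and
200 TMA replicates for chi-square null calibration. These sizes give the
binomial/KS acceptance bounds comfortable power while keeping the whole
suite around a minute of CPU.

## Known limitations

* The gene-tag permutation null ignores gene-gene correlation, as does
  preranked GSEA generally; nominal p values are exact only under the
  independent-ranking null.
* The differential-binding surrogate has no dispersion model (above).
* The Mann–Whitney exact path is limited to ≤ 8 per group without ties.
* The cohort generator's noise model is a calibration choice, not a claim
  about any real tumor cohort.
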