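# Methods

## The locus model

The package models a tandem segmental duplication of two repeat units, A
(proximal) and B (distal), each `unit_length` bp (default 16,000, the size
of the distal analysis window of the FCGR-type locus that motivates the
design). The two references differ only at paralog sequence variants
(PSVs); with divergence 0.015 the generator places `round(0.015 × 16000)
= 240` PSVs uniformly at random without replacement, giving 98.5% pairwise
identity. An optional `psv_desert` interval with down-weighted sampling
emulates PSV-poor regions; it is off by default because every downstream
property is already exercised by the uniform design.

Structural alleles are unit lists whose units are mosaics of A/B-sourced
segments:

* normal allele: `[A, B]`;
* NAHR deletion at breakpoint *b*: one chimera, A-source on `[1, b]`,
  B-source on `(b, L]`;
* NAHR duplication at *b*: `[A, chimera, B]` with the middle unit the
  reciprocal chimera (B then A). The middle-unit convention is configurable
  (`duplication_middle`), since only the single-switch structure, not its
  phase, is observable in mismatch profiles;
* gene conversion: a tract's source overwritten by the donor paralog.
  Overlapping tracts on one unit are rejected; an empty tract
  (`end == start − 1`) is an explicit no-op.

Breakpoints of the two deletion classes are drawn uniformly inside two
hotspot intervals at fixed unit fractions (proximal ≈ [2800, 4000], distal ≈
[12200, 13400] at L = 16,000). The region strictly between the hotspots is
the *deletion-determining region*: a distal-breakpoint chimera is A-source
there (called **B_deletion** — the B-identity copy of the region is lost),
a proximal-breakpoint chimera is B-source there (**A_deletion**).

## aCGH probe response

For sample *i*, probe *p* at unit position *x* with design paralog *T*, let
*m* be the number of units across both alleles whose source at *x* is *T*
and *u* the number of other-paralog units. The simulated log2 ratio is

    log2( max(m + γ·u, floor) / (2 + 2γ) ) + β_cohort + ε,   ε ~ N(0, σ²)

with cross-hybridization weight γ (default 0.3), noise sd σ (default 0.15
log2 units), and floor 0.05 effective copies guarding the logarithm for
homozygous deletions at γ = 0. The reference diploid (2 A + 2 B units)
scores exactly 0 at every probe for every γ; at γ = 1 probes lose all
paralog discrimination (only m + u matters), which is the symmetry limit
used to test that the classifier correctly refuses to call.

The probe panel has 33 probes, of which 20 lie strictly between the
hotspots (the discriminating subset) and 13 flank them; design paralogs
alternate A/B.

## Cohort design

`CohortDesign` fixes the study conditions of a simulated case/control
cohort (defaults in parentheses):

* n = 400 samples, half cases; cases belong to the "RA" cohort, controls
  split between "58C" and "NBS"; non-reference cohort intensity offsets are
  drawn once per run from N(0, 0.04) and recorded in the report.
* heterozygous B-deletion carrier frequency 0.025 among controls; case
  carrier odds = 1.6 × control odds (the generating odds ratio);
* heterozygous A-deletion 0.012 and duplication 0.08 carriers,
  status-independent. The duplication rate reflects that duplication
  alleles at tandem-duplication loci of this kind are common (of order 10%
  carrier frequency), and matters structurally: the three-component mixture
  needs genuine loss/normal/gain mass to attach its components to;
* homozygous B-deletion 0.002 — of the order implied by Hardy–Weinberg for
  a ~1–5% deletion allele. Because that expectation is below one sample at
  n = 400, two homozygotes are additionally planted so the
  homozygote-exclusion step is always exercised;
* 10 B-type and 5 A-type heterozygous carriers of known truth are planted
  as the first samples — the synthetic counterpart of validation samples
  typed by an orthogonal paralog-ratio assay. Their truth labels are used
  only to score the classifier, never during fitting.

## Paralog assignment and profiles

Identity is the fraction of matching aligned bases over the placed span;
contigs are assigned to the higher-identity paralog, with spans under 400 bp
excluded and exact ties labelled ambiguous (a tie is informative — it marks
PSV-free sequence — so it is not broken arbitrarily). Synthetic contigs
carry truth placements; a 32-mer exact-match anchor placement is provided
for label-free use. Gapped alignment is out of scope: the generator emits
substitution errors only, and an erroneous base at a PSV matches neither
paralog and lands in the `other` state, which switch detection ignores.
Overlapping placed alignments are reduced to a maximum-total-span subset by
weighted interval scheduling (exact DP, order-invariant).

## Switch detection and event classification

Only informative (A/B) PSV states are scanned. Maximal runs shorter than
`min_run` (default 2) are masked — one discordant PSV is indistinguishable
from noise — and surviving same-state neighbours merge; each boundary
between surviving runs is a switch whose interval spans the last PSV of one
run to the first of the next. The true crossover lies strictly inside that
open interval, so the interval always contains the generating breakpoint
for error-free input.

An even number of switches parses entirely into conversion pairs; an odd
count leaves exactly one NAHR breakpoint. Which switch is the breakpoint is
ambiguous from the profile alone; the parser chooses the parse minimizing
the total length of called conversion tracts, on the grounds that
conversion tracts are kilobase-scale while chimera halves are much longer.
Interior tracts are always reported as conversions (the double-crossover
reading is noted, not called). Each conversion reports two intervals: the
inner donor-PSV span (contained in the true tract) and the outer interval
out to the flanking acceptor PSVs (containing the true tract). Within one
sample, PSVs with conflicting informative states across contigs — e.g. a
conversion on the homologous chromosome obscuring a breakpoint region — are
masked before detection and reported separately.

Two breakpoint alleles are `consistent_IBD` only if their intervals are
identical and every shared informative flanking PSV state agrees;
otherwise they are `distinct` (recurrence / identity-by-state). A/B group
separability of realized sequences is summarized as mean between-label over
mean within-label Hamming distance; an undefined ratio (zero within-group
distance) is reported as not separable rather than inventing a value.

## Copy-number calling

PC1 of the column-mean-centered sample × probe matrix (probes equally
weighted, no rescaling) is oriented so that it correlates negatively with
the per-sample mean log2 ratio: deletions score high. Calls come from a
three-component univariate Gaussian mixture with an additive cohort mean
offset (reference cohort fixed at 0), fitted by EM with coordinate-wise
M-steps (means, then offsets, then variances — an ECM scheme whose
observed-data log-likelihood is non-decreasing, asserted in tests).
Numerical choices: k-means initialization, 10 restarts (best likelihood
wins), convergence at log-likelihood gain < 1e-8, at most 500 iterations,
sd floor 1e-4; a restart that collapses a component is discarded and an
error raised only if all restarts collapse. Components ranked by mean give
gain < normal < loss; the call is the argmax responsibility and calls with
posterior below 0.5 are flagged uncertain.

The pipeline additionally requires the loss and normal components to be at
least 2 pooled sd apart; otherwise the "loss" component is a split of a
single cluster (as in a cohort without deletions), its calls are suppressed
with a warning, and downstream stages abort gracefully.

## Deletion-type classification

Deletion-called samples are filtered for homozygotes by a strict PC1
threshold (scores exactly at the threshold are kept). The published-scale
value 3.8 is data-scale-specific, so the default mode derives the cutoff
from the fitted mixture: with heterozygote displacement d = μ_loss −
μ_normal, homozygotes are expected near μ_normal + 2d, and the cutoff is
placed halfway, μ_loss + d/2. The remaining heterozygotes are re-projected
on PC1 of the 20 discriminating probes only, and a two-component mixture
with case/control status as the offset factor splits them. The larger
component is labelled B_deletion (the majority class in the emulated data);
supplying anchor samples of known type overrides the majority rule by
maximizing anchor agreement.

Separability requires both a component gap of at least 1 pooled sd and a
two-component BIC below the one-component BIC on the same scores; the BIC
clause is what catches the γ = 1 limit, where EM happily splits the single
unimodal cluster into two nearby components. Non-separable fits warn and
flag every call low-confidence.

## Exact association

Carrier status (B-deletion calls) against case/control status forms a 2×2
table. The two-sided Fisher p uses the point-probability rule (sum of
hypergeometric probabilities not exceeding the observed table's), matching
the standard R convention; the computation is delegated to scipy, which is
log-space safe at n ≈ 5,000. The confidence interval inverts the tails of
the noncentral hypergeometric distribution (lower bound: P(X ≥ x) = α/2;
upper: P(X ≤ x) = α/2) via Brent root-finding on log ψ, and the conditional
MLE solves E[X | ψ] = x. Both the sample cross-product OR (with a
Haldane–Anscombe 0.5 correction and flag when a cell is empty) and the
conditional MLE are reported. No multiple-testing correction is applied:
the pipeline tests a single primary hypothesis; the secondary A-deletion
table can be run as a second, flagged analysis.

## What the simulation does and does not show

The generator reproduces the statistical structure the analysis assumes —
PSV-mediated paralog identity, reciprocal NAHR products, conversion tracts,
copy-number- and identity-dependent probe response with cross-hybridization,
cohort intensity offsets, i.i.d. Gaussian log-ratio noise. It does not
emulate: GC- or position-dependent probe bias, spatially correlated array
noise, quantile normalization artefacts, technical duplicates, indels or
alignment gaps in contigs, population structure in carrier frequencies, or
PSV clustering beyond the optional desert. Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
calling performance on real arrays; in particular the 100% known-carrier
concordance shows the classifier is sound when the γ/noise regime is
favourable (component gap ≫ noise), which is the regime the probe-selection
step is designed to create.

## Problem sizes

Defaults used by the tests and the acceptance script: 400-sample cohorts
for classification checks (with 15 planted known carriers), 4,000-sample
cohorts × 50 replicates for odds-ratio recovery, 100 simulated alleles for
breakpoint containment, exhaustive enumeration up to grand total 12 for the
exact-test oracles. These sizes make every result reproducible on a single
CPU in well under an hour while keeping Monte-Carlo intervals tight enough
to be informative.

## Known limitations

* The classifier types the samples it was fitted on (transductive); it does
  not project new samples onto a frozen mixture.
* The auto homozygote threshold assumes the loss component is dominated by
  heterozygotes; a cohort where homozygotes outnumber heterozygotes would
  need the explicit threshold.
* Breakpoints falling in the same inter-PSV gap are inherently
  indistinguishable; IBD classification treats them as identical.
* The odd-switch-count parsimony rule can mislocalize the breakpoint when a
  conversion tract is longer than a chimera arm; such profiles are rare
  under the default tract menu but possible.
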