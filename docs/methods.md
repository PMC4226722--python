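# Methods

This note documents the models, conventions and numerical choices behind
`isomirpipe`, and what the synthetic-data generator does and does not
emulate.

## Coordinates, offsets and notation

All internal coordinates are 0-based half-open; GFF3 I/O is 1-based
inclusive. An isomiR is identified by its arm and the signed offsets of its
two termini relative to the reference mature entry, measured in the 5´→3´
direction of the mature strand (negative = upstream). On the minus strand
the genomic end maps to the 5´ terminus, so for a mature locus `[s, e)` a
read `[rs, re)` has `off5 = e − re` and `off3 = s − rs`. Offsets are bounded
by the flank (default 6 nt, configurable), the window within which reads
must fall wholly to be assigned. The printable name renders both offsets
with an explicit sign, including `+0`, so the reference variant has the
canonical name `[5´end+0][3´end+0]`; the parser accepts hyphen, minus and
en-dash as the negative sign.

## Read filters and assignment

A read is kept when it is at least 16 nt long, maps uniquely (NH tag == 1;
secondary/supplementary records are never unique; files without uniqueness
evidence are rejected in `strict` mode or trusted in `lenient` mode), has
no insertions or deletions in its CIGAR, and has at most ⌊0.04·L⌋
mismatches (NM tag) — the floor because "no more than 4%" is an upper bound.
Assignment requires containment in exactly one same-strand window; reads
containable in two or more windows (overlapping arms) are dropped as
ambiguous and tallied, never fractionally assigned. Reads with identical
endpoints merge regardless of internal mismatches; the group's
representative sequence is the genome-templated one. Per-sample tallies
satisfy `assigned + unassigned + ambiguous + rejected + unmapped = total`.

For throughput, alignment records are memoised on
(position, span, flag, length, NM, uniqueness): small-RNA data is massively
duplicated and per-class filter decisions are exact.

## Quantile normalization and abundance filters

Normalization is the classic rank-mean procedure: each column's sorted
values are replaced by the across-column means at each rank; tied values
within a column receive the mean of their tied rank-means. Column sums are
equal afterwards; within-column ranks are preserved. With a single sample
the transform is the identity (warned).

An arm is retained only if its most abundant isomiR (by mean normalized
count over the analysis group) reaches 25 reads per sample; within a
retained arm, isomiRs are ranked by mean abundance (ties broken by
(off5, off3) for determinism) and the smallest prefix whose cumulative
share reaches 0.95 is kept. The prefix rule is iterated to a fixed point:
a single pass is not idempotent in boundary cases (dropping a negligible
tail re-expresses the remaining shares and can push an earlier prefix past
the threshold), and a filter that is its own fixed point is easier to
reason about; on realistic profiles the first pass is already stable, and
the worked rule on shares (0.70, 0.20, 0.06, 0.04) keeps the first three
either way. The per-isomiR one-sample t-test runs on log2(normalized + 1)
against a null of 0 by default; both the transform and the null are
configurable since the analysis is meaningful for several choices.

Arm summaries compare the top isomiR with the reference. The
"conservative" disagreement flag requires the top isomiR to exceed the
reference by at least log2(1.5) ≈ 0.585 log2 units on pseudocounted
(+1) normalized means; the exact constant is used rather than the rounded
0.585 so that an exactly 1.5-fold ratio qualifies. A reference whose
normalized counts are zero contributes only the pseudocount floor.

## Differential expression

Testing runs on raw counts with median-of-ratios size factors (rows
containing any zero are excluded from the geometric-mean reference; if no
row is all-nonzero the estimator falls back to total-count scaling with a
warning). The quantile-normalized layer serves reporting and filtering
only; NB machinery needs counts.

The test is a conditional exact test on the common scale: per isomiR, the
sums of size-factor-normalized counts in the two groups (rounded to
pseudo-counts `kA`, `kB`) are modeled as sums of i.i.d. NB draws with a
common per-sample dispersion α, so the group sums have dispersions α/nA and
α/nB. Conditioning on `S = kA + kB`, `P(A = a | S) ∝ f_A(a) f_B(S − a)`;
the two-sided p-value doubles the smaller tail (observed point included in
both), capped at 1. Working entirely on the common scale makes the
statistics exactly invariant to rescaling any sample together with its size
factor — a raw-count conditional test cannot satisfy that exactly, because
resequencing a sample deeper genuinely changes its shot noise; the
common-scale model absorbs residual depth heterogeneity into α instead.

Dispersion: per-isomiR method of moments on normalized counts (pooled
within-group variance minus the unit shot-noise term, over the squared
mean, floored at 1e-8), a gamma-family regression of dispersion on
1/mean as the trend (median dispersion as fallback when the regression is
degenerate), and the **maximum** of per-isomiR and fitted values as a guard
against under-dispersion. Because taking a maximum selects upward noise —
for a well-estimated row E[max(α̂, α)] = α(1 + s/√(2π)) with s = √(2/df) the
relative sd of the moment estimator — the result is divided by that factor,
which recenters the null without giving up the guard; empirically the type-I
error at p ≤ 0.05 sits inside the binomial confidence band of 0.05 in a
30-vs-30 null simulation with 2000 isomiRs.

For large pooled counts the conditional distribution is enumerated only on
a ±15-standard-deviation window around its mode (plus a 50-count margin);
the omitted mass is far below double precision. Dispersion → 0 reduces the
test to the conditional binomial (Poisson) exact test. All-zero isomiRs
get p = 1, log2FC = 0, and a flag. Log2 fold changes use normalized group
means with a +0.5 pseudocount, oriented B over A; swapping the groups
negates them and leaves p-values unchanged. BH adjustment is the standard
step-up with monotonicity enforcement; NaN p-values propagate and are
excluded from the ranking.

Known limitation: median-of-ratios assumes the changed isomiRs are a
minority with roughly balanced direction. Under strongly one-directional
composition change (e.g. 10% of rows all shifted up in one group) the size
factors absorb part of the signal into a systematic offset of the null
rows, and the false-discovery proportion degrades for *any* calibrated
test built on them. The power/FDP property simulation therefore uses
compositional counts (fixed per-sample depth — the regime sequencing data
lives in) with balanced spike directions. A second consequence of
calibration worth knowing: across a battery of ~30 contrasts each
controlled at FDR ≤ 0.05, roughly one marginal false call per run is the
expected behavior; truly differential arms are called with FDRs orders of
magnitude smaller.

## PAR-CLIP Ago-loading support

Observed distinct-species counts start at 1, so the background is a
zero-truncated negative binomial (the truncation floor is configurable for
other acquisition regimes). Parameters are fitted by maximum likelihood
over (log r, logit p) with Nelder–Mead from an untruncated
method-of-moments start; fits on fewer than 50 species, degenerate
(all-equal) data, and non-convergence are hard errors. The background is
fitted per dataset — the count needed for tail significance grows with
dataset depth — and, by default, on *all* distinct species of the dataset;
restriction to isomiR-matching species is available (`background=
"matched"`) since either convention is defensible. An isomiR is supported
when its exact-endpoint count reaches P(X ≥ c) ≤ 0.05 in at least one
dataset; endpoint matching is exact coordinate equality after strand
normalization, and PAR-CLIP alignments reduced through the calling module
enforce zero mismatches. Support fractions are reported separately for
reference and non-reference isomiRs.

## Termini profile

Each retained isomiR contributes a point (X, Y) = (off5, off3) with height
Z = its share of the arm's group-mean normalized reads, so retained shares
sum to 1 per arm. The per-group grid spans X, Y ∈ [−flank, flank] and sums
Z across arms (summation rather than averaging, so a cell's height reflects
how much arm mass sits there); marginals count unique isomiRs with 3´
changes, 5´ changes, or both. Per-sample grids are available via the
library API.

## Synthetic data generator

The generator emulates the statistical structure of a multi-population LCL
small-RNA study: non-overlapping mixed-strand precursors with one or two
mature arms on a random genome; per arm, 2–5 isomiRs on a 3´-biased offset
support always containing the reference, with a composition drawn once per
arm from a Dirichlet; arm expression weights log-normal; per-sample depths
log-uniform over 2×10⁵–2×10⁶ (a scaled-down analogue of the ~2–50 M range
of real datasets); technical replicate runs that reuse their parent's
composition and expression and redraw only depth and multinomial noise;
spiked fold changes on designated arms for designated population (and
optionally sex) groups, defaulting to one population-wide arm at log2FC 2.2
and one female-only arm at 1.75 so the sex-stratified analysis path is
exercised; a configurable decoy fraction planting one read class per
rejection rule plus out-of-window reads; and PAR-CLIP datasets whose
distinct-species counts follow a ZTNB with depth-scaled mean, in which a
designated fraction of isomiRs receives counts a safe factor above each
dataset's critical count.

Compositions are rejection-sampled to respect classification margins: the
top isomiR leads its runner-up by ≥ 1.3×, cumulative shares stay ≥ 0.04
away from the 0.95 cutoff, the top-vs-reference ratio stays ≥ 0.15 log2
away from the conservative threshold, and for a designated ~30% of arms the
reference is pinned below the retention cutoff (emulating loci where the
canonical entry is a minor species). These margins put multinomial noise
many standard deviations away from every decision boundary at desk depth,
which is what makes exact truth-table comparisons meaningful.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: inter-individual biological variability
(samples within a group share expected proportions exactly; a
`sample_noise_sigma` knob adds per-sample log-normal arm-level noise for
robustness experiments but defaults to 0), sequencing error and
non-templated 3´ additions, cross-mapping between paralogous loci,
adapter-trimming artifacts, and any dependence structure between arms. Real
data will show higher dispersions and less clean classification margins
than the defaults produce.

The default ("desk") study — 30 arms, 5 populations × 2 sexes × 6 samples,
five replicate septets, 2×10⁵–2×10⁶ reads per sample — was chosen as the
smallest scale at which every analysis path (per-sex contrasts, replicate
concordance, 95%-prefix behavior) is exercised with comfortable statistical
margins; it completes in a few minutes on one CPU. A `paper_shaped_preset`
mirrors realistic per-population group sizes (87/93/94/89/89) at the same
reduced depth for heavier experiments. All outputs are byte-reproducible
functions of the master seed.

## Numerical details

- Mismatch budget: ⌊0.04·L⌋ exactly; no rounding.
- Quantile normalization ties: mean of tied rank-means; mergesort
  (stable) ordering throughout, so results are input-order independent.
- Filter ties: (off5, off3) lexicographic; cumulative-share comparisons use
  a 1e-12 tolerance so exact boundary shares (e.g. 0.95) are kept.
- Exact-test enumeration window: mode ± (15·√(varA+varB) + 50), clipped to
  [0, S]; outside the window tails are 0/1 to double precision.
- ZTNB optimization: Nelder–Mead on (log r, logit p), xatol 1e-8,
  fatol 1e-10; likelihood evaluated on unique counts with multiplicities.
- Critical counts: bracketed from `isf`, then adjusted to the exact minimal
  count with tail ≤ α.
- Degenerate one-sample t-tests: zero variance at the null gives p = 1,
  off the null p = 0, both flagged.
- Pseudocounts: +1 on normalized means for log2 comparisons in summaries;
  +0.5 on normalized group means for DE fold changes.
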