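# Methods

## The boundary-level model

Nested TAD callers (OnTAD-style) emit hierarchies of domains whose endpoints
repeatedly coincide on the calling grid (10 kb by default).  We define a
**boundary** as the resolution-wide bin whose start equals a shared TAD
endpoint, and stratify boundaries by how heavily they are shared: for a TAD
`[s, e)`, `e` contributes to the boundary's *left*-side count (the TAD lies
to the boundary's left) and `s` to its *right*-side count.  The **level** of
a boundary is

```
level = min(4, max(left_count, right_count))
```

so a boundary used by at most one TAD per side is level 1, and anything
shared by four or more TADs on a side is level 4 ("4+").  Level 0 is
reserved for non-boundary genomic bins and for random genome controls; the
extractor never emits it.  Adjacent distinct endpoint bins are *not* merged:
the unit of analysis is the bin, and a one-bin pad (a 30 kb span at 10 kb)
is applied only when comparing boundary sets across callers or cell lines.

Two comparison radii follow from that pad.  Cross-caller consensus expands
*both* the focal and the reference boundary by one bin, so two boundaries
agree when their bin indices differ by at most `2*pad`.  The cross-cell-line
conservation score counts the cell-line sets containing a boundary within
`pad` bins of the query (including its own set), giving a score in
`1..C` for `C` cell lines.

## TFBS-clustered regions (TFCRs)

Each transcription-factor motif match (FIMO output filtered at p <= 1e-5,
collapsed to its midpoint) contributes an **unnormalized** Gaussian kernel
`exp(-d^2 / (2*sigma^2))` with bandwidth sigma = 300 bp.  The kernel is
deliberately not normalized into a probability density: the contribution of
a hit at distance 0 is exactly 1, which makes the "contributes at least 0.1"
rule an absolute per-hit threshold (radius `300*sqrt(2 ln 10)` ~ 644.8 bp)
independent of the genome-wide hit count.

The density is evaluated on a 10 bp grid (configurable; 10 bp << 300 bp
bandwidth, and tests check a per-bp brute-force oracle agrees to 1e-9)
within 4 bandwidths of any hit and is defined as 0 elsewhere.  Every strict
local maximum is a TFCR; a plateau of equal grid values yields a single TFCR
at its leftmost point, a deterministic, order-independent tie rule.  Each
TFCR records:

* **strength** — the density value at the peak (the sum of above-threshold
  contributions is recorded separately as `contrib_sum`);
* **contributors** — hits with kernel contribution >= 0.1;
* **window** — peak +/- (max contributor distance + 150 bp, half the
  bandwidth).  Windows of adjacent TFCRs may overlap and are not merged;
* **complexity** — the family-collapsed contribution sum: per TF family the
  maximum contribution among that family's hits, summed over families.
  Collapsing by the max prevents one TF's motif redundancy from inflating
  the score while preserving sensitivity to both the number of distinct
  families and their proximity.  Complexity is bounded by the number of
  contributing families and recovers a planted family count within 0.5 when
  all hits sit within ~100 bp of the cluster center.

TFCRs are ranked by complexity and split into ten equal-count classes TC0
(lowest) to TC9 (highest); ties break by genomic position, class sizes
differ by at most one, and fewer than ten TFCRs leave the classes
unassigned with a warning.  Peak positions are annotated as promoter
(within the promoter pad of a TSS), genic (inside a strand-aware,
TSS-anchored gene body), or intergenic.

## Enrichment statistics

**Fisher's exact test.**  2x2 tables are tested two-sided by the
point-probability rule: the p-value sums the hypergeometric probabilities of
all tables with the observed margins whose point probability is at most the
observed one, with a 1e-12 relative tolerance for floating-point ties.  The
odds ratio is the sample `(a*d)/(b*c)`, with +inf when only the denominator
vanishes and NaN for 0/0.  Raw per-comparison p-values are reported without
multiple-testing correction (a Benjamini-Hochberg step can be layered on by
the caller); routine Wilcoxon rank-sum and one-way ANOVA comparisons are
thin scipy wrappers provided for reports.

**Level-0 control.**  The background stratum for per-level DSB overlap
fractions is a seeded uniform sample, without replacement, of non-boundary
resolution bins matching the boundary count.  Overlap fractions default to
the core boundary bin (`pad_bins=0`); the one-bin pad is configurable.

**Anchor profiles.**  Signal around boundary centers is averaged in 5 kb
bins over +/-50 kb (20 columns).  Bins extending past a chromosome end are
flagged NaN and excluded from column aggregates.

**Genome-wide bins.**  The genome is tiled at the TAD-calling resolution.
Each bin carries: its boundary level (0 if none); an accessibility category
— 0 when the coverage-weighted signal mass is exactly zero, otherwise the
genome-wide equal-count tertile (1-3) among positive-mass bins ("equal
width" signal intervals are a documented alternative reading, not used);
the number of DSB peak intervals intersecting the bin (a peak spanning a
bin edge counts in every bin it touches — deliberate double-count
semantics); and the genes whose TSS falls in the bin, with their FPKM
values (active = FPKM > 5).

**Gene-level aggregation.**  A gene's boundary level is the maximum level of
any boundary bin overlapped by its promoter window (TSS +/- 1 kb by
default; a 2 kb pad is available by configuration), or 0.  Flagged gene
sets (repair-related, essential, housekeeping) are tested for boundary
enrichment with the exact test on (flagged vs rest) x (level >= 1 vs 0).

**Compartments.**  Per level, the fraction of boundary bins whose midpoint
lies in an A-labeled interval, with the genome-wide A fraction of labeled
bases as the control; boundaries in unlabeled gaps leave the denominator
and are logged.

## The synthetic-data generator

Real inputs (Hi-C-derived TAD calls, DNase-seq, DSB sequencing, RNA-seq)
are multi-gigabyte downloads; the generator replaces them with a coherent
genome in which every association the pipeline measures is *planted* at a
known strength:

* **Hierarchy.**  Top-level TADs of 24-60 bins tile each chromosome with
  1-3-bin gaps.  For each, `k ~ boundary_share_probs` extra nested TADs
  reuse the start endpoint (child ends confined to the parent's left half),
  making that "anchor" boundary exactly level `1+k`; `m ~
  nesting_depth_probs` interior 3-bin children tile the right half and add
  only level-1 boundaries.  Endpoint bins are distinct by construction, so
  truth comes from the structure, not from annotation, and
  `planted_level_count_moments` supplies the analytic mean/sd of the level
  histogram for recovery tests.  TAD sizes respect the 3-200-bin range of
  the upstream caller's settings.
* **Features.**  TFBS counts per bin are Poisson with level-dependent rates
  and positions normal around bin centers (sd 150 bp); DSB hits are per-bin
  Bernoulli with `logit(p) = logit(base) + log(OR[level])` so a 2x2 table
  of level-l vs level-0 bins estimates exactly the planted odds ratio (an
  interval mode emits 0.5-3 kb peaks for overlap-semantics tests);
  accessibility is gamma noise scaled by level, with a zero-inflation
  probability at level 0 so category-0 bins exist; genes are uniform except
  flagged genes, whose TSS lands in a boundary bin with the configured
  bias, and FPKM is log-normal scaled by level.

Defaults are fixed once to echo the observed shape of real cell lines
(share probabilities (0.55, 0.25, 0.13, 0.07), DSB base rate 0.15 with
odds ratios (1.5, 2, 3, 4), accessibility and expression effects
increasing with level); the `paperlike` preset instantiates seven such
"cell lines" with derived seeds.  All draws flow from one
`numpy.random.Generator` seeded by the config, so equal configs give
byte-identical files.

What the generator does *not* emulate: sequence content (no FASTA, hence no
real motif matching), Hi-C contact matrices and caller noise, correlated
replication-timing or chromatin-state structure, distance-dependent DSB
spreading, or inter-chromosomal heterogeneity.  Passing recovery tests
therefore demonstrates the pipeline's statistical machinery is correct and
calibrated, not that any particular biological effect size in real data is
reproduced.

## Problem sizes and numerical choices

Tests run on 10-90 Mb synthetic genomes with 25-200 top-level TADs — large
enough that planted odds ratios of 2-4 are recovered with median bias well
under 15% (2000 bins per arm, 100 seeds) and the level histogram falls
inside its analytic 99% envelope, small enough that the whole suite runs in
well under a minute plus a few seconds for the exhaustive Fisher
enumeration (all 46 375 tables with total <= 30, checked against
exact-integer enumeration at 1e-12).

Numerical tie-breaks are all deterministic: nearest-grid TAD snapping
rounds ties down; density plateaus resolve leftmost; TC-class ties resolve
by position; kernel sums truncate hits beyond 10 bandwidths (error
< 2e-22 per hit, far below the 1e-9 oracle tolerance).  Degenerate inputs
are defined, not special-cased: empty hit lists give empty profiles, empty
signal tracks answer 0 everywhere, a degenerate Fisher margin gives p = 1.

## Known limitations

* The conservation score is a padded-overlap count across cell lines — the
  minimal reading of cross-line "appearance"; alternative weightings are
  possible.
* The complexity formula (family-collapsed max-contribution sum) is one
  concrete instantiation of "quantity and proximity of contributing TFBS";
  ranking-based analyses (TC classes) are robust to monotone variants.
* Whether per-level overlap fractions should use padded spans is
  configurable; the default is the core bin.
* The genome-wide accessibility tertile split is equal-count over
  positive-mass bins; equal-width is a plausible alternative reading.
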