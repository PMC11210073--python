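# tadhub

Stratification of topologically associating domain (TAD) boundaries by how
many nested TADs share them, and quantification of what accumulates at the
heavily shared ones: clustered transcription-factor binding sites, DNA
double-strand breaks (DSBs), chromatin accessibility, expressed genes, and
cross-cell-line conservation.

The package is for computational genomicists who already have TAD calls
(e.g. from a nested caller such as OnTAD), DSB peak intervals, an
accessibility track, FIMO motif matches and a gene table, and want the
boundary-hierarchy analyses as a tested, scriptable library rather than a
collection of one-off notebooks.  A synthetic-data generator with known
planted parameters replaces the multi-gigabyte real inputs for testing and
demonstration.

## The model

A **boundary** is the resolution-wide bin (10 kb by default) at a TAD
endpoint.  With `L` TADs ending at a bin and `R` starting there, its level
is

    level = min(4, max(L, R))

so two adjacent TADs sharing one endpoint give a level-1 boundary, a bin
used by three TADs on its left and four on its right is level 4, and "4"
means four *or more*.  Level 0 denotes non-boundary bins and random genome
controls.

**TFBS-clustered regions (TFCRs)** are the strict local maxima of the
unnormalized Gaussian kernel density `sum_i exp(-d_i^2 / (2*300^2))` over
motif-match midpoints.  Hits contributing at least 0.1 at the peak
(within ~645 bp) define the TFCR's window (max contributor distance +
150 bp) and its **complexity**: the sum over TF families of each family's
maximum contribution.  Complexity deciles TC0-TC9 rank TFCRs genome-wide.

**Enrichment** of features across boundary strata is measured by overlap
fractions against seeded random level-0 bin controls and by two-sided
Fisher's exact tests (point-probability rule, exact hypergeometric
arithmetic), plus anchor-centered signal profiles (5 kb bins, +/-50 kb) and
a genome-wide 10 kb bin classification by boundary level x accessibility
tertile.

## Worked example

Simulate a 20 Mb genome with planted level structure, then run every
analysis stage:

```
cat > sim.yaml <<EOF
chrom_sizes: {chrS1: 20000000}
n_top_tads: 50
EOF
tadhub simulate --seed 7 --config sim.yaml --out demo/data
tadhub run-all --data-dir demo/data --out demo/out --seed 7
```

`demo/out/summary.json` from this exact invocation contains (excerpt):

```
n_tads                 133
n_boundaries           208
level_histogram        {"1": 186, "2": 11, "3": 9, "4": 2}
n_tfcrs                915
mean_tfcr_complexity   1.650311
dsb_fraction_by_level  {"0": 0.173077, "1": 0.177419, "2": 0.454545,
                        "3": 0.777778, "4": 0.0}
```

Reading it: 50 top-level TADs plus their nested children yield 133 TAD
calls and 208 distinct boundary bins, most of them level 1 — the expected
shape of a nested hierarchy.  The DSB overlap fraction rises from 17% at
the random level-0 control to 78% at level 3 (level 4 has only two
boundaries here, so its 0% is pure small-sample noise).  The accompanying
exact test confirms the gradient:

```
"level3plus_vs_random": {"table": [7, 4, 36, 172],
                         "odds_ratio": 8.361111,
                         "p_two_sided": 0.0012825441}
```

i.e. 7 of 11 level-3+ boundaries overlap a DSB peak versus 36 of 208
random bins, odds ratio 8.4, p = 0.0013 — recovering the enrichment the
generator planted.  The repair-flagged gene set shows the planted promoter
bias the same way (odds ratio 8.0, p = 0.0028).  Per-stage tables
(`boundaries.bed`, `tfcrs.tsv`, `bin_group_summary.tsv`,
`gene_levels.tsv`, DNase profile matrix) land next to the summary.

The same operations are importable directly:

```python
from tadhub import extract_boundaries, level_histogram
bset = extract_boundaries(tads, resolution=10_000)
level_histogram(bset)          # {1: 186, 2: 11, 3: 9, 4: 2}
```

## Layout

    src/tadhub/genome_io.py       BED / bedGraph / FIMO / gene-table / chrom.sizes I/O
    src/tadhub/boundary_levels.py boundary extraction, levels, consensus, conservation
    src/tadhub/tfcr.py            kernel density, TFCR calling, complexity, TC classes
    src/tadhub/enrichment.py      Fisher tests, controls, profiles, genome bins, gene sets
    src/tadhub/synthetic_data.py  planted-parameter genome simulator
    src/tadhub/cli.py             `tadhub` command and the run-all orchestration
    docs/methods.md               model, parameters, generator scope, limitations
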