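"""Association statistics between boundary strata and genomic features.

Covers per-level overlap fractions with DSB peaks and A/B compartments,
exact 2x2 enrichment tests, random level-0 genome controls, anchor-centered
signal profiles, genome-wide 10 kb bin classification by boundary level and
accessibility tertile, and gene-level aggregation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tadhub.boundary_levels import Boundary, BoundarySet, expand_boundary
from tadhub.genome_io import ChromSizes, GeneRecord, GenomicInterval, SignalTrack

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# exact 2x2 testing
# ---------------------------------------------------------------------------


@dataclass
class ContingencyTable:
    """2x2 counts; rows = in-group / out-group, columns = feature+ / feature-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError("contingency counts must be non-negative integers")
            setattr(self, name, int(v))
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is all zero")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    table: ContingencyTable
    odds_ratio: float
    p_two_sided: float
    label: str = ""


def fisher_exact(table: ContingencyTable, label: str = "") -> EnrichmentResult:
    """Two-sided Fisher's exact test by the point-probability rule.

    The p-value sums the hypergeometric probabilities of every table with
    the observed margins whose point probability does not exceed that of the
    observed table (with a 1e-12 relative tolerance for floating-point ties).
    The odds ratio is the sample ``(a*d)/(b*c)``; a zero off-diagonal gives
    +inf, and 0/0 gives NaN.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, c1, n = a + b, a + c, table.total
    if table.a * table.d == 0 and table.b * table.c == 0:
        odds = math.nan
    elif table.b * table.c == 0:
        odds = math.inf
    else:
        odds = (table.a * table.d) / (table.b * table.c)
    k_lo = max(0, r1 + c1 - n)
    k_hi = min(r1, c1)
    if k_lo == k_hi:  # a degenerate margin fixes the table
        return EnrichmentResult(table=table, odds_ratio=odds, p_two_sided=1.0, label=label)
    support = np.arange(k_lo, k_hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - k_lo]
    p = float(np.sum(pmf[pmf <= p_obs * (1.0 + 1e-12)]))
    return EnrichmentResult(
        table=table, odds_ratio=odds, p_two_sided=min(1.0, p), label=label
    )


# ---------------------------------------------------------------------------
# interval overlap machinery
# ---------------------------------------------------------------------------


class _MergedFeatures:
    """Per-chromosome merged sorted intervals for O(log n) overlap queries."""

    def __init__(self, features: Iterable[GenomicInterval]):
        raw: dict[str, list[tuple[int, int]]] = {}
        for f in features:
            raw.setdefault(f.chrom, []).append((f.start, f.end))
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        for chrom, ivs in raw.items():
            ivs.sort()
            merged = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self.starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self.ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self.starts:
            return False
        starts = self.starts[chrom]
        i = int(np.searchsorted(starts, end, side="left"))
        return i > 0 and self.ends[chrom][i - 1] > start


def fraction_overlapping(
    intervals: Sequence[GenomicInterval], features: Sequence[GenomicInterval]
) -> float:
    """Fraction of ``intervals`` intersecting at least one feature."""
    if not intervals:
        return math.nan
    merged = _MergedFeatures(features)
    hits = sum(merged.overlaps(iv.chrom, iv.start, iv.end) for iv in intervals)
    return hits / len(intervals)


def overlap_fraction_by_level(
    bset: BoundarySet,
    features: Sequence[GenomicInterval],
    pad_bins: int = 0,
    chrom_sizes: ChromSizes | None = None,
) -> dict[int, float]:
    """Per boundary level, the fraction of boundaries whose (optionally
    padded) span intersects at least one feature interval.

    The default span is the core boundary bin; the one-bin expansion used
    for cross-caller comparison is available via ``pad_bins``.
    """
    merged = _MergedFeatures(features)
    hit: dict[int, int] = {}
    tot: dict[int, int] = {}
    for b in bset:
        span = expand_boundary(b, pad_bins, chrom_sizes)
        tot[b.level] = tot.get(b.level, 0) + 1
        if merged.overlaps(span.chrom, span.start, span.end):
            hit[b.level] = hit.get(b.level, 0) + 1
    return {lvl: hit.get(lvl, 0) / n for lvl, n in sorted(tot.items())}


def random_level0_control(
    bset: BoundarySet,
    chrom_sizes: ChromSizes,
    seed: int,
) -> list[GenomicInterval]:
    """Sample ``len(bset)`` distinct non-boundary bins uniformly at random.

    The control matches the boundary count with resolution-wide bins drawn
    without replacement from bins that are not boundary bins — the "level 0"
    background stratum.
    """
    res = bset.resolution
    boundary_bins = bset.bin_keys()
    eligible: list[tuple[str, int]] = []
    for chrom in sorted(chrom_sizes):
        for idx in range(chrom_sizes[chrom] // res):
            if (chrom, idx) not in boundary_bins:
                eligible.append((chrom, idx))
    n = len(bset)
    if n > len(eligible):
        raise ValueError(
            f"cannot sample {n} control bins from {len(eligible)} eligible bins"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(eligible), size=n, replace=False)
    return [
        GenomicInterval(eligible[i][0], eligible[i][1] * res, (eligible[i][1] + 1) * res)
        for i in sorted(picks)
    ]


def enrichment_vs_background(
    group: Sequence[GenomicInterval],
    background: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
    label: str = "",
) -> EnrichmentResult:
    """Fisher's exact test of feature overlap in a group vs a background set."""
    if not group:
        raise ValueError("empty group")
    merged = _MergedFeatures(features)
    g_hit = sum(merged.overlaps(iv.chrom, iv.start, iv.end) for iv in group)
    b_hit = sum(merged.overlaps(iv.chrom, iv.start, iv.end) for iv in background)
    table = ContingencyTable(
        a=g_hit, b=len(group) - g_hit, c=b_hit, d=len(background) - b_hit
    )
    return fisher_exact(table, label=label)


# ---------------------------------------------------------------------------
# anchor profiles
# ---------------------------------------------------------------------------


@dataclass
class ProfileMatrix:
    anchors: list[Boundary]
    bin_width: int
    flank: int
    matrix: np.ndarray  # anchors x columns; NaN marks clipped bins
    aggregate: np.ndarray  # per-column mean over anchors, ignoring clipped

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"{-self.flank + j * self.bin_width}"
            for j in range(self.n_columns)
        ]
        idx = [f"{b.chrom}:{b.position}" for b in self.anchors]
        return pd.DataFrame(self.matrix, index=idx, columns=cols)


def profile_matrix(
    anchors: BoundarySet,
    track: SignalTrack,
    bin_width: int = 5000,
    flank: int = 50000,
    chrom_sizes: ChromSizes | None = None,
) -> ProfileMatrix:
    """Mean signal in fixed bins around boundary centers.

    With the defaults (5 kb bins, +/-50 kb flank) each anchor gets 20
    columns.  Bins extending past a chromosome end are flagged NaN and
    excluded from the per-column aggregate.
    """
    if flank % bin_width:
        raise ValueError("flank must be a multiple of bin_width")
    ncols = 2 * flank // bin_width
    blist = list(anchors)
    mat = np.full((len(blist), ncols), np.nan)
    for i, b in enumerate(blist):
        center = b.position + b.resolution // 2
        size = chrom_sizes.get(b.chrom) if chrom_sizes else None
        for j in range(ncols):
            s = center - flank + j * bin_width
            e = s + bin_width
            if s < 0 or (size is not None and e > size):
                continue  # clipped bin stays NaN
            mat[i, j] = track.mean(b.chrom, s, e)
    with np.errstate(invalid="ignore"):
        agg = np.nanmean(mat, axis=0) if len(blist) else np.full(ncols, np.nan)
    return ProfileMatrix(
        anchors=blist, bin_width=bin_width, flank=flank, matrix=mat, aggregate=agg
    )


# ---------------------------------------------------------------------------
# genome-wide bin classification
# ---------------------------------------------------------------------------


@dataclass
class GenomeBin:
    chrom: str
    start: int
    end: int
    level: int = 0
    dnase_cat: int = 0
    dsb_count: int = 0
    gene_ids: list[str] = field(default_factory=list)
    gene_fpkms: list[float] = field(default_factory=list)

    @property
    def mean_fpkm(self) -> float:
        return float(np.mean(self.gene_fpkms)) if self.gene_fpkms else math.nan


def classify_genome_bins(
    chrom_sizes: ChromSizes,
    resolution: int,
    boundaries: BoundarySet,
    dnase: SignalTrack,
    dsbs: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord] = (),
) -> list[GenomeBin]:
    """Tile the genome at ``resolution`` and classify every bin.

    level: the boundary level of boundary bins, 0 elsewhere.
    dnase_cat: 0 for bins with zero accessibility mass; positive-mass bins
    are split into genome-wide equal-count tertiles 1-3 (ascending signal).
    dsb_count: number of DSB peak intervals intersecting the bin — a peak
    spanning a bin edge counts in each bin it touches.
    Genes are assigned to the bin holding their TSS.
    """
    levels = boundaries.levels_by_bin()
    bins: list[GenomeBin] = []
    index: dict[tuple[str, int], int] = {}
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        for k in range(-(-size // resolution)):
            start = k * resolution
            end = min(start + resolution, size)
            index[(chrom, k)] = len(bins)
            bins.append(
                GenomeBin(
                    chrom=chrom,
                    start=start,
                    end=end,
                    level=levels.get((chrom, k), 0),
                )
            )
    # accessibility tertiles over positive-mass bins, genome-wide
    mass = np.array([dnase.mass(b.chrom, b.start, b.end) for b in bins])
    pos = np.flatnonzero(mass > 0)
    if len(pos):
        order = pos[np.argsort(mass[pos], kind="stable")]
        for rank, i in enumerate(order):
            bins[i].dnase_cat = 1 + rank * 3 // len(pos)
    for dsb in dsbs:
        if dsb.chrom not in chrom_sizes:
            continue
        for k in range(dsb.start // resolution, (dsb.end - 1) // resolution + 1):
            i = index.get((dsb.chrom, k))
            if i is not None:
                bins[i].dsb_count += 1
    for g in genes:
        i = index.get((g.chrom, g.tss // resolution))
        if i is not None:
            bins[i].gene_ids.append(g.gene_id)
            bins[i].gene_fpkms.append(g.fpkm)
    return bins


def bin_group_summary(
    bins: Sequence[GenomeBin], active_cut: float = 5.0
) -> pd.DataFrame:
    """Summarize genome bins per (level, dnase_cat) subgroup.

    Reports bin count, mean DSB density (peaks per bin), gene counts, active
    gene count (FPKM above ``active_cut``) and mean FPKM, mirroring the
    genome-wide heatmap view of DSB density versus structure/accessibility.
    """
    rows = []
    groups: dict[tuple[int, int], list[GenomeBin]] = {}
    for b in bins:
        groups.setdefault((b.level, b.dnase_cat), []).append(b)
    for (level, cat), gb in sorted(groups.items()):
        fpkms = [f for b in gb for f in b.gene_fpkms]
        rows.append(
            {
                "level": level,
                "dnase_cat": cat,
                "n_bins": len(gb),
                "mean_dsb": float(np.mean([b.dsb_count for b in gb])),
                "n_genes": len(fpkms),
                "n_active_genes": sum(f > active_cut for f in fpkms),
                "mean_fpkm": float(np.mean(fpkms)) if fpkms else math.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "level",
            "dnase_cat",
            "n_bins",
            "mean_dsb",
            "n_genes",
            "n_active_genes",
            "mean_fpkm",
        ],
    )


# ---------------------------------------------------------------------------
# gene-level aggregation
# ---------------------------------------------------------------------------


def assign_gene_boundary_levels(
    genes: Sequence[GeneRecord],
    bset: BoundarySet,
    promoter_pad: int = 1000,
) -> dict[str, int]:
    """Map each gene to the level of the boundary its promoter overlaps.

    The promoter window is TSS +/- ``promoter_pad`` bp.  If it overlaps
    several boundary bins the maximum level wins; genes whose promoter hits
    no boundary get level 0.
    """
    if promoter_pad <= 0:
        raise ValueError("promoter_pad must be > 0")
    levels = bset.levels_by_bin()
    res = bset.resolution
    out: dict[str, int] = {}
    for g in genes:
        lo = max(0, g.tss - promoter_pad)
        hi = g.tss + promoter_pad  # inclusive endpoint of the +/- pad window
        best = 0
        for k in range(lo // res, hi // res + 1):
            best = max(best, levels.get((g.chrom, k), 0))
        out[g.gene_id] = best
    return out


def gene_set_boundary_enrichment(
    gene_levels: Mapping[str, int],
    flagged: set[str],
    label: str = "",
) -> EnrichmentResult:
    """Fisher's exact test: are flagged genes enriched at boundaries?

    2x2 of (flagged vs rest) x (promoter at a boundary, level >= 1, vs level
    0), as used for repair-related and essential gene sets.
    """
    if not flagged:
        raise ValueError("empty flagged gene set")
    unknown = flagged - set(gene_levels)
    if unknown:
        raise ValueError(f"flagged genes missing from gene_levels: {sorted(unknown)[:5]}")
    a = sum(1 for g in flagged if gene_levels[g] >= 1)
    b = len(flagged) - a
    rest = [g for g in gene_levels if g not in flagged]
    c = sum(1 for g in rest if gene_levels[g] >= 1)
    d = len(rest) - c
    return fisher_exact(ContingencyTable(a, b, c, d), label=label)


# ---------------------------------------------------------------------------
# compartments
# ---------------------------------------------------------------------------


def compartment_fraction_by_level(
    bset: BoundarySet,
    compartments: Sequence[GenomicInterval],
) -> tuple[dict[int, float], float]:
    """Per level, the fraction of boundary bins whose midpoint lies in an A
    compartment, plus the genome-wide A fraction of labeled bases as control.

    Compartment intervals carry their label ("A" or "B") in the name field.
    Boundaries whose midpoint falls in an unlabeled gap are excluded from
    the denominator (and logged).
    """
    labeled = [c for c in compartments if c.name in {"A", "B"}]
    if len(labeled) < len(list(compartments)):
        raise ValueError("compartment intervals must be labeled A or B")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for c in labeled:
        by_chrom.setdefault(c.chrom, []).append(c)
    starts: dict[str, np.ndarray] = {}
    for chrom, cs in by_chrom.items():
        cs.sort(key=lambda c: c.start)
        starts[chrom] = np.array([c.start for c in cs], dtype=np.int64)
    in_a: dict[int, int] = {}
    tot: dict[int, int] = {}
    n_gap = 0
    for b in bset:
        mid = b.bin.midpoint
        cs = by_chrom.get(b.chrom)
        label = None
        if cs:
            i = int(np.searchsorted(starts[b.chrom], mid, side="right")) - 1
            if i >= 0 and mid < cs[i].end:
                label = cs[i].name
        if label is None:
            n_gap += 1
            continue
        tot[b.level] = tot.get(b.level, 0) + 1
        if label == "A":
            in_a[b.level] = in_a.get(b.level, 0) + 1
    if n_gap:
        logger.info("%d boundaries in unlabeled compartment gaps excluded", n_gap)
    fractions = {lvl: in_a.get(lvl, 0) / n for lvl, n in sorted(tot.items())}
    a_bp = sum(len(c) for c in labeled if c.name == "A")
    ab_bp = sum(len(c) for c in labeled)
    control = a_bp / ab_bp if ab_bp else math.nan
    return fractions, control


# ---------------------------------------------------------------------------
# routine comparison wrappers used in reports
# ---------------------------------------------------------------------------


def rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value."""
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def one_way_anova(*groups: Sequence[float]) -> float:
    """One-way ANOVA p-value across groups."""
    return float(stats.f_oneway(*groups).pvalue)
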