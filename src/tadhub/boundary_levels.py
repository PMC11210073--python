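"""Boundary extraction from nested TAD sets and level assignment.

A boundary is the resolution-wide bin whose start coordinate equals a shared
TAD endpoint.  Its level is the maximum number of TADs using it as an
endpoint on either side, capped at 4 ("4+"): a TAD ``[s, e)`` contributes to
the *right* side of the boundary at ``s`` (the TAD lies to the boundary's
right) and to the *left* side of the boundary at ``e``.  A boundary used by
no more than one TAD on each side is level 1; one shared by, say, three TADs
on its left and four on its right is level 4.

Level 0 is reserved for non-boundary genomic bins and random controls; it is
never emitted by :func:`extract_boundaries`.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from tadhub.genome_io import ChromSizes, GenomicInterval, TadRecord

MAX_LEVEL = 4


@dataclass
class Boundary:
    chrom: str
    bin_index: int
    resolution: int
    left_count: int
    right_count: int
    cell_line: str = ""

    @property
    def level(self) -> int:
        return min(MAX_LEVEL, max(self.left_count, self.right_count))

    @property
    def bin(self) -> GenomicInterval:
        s = self.bin_index * self.resolution
        return GenomicInterval(self.chrom, s, s + self.resolution)

    @property
    def position(self) -> int:
        """The shared TAD endpoint coordinate (= bin start)."""
        return self.bin_index * self.resolution


@dataclass
class BoundarySet:
    resolution: int
    cell_line: str
    boundaries: list[Boundary] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        self.boundaries.sort(key=lambda b: (b.chrom, b.bin_index))
        seen = set()
        for b in self.boundaries:
            key = (b.chrom, b.bin_index)
            if key in seen:
                raise ValueError(f"duplicate boundary bin {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.boundaries)

    def __iter__(self):
        return iter(self.boundaries)

    def bin_keys(self) -> set[tuple[str, int]]:
        return {(b.chrom, b.bin_index) for b in self.boundaries}

    def levels_by_bin(self) -> dict[tuple[str, int], int]:
        return {(b.chrom, b.bin_index): b.level for b in self.boundaries}


@dataclass
class ConsensusAnnotation:
    boundary: Boundary
    methods_count: int
    group: str  # level3plus | methods3plus | both | neither


@dataclass
class ConservationScore:
    boundary: Boundary
    score: int


def extract_boundaries(
    tads: Sequence[TadRecord], resolution: int, cell_line: str | None = None
) -> BoundarySet:
    """Collect distinct TAD endpoint bins and count TAD sharing per side.

    All TADs must come from one cell line / caller and be snapped to the
    ``resolution`` grid (as :func:`tadhub.genome_io.read_tads` guarantees).
    """
    left: dict[tuple[str, int], int] = defaultdict(int)
    right: dict[tuple[str, int], int] = defaultdict(int)
    cell = cell_line
    for tad in tads:
        if tad.start % resolution or tad.end % resolution:
            raise ValueError(
                f"TAD {tad.chrom}:{tad.start}-{tad.end} is not on the "
                f"{resolution}-bp grid (mixed resolutions?)"
            )
        if cell is None:
            cell = tad.cell_line
        right[(tad.chrom, tad.start // resolution)] += 1
        left[(tad.chrom, tad.end // resolution)] += 1
    boundaries = [
        Boundary(
            chrom=chrom,
            bin_index=idx,
            resolution=resolution,
            left_count=left.get((chrom, idx), 0),
            right_count=right.get((chrom, idx), 0),
            cell_line=cell or "",
        )
        for chrom, idx in sorted(set(left) | set(right))
    ]
    return BoundarySet(resolution=resolution, cell_line=cell or "", boundaries=boundaries)


def expand_boundary(
    b: Boundary, pad_bins: int, chrom_sizes: ChromSizes | None = None
) -> GenomicInterval:
    """Expand a boundary bin by ``pad_bins`` bins on each side.

    At the default 10 kb resolution, ``pad_bins=1`` yields a 30 kb span,
    the padding used when comparing boundaries across callers or cell lines.
    Clipped at 0 and, when ``chrom_sizes`` is given, the chromosome end.
    """
    if pad_bins < 0:
        raise ValueError("pad_bins must be >= 0")
    start = max(0, (b.bin_index - pad_bins) * b.resolution)
    end = (b.bin_index + 1 + pad_bins) * b.resolution
    if chrom_sizes is not None and chrom_sizes.get(b.chrom, 0) > start:
        # a boundary bin may start at the very chromosome end (a TAD ending
        # there); clipping must never produce an empty span
        end = min(end, chrom_sizes[b.chrom])
    return GenomicInterval(b.chrom, start, end)


def _hit_within(
    b: Boundary, other_bins: Mapping[str, Sequence[int]], max_delta: int
) -> bool:
    """True if ``other_bins`` holds a bin index within ``max_delta`` of ``b``."""
    bins = other_bins.get(b.chrom)
    if not bins:
        return False
    i = bisect.bisect_left(bins, b.bin_index - max_delta)
    return i < len(bins) and bins[i] <= b.bin_index + max_delta


def _bins_by_chrom(bset: BoundarySet) -> dict[str, list[int]]:
    out: dict[str, list[int]] = defaultdict(list)
    for b in bset:
        out[b.chrom].append(b.bin_index)
    for v in out.values():
        v.sort()
    return out


def consensus_annotate(
    focal: BoundarySet,
    reference_sets: Sequence[BoundarySet],
    pad_bins: int = 1,
    level_cut: int = 3,
    methods_cut: int = 3,
) -> list[ConsensusAnnotation]:
    """Count, per focal boundary, how many reference callers recover it.

    Both the focal and each reference boundary are expanded by ``pad_bins``
    bins; a reference set counts if any of its expanded boundaries intersects
    the focal expanded span.  Boundaries are then grouped by
    (level >= level_cut) x (methods_count >= methods_cut).
    """
    for ref in reference_sets:
        if ref.resolution != focal.resolution:
            raise ValueError(
                f"resolution mismatch: focal {focal.resolution} vs "
                f"reference {ref.resolution}"
            )
    ref_bins = [_bins_by_chrom(r) for r in reference_sets]
    out = []
    for b in focal:
        # both spans are expanded by pad_bins, so they intersect iff the bin
        # indices differ by at most 2*pad_bins
        count = sum(_hit_within(b, bins, 2 * pad_bins) for bins in ref_bins)
        hi_level = b.level >= level_cut
        hi_methods = count >= methods_cut
        if hi_level and hi_methods:
            group = "both"
        elif hi_level:
            group = "level3plus"
        elif hi_methods:
            group = "methods3plus"
        else:
            group = "neither"
        out.append(ConsensusAnnotation(boundary=b, methods_count=count, group=group))
    return out


def conservation_scores(
    sets_by_cell_line: Sequence[BoundarySet], pad_bins: int = 1
) -> list[ConservationScore]:
    """Score each boundary by the number of cell lines it appears in.

    The score of a boundary is the count of cell-line sets (including its
    own) containing a boundary within ``pad_bins`` bins, so it ranges from 1
    to the number of cell lines compared.  Higher-level boundaries are
    expected to be more conserved across cell lines.
    """
    if len(sets_by_cell_line) < 2:
        raise ValueError("need at least two cell lines to score conservation")
    all_bins = [_bins_by_chrom(s) for s in sets_by_cell_line]
    scores = []
    for bset in sets_by_cell_line:
        for b in bset:
            score = sum(_hit_within(b, bins, pad_bins) for bins in all_bins)
            scores.append(ConservationScore(boundary=b, score=score))
    return scores


def level_histogram(bset: BoundarySet) -> dict[int, int]:
    """Count boundaries per level; keys 1..4 always present."""
    hist = {lvl: 0 for lvl in range(1, MAX_LEVEL + 1)}
    for b in bset:
        hist[b.level] += 1
    return hist


def write_boundaries_bed(bset: BoundarySet, path: str | Path) -> None:
    """BED6: name = level, score = uncapped max(left, right) sharing count."""
    with open(path, "w") as fh:
        for b in bset:
            fh.write(
                f"{b.chrom}\t{b.position}\t{b.position + b.resolution}\t"
                f"{b.level}\t{max(b.left_count, b.right_count)}\t.\n"
            )
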