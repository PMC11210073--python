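"""Readers and writers for the genomic file formats the pipeline touches.

All coordinates are 0-based half-open (BED convention) internally; the one
1-based source (FIMO match tables) is converted at parse time.  Chromosome
names are compared verbatim unless a ``chr_prefix`` harmonization switch is
passed to a reader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A file line could not be interpreted; carries the 1-based line number."""


class ValidationError(ValueError):
    """Parsed values violate an interval or record invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand is not None and self.strand not in {"+", "-", "."}:
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TadRecord:
    """One (possibly nested) TAD call, tagged with its cell line and caller."""

    interval: GenomicInterval
    cell_line: str = ""
    caller: str = ""

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class TfbsHit:
    """A single transcription-factor motif match collapsed to its midpoint."""

    chrom: str
    position: int
    motif_id: str
    tf_family: str
    match_score: float = 0.0

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValidationError(f"negative TFBS position {self.position}")
        if not self.tf_family:
            self.tf_family = self.motif_id


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    length: int
    fpkm: float
    flags: frozenset[str] = frozenset()
    age_class: int | None = None
    cs_class: int | None = None

    def __post_init__(self) -> None:
        if self.fpkm < 0:
            raise ValidationError(f"negative FPKM for {self.gene_id}")
        if self.length <= 0:
            raise ValidationError(f"non-positive length for {self.gene_id}")

    def body(self) -> GenomicInterval:
        """Gene body as a TSS-anchored, strand-aware interval of ``length`` bp."""
        if self.strand == "-":
            start = max(0, self.tss - self.length + 1)
            return GenomicInterval(self.chrom, start, self.tss + 1)
        return GenomicInterval(self.chrom, self.tss, self.tss + self.length)


ChromSizes = dict[str, int]


class SignalTrack:
    """Sorted non-overlapping per-chromosome intervals with numeric values.

    bedGraph semantics: any position not covered by an interval has value 0.
    """

    def __init__(self, records: Iterable[tuple[str, int, int, float]] = ()):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if end <= start or start < 0:
                raise ValidationError(f"bad signal interval {chrom}:{start}-{end}")
            if not math.isfinite(value):
                raise ValidationError(f"non-finite value at {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end, float(value)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, recs in per_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValidationError(
                    f"overlapping signal intervals on {chrom} near position {starts[i + 1]}"
                )
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = np.array([r[2] for r in recs], dtype=float)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def records(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            for s, e, v in zip(
                self._starts[chrom], self._ends[chrom], self._values[chrom]
            ):
                yield chrom, int(s), int(e), float(v)

    def value_at(self, chrom: str, pos: int) -> float:
        """Point query; uncovered positions return exactly 0."""
        if chrom not in self._starts:
            return 0.0
        starts = self._starts[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < self._ends[chrom][i]:
            return float(self._values[chrom][i])
        return 0.0

    def mass(self, chrom: str, start: int, end: int) -> float:
        """Sum of value x covered-bp over ``[start, end)``."""
        if chrom not in self._starts or end <= start:
            return 0.0
        starts = self._starts[chrom]
        ends = self._ends[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(ov * self._values[chrom][lo:hi]))

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean value over ``[start, end)`` counting uncovered bp as 0."""
        if end <= start:
            return 0.0
        return self.mass(chrom, start, end) / (end - start)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _norm_chrom(name: str, chr_prefix: bool | None) -> str:
    if chr_prefix is None:
        return name
    bare = name[3:] if name.startswith("chr") else name
    return f"chr{bare}" if chr_prefix else bare


def snap_to_grid(pos: int, resolution: int) -> int:
    """Round ``pos`` to the nearest multiple of ``resolution``; ties round down."""
    q, r = divmod(pos, resolution)
    if r * 2 > resolution:
        q += 1
    return q * resolution


def _open_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, chr_prefix: bool | None = None) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals, preserving input order."""
    out: list[GenomicInterval] = []
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = None
        if len(fields) > 4 and fields[4] not in {".", ""}:
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
        strand = fields[5] if len(fields) > 5 else None
        try:
            out.append(
                GenomicInterval(
                    _norm_chrom(fields[0], chr_prefix), start, end, name, score, strand
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
                fields.append(f"{iv.score:g}" if iv.score is not None else ".")
                fields.append(iv.strand if iv.strand is not None else ".")
            fh.write("\t".join(fields) + "\n")


def read_tads(
    path: str | Path,
    cell_line: str,
    caller: str,
    resolution: int,
    chr_prefix: bool | None = None,
) -> list[TadRecord]:
    """Read a TAD interval table, snapping endpoints to the resolution grid.

    The first three recognized columns are chrom/start/end; extra columns
    (nesting level, scores from the caller) are ignored.  Start and end are
    independently rounded to the nearest grid point; a TAD shorter than one
    bin after snapping is rejected.
    """
    tads: list[TadRecord] = []
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 columns")
        if fields[1] in {"start", "tss"}:  # header row
            continue
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        start = snap_to_grid(start, resolution)
        end = snap_to_grid(end, resolution)
        if end - start < resolution:
            raise ValidationError(
                f"{path}:{lineno}: TAD {fields[0]}:{fields[1]}-{fields[2]} "
                f"shorter than one {resolution}-bp bin after snapping"
            )
        tads.append(
            TadRecord(
                GenomicInterval(_norm_chrom(fields[0], chr_prefix), start, end),
                cell_line=cell_line,
                caller=caller,
            )
        )
    return tads


def write_tads(tads: Iterable[TadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcell_line\tcaller\n")
        for t in tads:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.cell_line}\t{t.caller}\n")


def read_bedgraph(path: str | Path, chr_prefix: bool | None = None) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`."""
    records = []
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
        try:
            records.append(
                (
                    _norm_chrom(fields[0], chr_prefix),
                    int(fields[1]),
                    int(fields[2]),
                    float(fields[3]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad coordinate or value") from exc
    return SignalTrack(records)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


#: column order of FIMO's tab-separated match table (1-based inclusive coords)
_FIMO_COLS = (
    "motif_id",
    "motif_alt_id",
    "sequence_name",
    "start",
    "stop",
    "strand",
    "score",
    "p-value",
    "q-value",
    "matched_sequence",
)


def read_fimo(
    path: str | Path,
    family_map: Mapping[str, str] | None = None,
    p_threshold: float = 1e-5,
    chr_prefix: bool | None = None,
) -> list[TfbsHit]:
    """Read a FIMO match table (or BED with motif in the name field) to hits.

    Each match is collapsed to the midpoint of its 0-based half-open span.
    Matches with p-value above ``p_threshold`` (default 1e-5, the usual FIMO
    scan cutoff) are dropped.  ``family_map`` maps motif_id -> TF family;
    motifs without an entry fall back to their own id.
    """
    family_map = family_map or {}
    hits: list[TfbsHit] = []
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) >= 8 and not fields[1].isdigit():
            # FIMO TSV: motif_id, motif_alt_id, seq, start, stop, strand, score, p
            if fields[0] == "motif_id":
                continue
            motif, chrom = fields[0], fields[2]
            try:
                start1, stop1 = int(fields[3]), int(fields[4])
                score = float(fields[6])
                pval = float(fields[7])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad FIMO coordinates") from exc
            start0, end0 = start1 - 1, stop1  # 1-based inclusive -> half-open
        elif len(fields) >= 4 and fields[1].isdigit():
            # BED with motif id in the name column
            chrom, motif = fields[0], fields[3]
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad BED coordinates") from exc
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            pval = 0.0
        else:
            raise ParseError(f"{path}:{lineno}: missing coordinate columns")
        if pval > p_threshold:
            continue
        hits.append(
            TfbsHit(
                chrom=_norm_chrom(chrom, chr_prefix),
                position=(start0 + end0) // 2,
                motif_id=motif,
                tf_family=family_map.get(motif, motif),
                match_score=score,
            )
        )
    return hits


def write_fimo(hits: Iterable[TfbsHit], path: str | Path) -> None:
    """Write hits back out in FIMO's column layout (1-bp matches at midpoint)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_FIMO_COLS) + "\n")
        for h in hits:
            fh.write(
                f"{h.motif_id}\t{h.tf_family}\t{h.chrom}\t{h.position + 1}\t"
                f"{h.position + 1}\t+\t{h.match_score:g}\t1e-06\t.\t.\n"
            )


def read_chrom_sizes(path: str | Path, chr_prefix: bool | None = None) -> ChromSizes:
    sizes: ChromSizes = {}
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        try:
            size = int(fields[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer size") from exc
        if size <= 0:
            raise ValidationError(f"{path}:{lineno}: non-positive chromosome size")
        sizes[_norm_chrom(fields[0], chr_prefix)] = size
    return sizes


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


_GENE_COLS = [
    "gene_id",
    "chrom",
    "tss",
    "strand",
    "length",
    "fpkm",
    "flags",
    "age_class",
    "cs_class",
]


def read_genes(path: str | Path, chr_prefix: bool | None = None) -> list[GeneRecord]:
    """Read the headered gene table (gene_id, chrom, tss, strand, length, fpkm,
    flags as comma-separated labels, optional age_class / cs_class)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "flags": str})
    missing = [c for c in _GENE_COLS[:6] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing gene columns {missing}")
    genes: list[GeneRecord] = []
    for row in df.itertuples(index=False):
        flags = getattr(row, "flags", None)
        flagset = (
            frozenset(f for f in str(flags).split(",") if f)
            if isinstance(flags, str) and flags and flags != "nan"
            else frozenset()
        )
        age = getattr(row, "age_class", None)
        cs = getattr(row, "cs_class", None)
        genes.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                chrom=_norm_chrom(str(row.chrom), chr_prefix),
                tss=int(row.tss),
                strand=str(row.strand),
                length=int(row.length),
                fpkm=float(row.fpkm),
                flags=flagset,
                age_class=None if pd.isna(age) else int(age),
                cs_class=None if pd.isna(cs) else int(cs),
            )
        )
    return genes


def write_genes(genes: Iterable[GeneRecord], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "tss": g.tss,
                "strand": g.strand,
                "length": g.length,
                "fpkm": g.fpkm,
                "flags": ",".join(sorted(g.flags)),
                "age_class": "" if g.age_class is None else g.age_class,
                "cs_class": "" if g.cs_class is None else g.cs_class,
            }
        )
    pd.DataFrame(rows, columns=_GENE_COLS).to_csv(path, sep="\t", index=False)
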