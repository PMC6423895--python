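"""Genomic interval arithmetic and annotation.

All coordinates are 0-based half-open (BED convention). GFF/GTF input is
converted to this convention on read. Overlap means at least one shared base
unless a larger ``min_overlap`` is requested, matching ``bedops -element-of 1``
semantics.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome.

    Width-0 records are rejected: single-base features are width 1 in BED
    (end = start + 1), and degenerate zero-width records are not meaningful
    downstream.
    """

    chrom: str
    start: int
    end: int
    id: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class GeneRecord:
    """A gene with its TSS and exon structure.

    The TSS is the first transcribed base: ``start`` on the + strand and
    ``end - 1`` on the - strand.
    """

    id: str
    interval: GenomicInterval
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be +/-: {self.strand!r}")
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon {ex} outside gene body {self.interval}")

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals per chromosome.

    Returns a sorted list of pairwise-disjoint, non-adjacent intervals covering
    exactly the union of the input bases (``bedops --merge`` behaviour). Labels
    and strands are dropped.
    """
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # overlap or touching
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def elements_of(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> list[GenomicInterval]:
    """Members of ``a`` overlapping the union of ``b`` by >= ``min_overlap`` bp.

    Elements are returned unmodified, in input order (``bedops -element-of``).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    merged = merge_intervals(b) if b else []
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in merged:
        by_chrom[iv.chrom].append(iv)
    out = []
    for iv in a:
        total = 0
        for m in by_chrom.get(iv.chrom, ()):
            if m.start >= iv.end:
                break
            total += iv.overlap(m)
        if total >= min_overlap:
            out.append(iv)
    return out


def define_regulatory_region(
    gene: GeneRecord, chrom_length: int, half_width: int = 50_000
) -> GenomicInterval:
    """Regulatory space of a gene: +-half_width around the gene-body center.

    The center uses floor division for odd gene lengths. The window is clamped
    to [0, chrom_length).
    """
    center = gene.interval.center
    start = max(0, center - half_width)
    end = min(chrom_length, center + half_width)
    return GenomicInterval(gene.interval.chrom, start, end, id=gene.id)


def distance_to_tss(
    dhs: GenomicInterval, genes: Sequence[GeneRecord]
) -> tuple[int, str]:
    """Signed distance from the DHS center to the nearest TSS.

    Negative when the TSS lies upstream (5') of the DHS center relative to the
    assigned gene's strand. Nearest is by absolute distance; exact ties go to
    the lexicographically smaller gene id.
    """
    if not genes:
        raise ValueError("empty gene list")
    center = dhs.center
    candidates = [g for g in genes if g.interval.chrom == dhs.chrom]
    if not candidates:
        raise ValueError(f"no genes on chromosome {dhs.chrom}")
    best = min(candidates, key=lambda g: (abs(center - g.tss), g.id))
    dist = abs(center - best.tss)
    if dist == 0:
        return 0, best.id
    # TSS upstream of the DHS: on + strand the TSS is 5' when tss < center;
    # on - strand 5' means tss > center.
    upstream = best.tss < center if best.strand == "+" else best.tss > center
    return (-dist if upstream else dist), best.id


def annotate_feature(
    dhs: GenomicInterval,
    genes: Sequence[GeneRecord],
    other_track: Sequence[GenomicInterval] = (),
) -> str:
    """Classify a DHS as exon / intron / other / intergenic.

    Precedence: exon > intron > other > intergenic. "other" covers annotated
    non-coding features supplied as an optional extra track.
    """
    for g in genes:
        for ex in g.exons:
            if dhs.overlap(ex) >= 1:
                return "exon"
    for g in genes:
        if dhs.overlap(g.interval) >= 1:
            return "intron"
    for iv in other_track:
        if dhs.overlap(iv) >= 1:
            return "other"
    return "intergenic"


def chromhmm_overlap(
    dhss: Sequence[GenomicInterval],
    segments: Sequence[tuple[GenomicInterval, str]],
) -> dict[str, int]:
    """Count DHSs per chromatin state.

    A DHS counts once per distinct state it overlaps; a DHS spanning two states
    contributes to both.
    """
    counts: dict[str, int] = defaultdict(int)
    for dhs in dhss:
        states = {label for seg, label in segments if dhs.overlap(seg) >= 1}
        for s in states:
            counts[s] += 1
    return dict(counts)


# ---------------------------------------------------------------------------
# I/O: BED and GFF readers/writers, TSV segment tables
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 (tab-separated, no header)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: need >=3 BED columns")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), id=name, strand=strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6 with stable column order, newline-terminated."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t0\t{iv.strand}\n"
            )


def read_genes_gff(path: str | Path) -> list[GeneRecord]:
    """Read gene/exon structure from GFF3 or GTF.

    1-based closed GFF coordinates are converted to 0-based half-open. Exons
    attach to genes via the ``Parent=``/``gene_id`` attribute; a plain ``ID=``
    names the gene.
    """
    genes: dict[str, dict] = {}
    exons: dict[str, list[GenomicInterval]] = defaultdict(list)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, ftype, s, e, _, strand, _, attrs = f[:9]
            start, end = int(s) - 1, int(e)
            ident = _gff_attr(attrs, ("ID", "gene_id"))
            parent = _gff_attr(attrs, ("Parent", "gene_id"))
            if ftype == "gene":
                genes[ident] = dict(
                    interval=GenomicInterval(chrom, start, end, id=ident), strand=strand
                )
            elif ftype == "exon" and parent is not None:
                exons[parent].append(GenomicInterval(chrom, start, end))
    return [
        GeneRecord(gid, rec["interval"], rec["strand"], exons=sorted(
            exons.get(gid, []), key=lambda iv: iv.start))
        for gid, rec in genes.items()
    ]


def _gff_attr(attrs: str, keys: tuple[str, ...]) -> str | None:
    for part in attrs.replace("; ", ";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
        else:
            bits = part.split(None, 1)
            if len(bits) != 2:
                continue
            k, v = bits
        if k in keys:
            return v.strip().strip('"')
    return None


def read_chromhmm(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read a TSV segmentation: chrom, start, end, state."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, s, e, state = line.rstrip("\n").split("\t")[:4]
            out.append((GenomicInterval(chrom, int(s), int(e)), state))
    return out
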