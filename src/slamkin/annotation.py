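"""Genomic intervals, gene models, and readers/writers for GTF/BED/TSV.

All internal coordinates are 0-based half-open (BED convention). GTF input,
which is 1-based inclusive, is converted at parse time. Chromosome names are
compared by exact string match; no "chr" normalization is attempted.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


class AnnotationError(ValueError):
    """Malformed annotation input or invalid interval arithmetic."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(
                f"invalid strand {self.strand!r} (allowed: {STRANDS})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap in bp; 0 when the intervals overlap or touch."""
        if self.chrom != other.chrom:
            raise AnnotationError(
                f"distance undefined across chromosomes "
                f"({self.chrom} vs {other.chrom})"
            )
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end


@dataclass(frozen=True)
class GeneModel:
    """A gene as the strand-aware union of its exons.

    Multi-isoform genes are collapsed to the exon union, so every model has
    non-overlapping exons sorted by start; gaps between consecutive exons are
    the introns. The transcription end site (TES) is the 3'-most coordinate:
    span end on the + strand, span start on the - strand.
    """

    gene_id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    polyadenylated: bool = True

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: no exons")
        for ex in self.exons:
            if ex.chrom != self.span.chrom or ex.strand != self.span.strand:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon {ex} not on span "
                    f"chrom/strand {self.span.chrom}/{self.span.strand}"
                )
        starts = [ex.start for ex in self.exons]
        if starts != sorted(starts):
            raise AnnotationError(f"gene {self.gene_id}: exons not sorted")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"gene {self.gene_id}: overlapping exons {a} / {b}"
                )
            if b.start == a.end:
                raise AnnotationError(
                    f"gene {self.gene_id}: abutting exons {a} / {b} "
                    "(introns must be non-empty; merge at parse)"
                )
        if self.exons[0].start != self.span.start or self.exons[-1].end != self.span.end:
            raise AnnotationError(
                f"gene {self.gene_id}: exon union does not match span"
            )

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tes(self) -> int:
        """Strand-aware transcription end site coordinate."""
        return self.span.end if self.strand != "-" else self.span.start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return len(self.span)

    @property
    def total_intron_length(self) -> int:
        return self.length - sum(len(ex) for ex in self.exons)


def introns_of(gene: GeneModel) -> list[GenomicInterval]:
    """Introns of a gene in 5'->3' transcript order.

    For + strand genes that is genomic order; for - strand genes the genomic
    list is reversed so the first intron is always 5'-most.
    """
    gaps = [
        GenomicInterval(gene.chrom, a.end, b.start, gene.strand)
        for a, b in zip(gene.exons, gene.exons[1:])
    ]
    if gene.strand == "-":
        gaps.reverse()
    return gaps


@dataclass
class SegmentSet:
    """Labeled genomic intervals (peak calls, compartment-state segments)."""

    intervals: list[GenomicInterval]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = [str(i) for i in range(len(self.intervals))]
        if len(self.labels) != len(self.intervals):
            raise AnnotationError(
                f"{len(self.intervals)} intervals but {len(self.labels)} labels"
            )
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (self.intervals[i].chrom, self.intervals[i].start),
        )
        self.intervals = [self.intervals[i] for i in order]
        self.labels = [self.labels[i] for i in order]

    def __len__(self) -> int:
        return len(self.intervals)

    def on_chrom(self, chrom: str) -> "SegmentSet":
        keep = [i for i, iv in enumerate(self.intervals) if iv.chrom == chrom]
        return SegmentSet(
            [self.intervals[i] for i in keep], [self.labels[i] for i in keep]
        )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _merge_union(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals; overlapping or abutting pieces are merged."""
    merged: list[list[int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse exon features from a GTF file into per-gene models.

    Coordinates are converted from the 1-based inclusive GTF convention to
    0-based half-open. Exons are grouped by ``gene_id`` and collapsed to
    their union across isoforms (the pipeline quantifies at gene level).
    Genes are returned sorted by (chrom, start, gene_id).
    """
    per_gene: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = cols
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end1 < start1:
                raise AnnotationError(
                    f"{path}:{lineno}: end < start ({end1} < {start1})"
                )
            if strand not in ("+", "-"):
                raise AnnotationError(
                    f"{path}:{lineno}: unknown strand symbol {strand!r}"
                )
            attr = dict(_GTF_ATTR_RE.findall(attrs))
            gene_id = attr.get("gene_id")
            if not gene_id:
                raise AnnotationError(f"{path}:{lineno}: missing gene_id attribute")
            rec = per_gene.setdefault(
                gene_id, {"chrom": chrom, "strand": strand, "exons": []}
            )
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise AnnotationError(
                    f"{path}:{lineno}: gene {gene_id} spans multiple "
                    f"chromosomes/strands ({rec['chrom']}{rec['strand']} vs "
                    f"{chrom}{strand})"
                )
            rec["exons"].append((start1 - 1, end1))  # to 0-based half-open
    genes = []
    for gene_id, rec in per_gene.items():
        merged = _merge_union(rec["exons"])
        exons = tuple(
            GenomicInterval(rec["chrom"], s, e, rec["strand"]) for s, e in merged
        )
        span = GenomicInterval(
            rec["chrom"], merged[0][0], merged[-1][1], rec["strand"]
        )
        genes.append(GeneModel(gene_id, span, exons))
    genes.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "slamkin") -> None:
    """Emit gene models as GTF (gene + exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                "\t".join(
                    [
                        g.chrom, source, "gene",
                        str(g.span.start + 1), str(g.span.end),
                        ".", g.strand, ".", attrs,
                    ]
                )
                + "\n"
            )
            for ex in g.exons:
                fh.write(
                    "\t".join(
                        [
                            g.chrom, source, "exon",
                            str(ex.start + 1), str(ex.end),
                            ".", g.strand, ".", attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> SegmentSet:
    """Read a BED3/BED4+ file into a SegmentSet (sorted, labeled).

    Column 4 is used as the label when present, else a running index.
    """
    intervals: list[GenomicInterval] = []
    labels: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise AnnotationError(
                    f"{path}:{lineno}: BED needs >= 3 columns, got {len(cols)}"
                )
            chrom, start_s, end_s = cols[0], cols[1], cols[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise AnnotationError(
                    f"{path}:{lineno}: end <= start ({end} <= {start})"
                )
            strand = cols[5] if len(cols) >= 6 and cols[5] in STRANDS else "."
            intervals.append(GenomicInterval(chrom, start, end, strand))
            labels.append(cols[3] if len(cols) >= 4 else str(len(labels)))
    return SegmentSet(intervals, labels)


def write_bed(segments: SegmentSet, path: str | Path) -> None:
    """Write a SegmentSet as BED4 (BED6 when any interval is stranded)."""
    stranded = any(iv.strand != "." for iv in segments.intervals)
    with open(path, "w") as fh:
        for iv, label in zip(segments.intervals, segments.labels):
            cols = [iv.chrom, str(iv.start), str(iv.end), label]
            if stranded:
                cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write a per-gene TSV summary of the annotation."""
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tchrom\tstart\tend\tstrand\tn_exons\t"
            "gene_length\ttotal_intron_length\n"
        )
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.span.start}\t{g.span.end}\t"
                f"{g.strand}\t{g.n_exons}\t{g.length}\t{g.total_intron_length}\n"
            )
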