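"""Per-read T>C conversion counting and cB-style conversion tables.

The sequencing library is forward-stranded: read sequences match the
transcribed strand. A labeled uridine therefore appears as a reference-T
read-C mismatch for + strand genes, and as a reference-A read-G mismatch
(on the reference top strand) for - strand genes; both are the same T>C
event counted on the transcribed strand. Reference bases are recovered
from MD tags when present, or from a FASTA otherwise.
"""
from __future__ import annotations

import logging
from bisect import bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import GeneModel, GenomicInterval, SegmentSet

logger = logging.getLogger(__name__)


class ConversionError(ValueError):
    """Unusable alignment input for conversion counting."""


@dataclass(frozen=True)
class ReadObservation:
    """One read's conversion evidence: assayable Ts covered and converted."""

    gene_id: str
    sample: str
    replicate: int
    n_T: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n_T):
            raise ConversionError(f"need 0 <= k <= n_T, got k={self.k}, n_T={self.n_T}")


def count_read_conversions(
    read: pysam.AlignedSegment,
    reference: Mapping[str, np.ndarray] | None = None,
    mask: frozenset | set | None = None,
    min_baseq: int | None = None,
) -> tuple[int, int]:
    """Count (n_T, k) for one aligned read on its transcribed strand.

    ``n_T`` is the number of unmasked reference thymines (reference A for
    reverse-strand reads) covered by aligned bases; ``k`` is how many were
    read as the converted base. Insertions and soft-clipped bases cover no
    reference position and contribute nothing.

    Reference bases come from the MD tag; if absent, ``reference`` (a
    chrom -> uint8 ASCII array mapping) is used. Neither available is a
    hard error.
    """
    if read.is_unmapped:
        raise ConversionError(f"read {read.query_name} is unmapped")
    if read.has_tag("MD"):
        pairs = read.get_aligned_pairs(matches_only=True, with_seq=True)
    elif reference is not None:
        ref = reference[read.reference_name]
        pairs = [
            (q, r, chr(ref[r]))
            for q, r in read.get_aligned_pairs(matches_only=True)
        ]
    else:
        raise ConversionError(
            f"read {read.query_name}: no MD tag and no reference FASTA given"
        )
    if read.is_reverse:
        ref_base, conv_base = "A", "G"
    else:
        ref_base, conv_base = "T", "C"
    seq = read.query_sequence
    quals = read.query_qualities
    chrom = read.reference_name
    n_T = 0
    k = 0
    for qpos, rpos, rbase in pairs:
        if rbase is None or rbase.upper() != ref_base:
            continue
        if mask is not None and (chrom, rpos) in mask:
            continue
        if min_baseq is not None and quals is not None and quals[qpos] < min_baseq:
            continue
        n_T += 1
        if seq[qpos].upper() == conv_base:
            k += 1
    return n_T, k


def iter_alignments(path: str | Path) -> Iterator[pysam.AlignedSegment]:
    """Iterate mapped primary alignments of a SAM/BAM file."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            yield read


def build_snp_mask(
    control_reads: Iterable[pysam.AlignedSegment] | str | Path,
    reference: Mapping[str, np.ndarray] | None = None,
    min_coverage: int = 10,
    rate_threshold: float = 0.8,
) -> set[tuple[str, int]]:
    """Genome-wide positions behaving like homozygous T>C variants.

    From a control library (unlabeled or nucleoplasmic IgG), any
    transcribed-strand T position with coverage >= ``min_coverage`` and an
    apparent conversion rate > ``rate_threshold`` is masked. An empty
    control yields an empty mask with a warning.
    """
    if isinstance(control_reads, (str, Path)):
        control_reads = iter_alignments(control_reads)
    cov: Counter = Counter()
    conv: Counter = Counter()
    n_reads = 0
    for read in control_reads:
        n_reads += 1
        if read.has_tag("MD"):
            pairs = read.get_aligned_pairs(matches_only=True, with_seq=True)
        elif reference is not None:
            ref = reference[read.reference_name]
            pairs = [
                (q, r, chr(ref[r]))
                for q, r in read.get_aligned_pairs(matches_only=True)
            ]
        else:
            raise ConversionError(
                f"read {read.query_name}: no MD tag and no reference FASTA given"
            )
        ref_base, conv_base = ("A", "G") if read.is_reverse else ("T", "C")
        seq = read.query_sequence
        chrom = read.reference_name
        for qpos, rpos, rbase in pairs:
            # MD reports the true reference base (lowercased at mismatches),
            # so homozygous-variant sites still show rbase == ref_base here
            if rbase is None or rbase.upper() != ref_base:
                continue
            key = (chrom, rpos)
            cov[key] += 1
            if seq[qpos].upper() == conv_base:
                conv[key] += 1
    if n_reads == 0:
        logger.warning("empty control library: SNP mask is empty")
        return set()
    return {
        key
        for key, c in cov.items()
        if c >= min_coverage and conv[key] / c > rate_threshold
    }


# ---------------------------------------------------------------------------
# gene assignment + aggregation
# ---------------------------------------------------------------------------

class _GeneIndex:
    """Midpoint containment lookup over gene spans, per (chrom, strand)."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._by_key: dict[tuple[str, str], tuple[list[int], list[int], list[GeneModel]]] = {}
        grouped: dict[tuple[str, str], list[GeneModel]] = defaultdict(list)
        for g in genes:
            grouped[(g.chrom, g.strand)].append(g)
        for key, gs in grouped.items():
            gs.sort(key=lambda g: g.span.start)
            starts = [g.span.start for g in gs]
            ends = [g.span.end for g in gs]
            self._by_key[key] = (starts, ends, gs)

    def assign(self, chrom: str, strand: str, midpoint: int) -> GeneModel | str:
        """Gene whose span contains the midpoint, or 'none'/'ambiguous'."""
        entry = self._by_key.get((chrom, strand))
        if entry is None:
            return "none"
        starts, ends, gs = entry
        i = bisect_right(starts, midpoint)
        hits = [g for g in gs[max(i - 5, 0) : i] if g.span.start <= midpoint < g.span.end]
        if not hits:
            return "none"
        if len(hits) > 1:
            return "ambiguous"
        return hits[0]


@dataclass
class AggregateStats:
    """Bookkeeping counters from read-to-gene assignment."""

    assigned: int = 0
    no_gene: int = 0
    ambiguous: int = 0
    unmapped: int = 0


class ConversionTable:
    """Per (gene, sample, replicate) histogram of reads over (n_T, k).

    The cB-style core record: rows are (gene_id, sample, replicate, n_T,
    k, n_reads). Replicates are pooled on demand when extracting a gene's
    histogram.
    """

    COLUMNS = ["gene_id", "sample", "replicate", "n_T", "k", "n_reads"]

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=self.COLUMNS)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ConversionError(f"conversion table missing columns: {sorted(missing)}")
        bad = df[df["k"] > df["n_T"]]
        if len(bad):
            raise ConversionError("conversion table rows with k > n_T")
        self.df = df[self.COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_observations(cls, obs: pd.DataFrame) -> "ConversionTable":
        """Histogram per-read observations (gene_id, sample, replicate, n_T, k)."""
        if obs.empty:
            return cls()
        g = (
            obs.groupby(["gene_id", "sample", "replicate", "n_T", "k"], sort=True)
            .size()
            .rename("n_reads")
            .reset_index()
        )
        return cls(g)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def histogram(
        self, gene_id: str, sample: str, replicate: int | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(n_T, k, weight) arrays for one gene/sample, replicates pooled
        unless a specific replicate is requested."""
        sel = self.df[(self.df["gene_id"] == gene_id) & (self.df["sample"] == sample)]
        if replicate is not None:
            sel = sel[sel["replicate"] == replicate]
        pooled = sel.groupby(["n_T", "k"], sort=True)["n_reads"].sum().reset_index()
        return (
            pooled["n_T"].to_numpy(int),
            pooled["k"].to_numpy(int),
            pooled["n_reads"].to_numpy(int),
        )

    def totals(self) -> pd.DataFrame:
        """Per (gene, sample) totals: reads, T positions, conversions."""
        df = self.df.copy()
        df["sum_T"] = df["n_T"] * df["n_reads"]
        df["sum_k"] = df["k"] * df["n_reads"]
        out = (
            df.groupby(["gene_id", "sample"], sort=True)
            .agg(n_reads=("n_reads", "sum"), sum_T=("sum_T", "sum"), sum_k=("sum_k", "sum"))
            .reset_index()
        )
        return out

    def pooled_totals(self, sample: str | None = None) -> tuple[int, int, int]:
        df = self.df if sample is None else self.df[self.df["sample"] == sample]
        n = int(df["n_reads"].sum())
        st = int((df["n_T"] * df["n_reads"]).sum())
        sk = int((df["k"] * df["n_reads"]).sum())
        return n, st, sk

    def subset(self, sample: str) -> "ConversionTable":
        return ConversionTable(self.df[self.df["sample"] == sample].reset_index(drop=True))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ConversionTable":
        return cls(pd.read_csv(path, sep="\t"))


def aggregate(
    reads: Iterable[pysam.AlignedSegment] | str | Path,
    genes: Sequence[GeneModel],
    sample: str,
    replicate: int = 1,
    mask: set | frozenset | None = None,
    reference: Mapping[str, np.ndarray] | None = None,
    min_baseq: int | None = None,
    min_mapq: int = 0,
    keep_positions: bool = False,
) -> tuple[pd.DataFrame, AggregateStats]:
    """Count conversions per read and assign reads to genes.

    Assignment uses the read midpoint: the read belongs to the gene whose
    span contains it, strand-matched (forward-stranded library, so a
    reverse-flagged read belongs to a - strand gene). Reads hitting no
    gene or more than one are dropped with counters. Returns a per-read
    observation frame (plus 5'-end positions when ``keep_positions``) and
    the assignment stats.
    """
    if isinstance(reads, (str, Path)):
        reads = iter_alignments(reads)
    index = _GeneIndex(genes)
    stats = AggregateStats()
    rows = []
    for read in reads:
        if read.mapping_quality < min_mapq:
            continue
        strand = "-" if read.is_reverse else "+"
        mid = (read.reference_start + read.reference_end) // 2
        hit = index.assign(read.reference_name, strand, mid)
        if hit == "none":
            stats.no_gene += 1
            continue
        if hit == "ambiguous":
            stats.ambiguous += 1
            continue
        n_T, k = count_read_conversions(read, reference, mask, min_baseq)
        stats.assigned += 1
        row = [hit.gene_id, sample, replicate, n_T, k]
        if keep_positions:
            pos5 = read.reference_end - 1 if read.is_reverse else read.reference_start
            row += [read.reference_name, pos5]
        rows.append(row)
    cols = ["gene_id", "sample", "replicate", "n_T", "k"]
    if keep_positions:
        cols += ["chrom", "pos5"]
    return pd.DataFrame(rows, columns=cols), stats


def mask_to_bed(mask: set[tuple[str, int]]) -> SegmentSet:
    """Masked positions as 1-bp BED intervals."""
    ivs = [GenomicInterval(c, p, p + 1) for c, p in sorted(mask)]
    return SegmentSet(ivs, [f"snp_{i}" for i in range(len(ivs))])
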