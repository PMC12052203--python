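"""Genomic-context characterization of compartment transcripts.

Peak proximity (gene-body edge to peak edge), compartment-state
assignment by maximal overlap with a consolidation to four groups, and
read-density signal matrices over scaled feature bodies or fixed windows
upstream of the transcription end site.
"""
from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, SegmentSet


class FeaturesError(ValueError):
    """Invalid feature-analysis input."""


def nearest_peak_distance(gene: GeneModel, peaks: SegmentSet) -> float:
    """Gap in bp from the gene body to the nearest peak on its chromosome.

    0 when any peak overlaps the gene span; NaN when the chromosome has
    no peaks (distance undefined).
    """
    best = math.inf
    for iv in peaks.intervals:
        if iv.chrom != gene.chrom:
            continue
        d = gene.span.distance_to(iv)
        if d < best:
            best = d
            if best == 0:
                break
    return float(best) if best < math.inf else math.nan


def fraction_overlapping(genes: Sequence[GeneModel], peaks: SegmentSet) -> float:
    """Percent of genes whose body directly overlaps a peak."""
    if not genes:
        return 0.0
    hits = sum(1 for g in genes if nearest_peak_distance(g, peaks) == 0)
    return 100.0 * hits / len(genes)


def assign_state(
    gene: GeneModel,
    states: SegmentSet,
    consolidation: Mapping[str, str],
) -> str | None:
    """Consolidated compartment-state group for a gene.

    The raw state is the label with maximal bp overlap with the gene span
    (ties broken by the smaller start of the earliest overlapping
    segment), then mapped through ``consolidation``. Returns None when no
    segment overlaps the gene.
    """
    overlap_bp: dict[str, int] = {}
    first_start: dict[str, int] = {}
    for iv, label in zip(states.intervals, states.labels):
        if iv.chrom != gene.chrom:
            continue
        ov = min(iv.end, gene.span.end) - max(iv.start, gene.span.start)
        if ov <= 0:
            continue
        overlap_bp[label] = overlap_bp.get(label, 0) + ov
        if label not in first_start or iv.start < first_start[label]:
            first_start[label] = iv.start
    if not overlap_bp:
        return None
    raw = min(overlap_bp, key=lambda lab: (-overlap_bp[lab], first_start[lab]))
    if raw not in consolidation:
        raise FeaturesError(
            f"state label {raw!r} absent from the consolidation mapping"
        )
    return consolidation[raw]


def state_group_percentages(
    genes: Sequence[GeneModel],
    states: SegmentSet,
    consolidation: Mapping[str, str],
) -> pd.Series:
    """Percent of genes per consolidated group (unassigned genes excluded)."""
    groups = [assign_state(g, states, consolidation) for g in genes]
    ser = pd.Series([g for g in groups if g is not None], dtype="object")
    if ser.empty:
        return pd.Series(dtype=float)
    return 100.0 * ser.value_counts() / len(ser)


# ---------------------------------------------------------------------------
# signal matrices
# ---------------------------------------------------------------------------

def signal_matrix(
    reads: pd.DataFrame,
    features: Sequence[GenomicInterval],
    mode: str,
    bins: int = 10,
    upstream_bp: int = 500,
    feature_ids: Sequence[str] | None = None,
    library_size: int | None = None,
    normalize: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Binned read 5'-end density over features for one library.

    ``reads`` needs columns chrom and pos5 (genomic position of the
    5'-most aligned base). Modes:

    - ``scaled_body``: each feature span split into ``bins`` equal parts.
    - ``fixed_upstream``: the strand-aware window [TES - upstream_bp, TES).

    Column 1 is always the 5'-most bin: minus-strand features have their
    bin order reversed. Counts are scaled to counts-per-million of
    ``library_size`` (default: number of rows in ``reads``) unless
    ``normalize`` is False. Features shorter than ``bins`` in scaled mode
    fall back to a single bin (counts in column 1) and are reported in the
    returned flag list.
    """
    if mode not in ("scaled_body", "fixed_upstream"):
        raise FeaturesError(f"unknown mode {mode!r}")
    if feature_ids is None:
        feature_ids = [f"feature_{i}" for i in range(len(features))]
    if len(feature_ids) != len(features):
        raise FeaturesError("feature_ids length does not match features")
    if not {"chrom", "pos5"} <= set(reads.columns):
        raise FeaturesError("reads frame needs columns 'chrom' and 'pos5'")

    by_chrom: dict[str, np.ndarray] = {
        chrom: np.sort(sub["pos5"].to_numpy(int))
        for chrom, sub in reads.groupby("chrom")
    }
    mat = np.zeros((len(features), bins))
    flagged: list[str] = []
    for i, iv in enumerate(features):
        if mode == "fixed_upstream":
            if iv.strand == "-":
                win = (iv.start, iv.start + upstream_bp)
            else:
                win = (iv.end - upstream_bp, iv.end)
            start, end = max(win[0], 0), win[1]
        else:
            start, end = iv.start, iv.end
        width = end - start
        single_bin = mode == "scaled_body" and width < bins
        if single_bin:
            flagged.append(feature_ids[i])
        pos = by_chrom.get(iv.chrom)
        if pos is None or width <= 0:
            continue
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        inside = pos[lo:hi]
        if inside.size == 0:
            continue
        if single_bin:
            mat[i, 0] = inside.size
            continue
        idx = ((inside - start) * bins) // width
        counts = np.bincount(idx, minlength=bins)[:bins]
        if iv.strand == "-":
            counts = counts[::-1]
        mat[i] += counts
    if normalize:
        total = library_size if library_size is not None else len(reads)
        if total > 0:
            mat = mat * 1e6 / total
    return (
        pd.DataFrame(mat, index=list(feature_ids), columns=[f"bin_{b + 1}" for b in range(bins)]),
        flagged,
    )


def intronic_enrichment(
    target_matrix: pd.DataFrame,
    control_matrix: pd.DataFrame,
    fold_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Per-intron target/control log2 ratio and the percent enriched.

    Both matrices must be CPM-normalized over identical features; the
    per-feature statistic is log2((target_sum + pseudocount) /
    (control_sum + pseudocount)), enriched when the linear ratio exceeds
    ``fold_threshold``.
    """
    if target_matrix.shape != control_matrix.shape or list(target_matrix.index) != list(
        control_matrix.index
    ):
        raise FeaturesError("target and control matrices must share shape and features")
    t_sum = target_matrix.sum(axis=1)
    c_sum = control_matrix.sum(axis=1)
    log2_ratio = np.log2((t_sum + pseudocount) / (c_sum + pseudocount))
    enriched = log2_ratio > math.log2(fold_threshold)
    out = pd.DataFrame(
        {"log2_ratio": log2_ratio, "enriched": enriched}, index=target_matrix.index
    )
    frac = 100.0 * enriched.mean() if len(enriched) else 0.0
    return out, float(frac)
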