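"""Synthetic compartment-labeling data generator.

Emulates the data structure of an antibody-tethered compartment RNA assay
combined with a 4-hour 4-thiouridine pulse: three gene classes
(long-intron "polycomb_adjacent" genes placed near repressive-mark peaks,
exon-rich "speckle" genes, and background genes), per-gene global and
compartment-localized degradation rates, compartment-specific capture
enrichment, and single-end forward-stranded reads carrying T>C conversions
(background rate ``p_e`` for pre-existing RNA, ``p_c`` for RNA made during
the pulse). Output is plain-text SAM with MD tags (conversions recoverable
without a FASTA), a per-read observation table, and a per-gene truth table.

Reference sequences are synthetic and lattice-structured: reference T at
positions == 0 (mod 5) and A at positions == 2 (mod 5), remaining positions
G/C. With the default 100 bp reads this yields exactly 20 assayable
thymines per read on either strand, the default per-read T content.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotation import GeneModel, GenomicInterval, SegmentSet

COMPARTMENTS = ("h3k27me3", "sc35")
#: library name -> kinetic regime; "unlabeled" carries no s4U (all reads old)
LIBRARIES = ("igg", "h3k27me3", "sc35", "unlabeled")
DYNAMICS_LABELS = ("transient", "persistent", "intermediate")

#: raw compartment-state segmentation labels and their 4-group consolidation
DEFAULT_CONSOLIDATION = {
    "Speckle": "speckle",
    "Interior_Act1": "active",
    "Interior_Act2": "active",
    "Interior_Act3": "active",
    "Interior_Repr1": "repressive",
    "Interior_Repr2": "repressive",
    "Near_Lm1": "lamina",
    "Near_Lm2": "lamina",
    "Lamina": "lamina",
}
_RAW_BY_GROUP = {
    "speckle": ["Speckle"],
    "active": ["Interior_Act1", "Interior_Act2", "Interior_Act3"],
    "repressive": ["Interior_Repr1", "Interior_Repr2"],
    "lamina": ["Near_Lm1", "Near_Lm2", "Lamina"],
}


class SimulationError(ValueError):
    """Invalid simulation configuration or infeasible placement."""


@dataclass
class ClassParams:
    """Per-gene-class samplers and compartment behavior.

    ``enrichment_fold`` maps compartment library names to the capture-fold
    of this class's genes in that library (absent -> 1, not enriched).
    ``frac_transient``/``frac_persistent`` set, for enriched compartments,
    the fractions of genes drawn with localized/global rate ratio R in the
    transient (R in [2.5, 6]) and persistent (R in [0.6, 0.9]) regimes; the
    remainder are intermediate (R in [1.3, 1.8]).
    """

    n_genes: int
    median_gene_length: float
    mean_exons: float
    median_half_life_h: float
    expression_scale: float
    enrichment_fold: dict[str, float] = field(default_factory=dict)
    frac_transient: float = 0.0
    frac_persistent: float = 0.0
    sigma_gene_length: float = 0.35
    mean_exon_length: float = 270.0
    sigma_half_life: float = 0.5
    expression_sigma: float = 0.8
    frac_polyadenylated: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise SimulationError("n_genes must be >= 0")
        if self.frac_transient + self.frac_persistent > 1:
            raise SimulationError("frac_transient + frac_persistent > 1")
        for comp, fold in self.enrichment_fold.items():
            if comp not in COMPARTMENTS:
                raise SimulationError(f"unknown compartment {comp!r}")
            if fold <= 0:
                raise SimulationError("enrichment_fold must be > 0")


def default_classes() -> dict[str, ClassParams]:
    """Default gene-class mix mirroring the assayed compartments.

    polycomb_adjacent: long genes (median 156 kb) with long introns, low
    expression, enriched in the repressive-mark library, mostly nascent
    (not yet polyadenylated). speckle: exon-rich genes (double the
    background exon count), enriched in the speckle library. background:
    unenriched filler transcriptome.
    """
    return {
        "polycomb_adjacent": ClassParams(
            n_genes=40,
            median_gene_length=156_000.0,
            mean_exons=13.0,
            median_half_life_h=3.2,
            expression_scale=0.2,
            enrichment_fold={"h3k27me3": 8.0},
            frac_transient=0.55,
            frac_persistent=0.10,
            frac_polyadenylated=0.1,
        ),
        "speckle": ClassParams(
            n_genes=40,
            median_gene_length=25_000.0,
            mean_exons=16.0,
            median_half_life_h=6.0,
            expression_scale=1.0,
            enrichment_fold={"sc35": 8.0},
            frac_transient=0.69,
            frac_persistent=0.08,
            frac_polyadenylated=1.0,
        ),
        "background": ClassParams(
            n_genes=120,
            median_gene_length=25_000.0,
            mean_exons=8.0,
            median_half_life_h=4.0,
            expression_scale=1.0,
            frac_polyadenylated=0.9,
        ),
    }


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults encode the labeling design the analysis assumes: a 4-hour
    pulse, three replicates per library, background conversion probability
    ``p_e`` = 0.001 and labeled-read conversion probability ``p_c`` = 0.05
    per assayable T, 100 bp single-end forward-stranded reads with 20
    reference thymines each.
    """

    classes: dict[str, ClassParams] = field(default_factory=default_classes)
    pulse_hours: float = 4.0
    p_e: float = 0.001
    p_c: float = 0.05
    reads_per_library: int = 50_000
    replicates: int = 3
    read_length: int = 100
    n_T_per_read: int = 20
    n_chromosomes: int = 4
    min_intergene_gap: int = 20_000
    max_intergene_gap: int = 60_000
    peak_median_distance: float = 25_000.0
    peak_sigma_distance: float = 0.6
    peak_overlap_fraction: float = 0.19
    peak_width: int = 5_000
    n_background_peaks: int = 40
    n_snps: int = 30
    p_speckle_adjacent: float = 0.55
    tes_priming_scale: float = 500.0
    tes_priming_fraction: float = 0.6
    genome_size: int | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.p_e < self.p_c <= 1):
            raise SimulationError(
                f"need 0 <= p_e < p_c <= 1, got p_e={self.p_e}, p_c={self.p_c}"
            )
        if self.pulse_hours <= 0:
            raise SimulationError("pulse_hours must be > 0")
        for name, val in [
            ("reads_per_library", self.reads_per_library),
            ("replicates", self.replicates),
            ("read_length", self.read_length),
            ("n_T_per_read", self.n_T_per_read),
            ("n_chromosomes", self.n_chromosomes),
        ]:
            if val <= 0:
                raise SimulationError(f"{name} must be > 0")
        if self.n_T_per_read > self.read_length:
            raise SimulationError("n_T_per_read cannot exceed read_length")
        if not 0 <= self.peak_overlap_fraction < 0.5:
            raise SimulationError("peak_overlap_fraction must be in [0, 0.5)")


# ---------------------------------------------------------------------------
# truth sampling helpers
# ---------------------------------------------------------------------------

def _sample_ratio(rng: np.random.Generator, regime: str) -> float:
    """Localized/global degradation-rate ratio for one gene."""
    if regime == "transient":
        return float(np.exp(rng.uniform(np.log(2.5), np.log(6.0))))
    if regime == "persistent":
        return float(rng.uniform(0.6, 0.9))
    return float(rng.uniform(1.3, 1.8))


def truth_label(ratio: float) -> str:
    """Dynamics label implied by a true rate ratio (no sampling noise)."""
    if ratio >= 2.0:
        return "transient"
    if ratio <= 1.0:
        return "persistent"
    return "intermediate"


# ---------------------------------------------------------------------------
# the simulation
# ---------------------------------------------------------------------------

class CompartmentSimulation:
    """Deterministic synthetic dataset for a given (config, seed) pair.

    Construction samples the annotation (gene models, repressive-mark
    peaks, compartment-state segments) and the per-gene kinetic truth;
    ``write_sam``/``simulate_library`` then generate reads per library and
    replicate. All randomness derives from the seed, so equal seeds give
    byte-identical output files.
    """

    def __init__(self, config: SimulationConfig, seed: int | None = None):
        self.config = config
        self.seed = int(config.seed if seed is None else seed)
        self._build()

    # -- annotation + truth ------------------------------------------------

    def _build(self) -> None:
        cfg = self.config
        rng = np.random.default_rng([self.seed, 0])

        gene_specs = []  # (class_name, length, n_exons)
        for cls_name, cls in cfg.classes.items():
            lengths = np.exp(
                rng.normal(np.log(cls.median_gene_length), cls.sigma_gene_length, cls.n_genes)
            ).astype(int)
            n_exons = 2 + rng.poisson(max(cls.mean_exons - 2, 0), cls.n_genes)
            for L, ne in zip(lengths, n_exons):
                gene_specs.append((cls_name, max(int(L), 2_000), int(ne)))
        order = rng.permutation(len(gene_specs))
        gene_specs = [gene_specs[i] for i in order]

        # offset-adjusted log-normal so the peak-distance *mixture* median
        # (zeros from direct overlaps included) sits at the configured value
        p0 = cfg.peak_overlap_fraction
        zstar = norm.ppf((0.5 - p0) / (1.0 - p0))
        dist_median = cfg.peak_median_distance * math.exp(-cfg.peak_sigma_distance * zstar)

        genes: list[GeneModel] = []
        gene_class: dict[str, str] = {}
        peak_ivs: list[GenomicInterval] = []
        chrom_sizes: dict[str, int] = {}
        n_chrom = cfg.n_chromosomes
        cursors = {f"chrSim{i + 1}": 0 for i in range(n_chrom)}
        chrom_names = list(cursors)

        for idx, (cls_name, length, n_exons) in enumerate(gene_specs):
            cls = cfg.classes[cls_name]
            chrom = chrom_names[idx % n_chrom]
            gap = int(rng.integers(cfg.min_intergene_gap, cfg.max_intergene_gap))
            start = cursors[chrom] + gap
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"{cls_name}_{idx:04d}"
            exons = self._sample_exons(rng, start, length, n_exons, cls, chrom, strand)
            span = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
            polyA = bool(rng.random() < cls.frac_polyadenylated)
            genes.append(GeneModel(gene_id, span, tuple(exons), polyadenylated=polyA))
            gene_class[gene_id] = cls_name
            cursors[chrom] = span.end

            if cls_name == "polycomb_adjacent":
                if rng.random() < p0:
                    # peak overlapping the gene edge
                    edge = span.start if rng.random() < 0.5 else span.end - 1
                    pk_start = max(edge - cfg.peak_width // 2, 0)
                else:
                    d = int(np.exp(rng.normal(np.log(dist_median), cfg.peak_sigma_distance)))
                    pk_start = span.end + max(d, 1)
                peak_ivs.append(
                    GenomicInterval(chrom, pk_start, pk_start + cfg.peak_width)
                )
                cursors[chrom] = max(cursors[chrom], pk_start + cfg.peak_width)

        for chrom in chrom_names:
            tail = int(rng.integers(cfg.min_intergene_gap, cfg.max_intergene_gap))
            chrom_sizes[chrom] = cursors[chrom] + tail
        if cfg.genome_size is not None and sum(chrom_sizes.values()) > cfg.genome_size:
            raise SimulationError(
                f"genome_size={cfg.genome_size} too small: placement needs "
                f"{sum(chrom_sizes.values())} bp"
            )

        # scattered background peaks, kept off gene bodies so the planted
        # per-gene peak distances stay in control of the proximity stats
        spans_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for g in genes:
            spans_by_chrom.setdefault(g.chrom, []).append((g.span.start, g.span.end))
        placed = 0
        attempts = 0
        while placed < cfg.n_background_peaks and attempts < 50 * cfg.n_background_peaks:
            attempts += 1
            chrom = chrom_names[int(rng.integers(n_chrom))]
            pos = int(rng.integers(0, max(chrom_sizes[chrom] - cfg.peak_width, 1)))
            if any(
                pos < e and s < pos + cfg.peak_width
                for s, e in spans_by_chrom.get(chrom, ())
            ):
                continue
            peak_ivs.append(GenomicInterval(chrom, pos, pos + cfg.peak_width))
            placed += 1

        genes.sort(key=lambda g: (g.chrom, g.span.start))
        self.genes = genes
        self.gene_class = gene_class
        self.chrom_sizes = chrom_sizes
        self.peaks = SegmentSet(peak_ivs, [f"peak_{i}" for i in range(len(peak_ivs))])
        self.states = self._tile_states(rng)
        self.truth = self._sample_truth(rng)
        self._ref_cache: dict[str, np.ndarray] = {}
        self.snp_positions = self._plant_snps(rng)
        self._snps_by_chrom: dict[str, set[int]] = {}
        for c, p in self.snp_positions:
            self._snps_by_chrom.setdefault(c, set()).add(p)

    def _sample_exons(self, rng, start, length, n_exons, cls, chrom, strand):
        n_exons = max(2, n_exons) if length > 10 * cls.mean_exon_length else 1
        exon_lens = np.maximum(
            rng.normal(cls.mean_exon_length, cls.mean_exon_length / 4, n_exons), 50
        ).astype(int)
        exonic = int(exon_lens.sum())
        intron_total = max(length - exonic, n_exons - 1)
        if n_exons == 1:
            return [GenomicInterval(chrom, start, start + max(length, 50), strand)]
        w = rng.dirichlet(np.full(n_exons - 1, 3.0))
        intron_lens = np.maximum((w * intron_total).astype(int), 20)
        exons = []
        pos = start
        for i in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[i]), strand))
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        return exons

    def _tile_states(self, rng) -> SegmentSet:
        """Tile each chromosome with raw compartment-state segments.

        Gene-covering segments get a class-biased state (speckle genes land
        in a "Speckle" segment with probability ``p_speckle_adjacent``);
        intergenic gaps get random states.
        """
        cfg = self.config
        group_bias = {
            "speckle": ("speckle", cfg.p_speckle_adjacent),
            "polycomb_adjacent": ("repressive", 0.6),
            "background": ("active", 0.6),
        }
        ivs: list[GenomicInterval] = []
        labels: list[str] = []

        def pick_raw(group: str) -> str:
            raws = _RAW_BY_GROUP[group]
            return raws[int(rng.integers(len(raws)))]

        groups = list(_RAW_BY_GROUP)
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, size in self.chrom_sizes.items():
            pos = 0
            for g in by_chrom.get(chrom, []):
                seg_start = max(pos, g.span.start - 5_000)
                if seg_start > pos:  # fill the gap with random segments
                    gap_groups = rng.integers(0, len(groups), 1 + (seg_start - pos) // 300_000)
                    bounds = np.linspace(pos, seg_start, len(gap_groups) + 1).astype(int)
                    for i, gi in enumerate(gap_groups):
                        if bounds[i + 1] > bounds[i]:
                            ivs.append(GenomicInterval(chrom, int(bounds[i]), int(bounds[i + 1])))
                            labels.append(pick_raw(groups[gi]))
                seg_end = min(g.span.end + 5_000, size)
                fav, p = group_bias[self.gene_class[g.gene_id]]
                group = fav if rng.random() < p else groups[int(rng.integers(len(groups)))]
                ivs.append(GenomicInterval(chrom, seg_start, seg_end))
                labels.append(pick_raw(group))
                pos = seg_end
            if pos < size:
                ivs.append(GenomicInterval(chrom, pos, size))
                labels.append(pick_raw(groups[int(rng.integers(len(groups)))]))
        return SegmentSet(ivs, labels)

    def _sample_truth(self, rng) -> pd.DataFrame:
        cfg = self.config
        rows = []
        for g in self.genes:
            cls = cfg.classes[self.gene_class[g.gene_id]]
            t_half = float(
                np.clip(np.exp(rng.normal(np.log(cls.median_half_life_h), cls.sigma_half_life)),
                        0.3, 24.0)
            )
            kdeg = math.log(2) / t_half
            expr = float(
                cls.expression_scale * np.exp(rng.normal(0.0, cls.expression_sigma))
            )
            row = {
                "gene_id": g.gene_id,
                "class": self.gene_class[g.gene_id],
                "polyadenylated": g.polyadenylated,
                "expression": expr,
                "kdeg_global": kdeg,
                "t_half_global": t_half,
            }
            for comp in COMPARTMENTS:
                enriched = comp in cls.enrichment_fold
                if enriched:
                    u = rng.random()
                    if u < cls.frac_transient:
                        regime = "transient"
                    elif u < cls.frac_transient + cls.frac_persistent:
                        regime = "persistent"
                    else:
                        regime = "intermediate"
                    ratio = _sample_ratio(rng, regime)
                else:
                    ratio = 1.0
                row[f"enriched_{comp}"] = enriched
                row[f"fold_{comp}"] = cls.enrichment_fold.get(comp, 1.0)
                row[f"ratio_{comp}"] = ratio
                row[f"kdeg_{comp}"] = kdeg * ratio
                row[f"label_{comp}"] = truth_label(ratio)
            rows.append(row)
        return pd.DataFrame(rows)

    def _plant_snps(self, rng) -> set[tuple[str, int]]:
        """Homozygous T>C / A>G variant positions inside gene spans.

        Every read covering such a position shows the variant base, which
        an unlabeled-control mask should identify and exclude. Sites are
        planted where priming concentrates coverage (near the TES of
        polyadenylated genes, near internal anchors otherwise), sampling
        genes proportional to expression, so the control library can
        actually see them.
        """
        cfg = self.config
        snps: set[tuple[str, int]] = set()
        if cfg.n_snps <= 0 or not self.genes:
            return snps
        expr = self.truth.set_index("gene_id")["expression"]
        genes = list(self.genes)
        w = np.array([expr[g.gene_id] for g in genes])
        w /= w.sum()
        for _ in range(cfg.n_snps):
            g = genes[int(rng.choice(len(genes), p=w))]
            L = cfg.read_length
            if g.polyadenylated:
                off = int(rng.integers(10, L + int(cfg.tes_priming_scale)))
                pos = (g.span.start + off) if g.strand == "-" else (g.span.end - off)
            else:
                anchors = self._anchors(g)
                pos = int(anchors[int(rng.integers(len(anchors)))]) + int(
                    rng.integers(0, L)
                )
            pos -= pos % 5  # snap to the T lattice...
            if rng.random() < 0.5:
                pos += 2  # ...or the A lattice
            if g.span.start <= pos < g.span.end:
                snps.add((g.chrom, pos))
        return snps

    # -- reference sequence ------------------------------------------------

    def reference(self, chrom: str) -> np.ndarray:
        """Synthetic reference sequence as a uint8 array of ASCII bases.

        Lattice layout: T at pos % 5 == 0, A at pos % 5 == 2, G/C elsewhere
        (seeded per chromosome, regenerated deterministically on demand).
        """
        cached = self._ref_cache.get(chrom)
        if cached is not None:
            return cached
        size = self.chrom_sizes[chrom]
        ci = list(self.chrom_sizes).index(chrom)
        rng = np.random.default_rng([self.seed, 1_000 + ci])
        seq = np.frombuffer(b"GC", dtype=np.uint8)[rng.integers(0, 2, size)]
        seq[0::5] = ord("T")
        seq[2::5] = ord("A")
        self._ref_cache[chrom] = seq
        return seq

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chrom_sizes:
                fh.write(f">{chrom}\n")
                seq = self.reference(chrom).tobytes().decode()
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    # -- read generation ---------------------------------------------------

    def _fraction_new(self, gene_id: str, library: str) -> float:
        if library == "unlabeled":
            return 0.0
        row = self.truth.set_index("gene_id").loc[gene_id]
        kdeg = row[f"kdeg_{library}"] if library in COMPARTMENTS else row["kdeg_global"]
        return 1.0 - math.exp(-float(kdeg) * self.config.pulse_hours)

    def simulate_library(
        self, library: str, replicate: int, n_reads: int | None = None
    ) -> pd.DataFrame:
        """Generate one replicate library; returns the per-read truth table.

        Columns: read_name, gene_id, chrom, pos (0-based leftmost), strand,
        new (bool), n_T, k. SAM emission (``write_sam``) re-uses this table.
        """
        cfg = self.config
        if library not in LIBRARIES:
            raise SimulationError(
                f"unknown library {library!r} (allowed: {LIBRARIES})"
            )
        lib_idx = LIBRARIES.index(library)
        rng = np.random.default_rng([self.seed, 10 + lib_idx, int(replicate)])
        n_reads = cfg.reads_per_library if n_reads is None else int(n_reads)
        L = cfg.read_length

        tr = self.truth
        expr = tr["expression"].to_numpy()
        fold = (
            np.where(tr[f"enriched_{library}"].to_numpy(), tr[f"fold_{library}"].to_numpy(), 1.0)
            if library in COMPARTMENTS
            else np.ones(len(tr))
        )
        probs = expr * fold
        probs /= probs.sum()
        counts = rng.multinomial(n_reads, probs)

        if library == "unlabeled":
            fnew = np.zeros(len(tr))
        else:
            kcol = f"kdeg_{library}" if library in COMPARTMENTS else "kdeg_global"
            fnew = 1.0 - np.exp(-tr[kcol].to_numpy() * cfg.pulse_hours)

        genes_by_id = {g.gene_id: g for g in self.genes}
        rows = []
        for gi, gene_id in enumerate(tr["gene_id"]):
            m = int(counts[gi])
            if m == 0:
                continue
            g = genes_by_id[gene_id]
            starts = self._read_starts(rng, g, m)
            new = rng.random(m) < fnew[gi]
            for j in range(m):
                s = int(starts[j])
                assayed = self._assayed_positions(g, s)
                n_T = len(assayed)
                p = cfg.p_c if new[j] else cfg.p_e
                k = int(rng.binomial(n_T, p)) if n_T else 0
                conv = rng.choice(n_T, size=k, replace=False) if k else np.empty(0, int)
                rows.append(
                    (
                        gene_id, g.chrom, s, g.strand, bool(new[j]),
                        n_T, k, tuple(int(assayed[c]) for c in conv),
                    )
                )
        df = pd.DataFrame(
            rows,
            columns=["gene_id", "chrom", "pos", "strand", "new", "n_T", "k", "conv"],
        )
        df.sort_values(["chrom", "pos"], kind="mergesort", inplace=True, ignore_index=True)
        df.insert(
            0,
            "read_name",
            [f"{library}.{replicate}.{i:07d}" for i in range(len(df))],
        )
        df["sample"] = library
        df["replicate"] = int(replicate)
        return df

    def _read_starts(self, rng, g: GeneModel, m: int) -> np.ndarray:
        """Read leftmost positions: 3'-biased for polyadenylated genes,
        A-rich-anchor-like internal positions otherwise."""
        cfg = self.config
        L = cfg.read_length
        lo, hi = g.span.start, max(g.span.end - L, g.span.start + 1)
        if g.polyadenylated:
            tes_reads = rng.random(m) < cfg.tes_priming_fraction
            off = rng.exponential(cfg.tes_priming_scale, m).astype(int)
            if g.strand == "-":
                tes_pos = g.span.start + off
            else:
                tes_pos = g.span.end - L - off
            internal = rng.integers(lo, hi, m)
            starts = np.where(tes_reads, tes_pos, internal)
        else:
            anchors = self._anchors(g)
            starts = anchors[rng.integers(0, len(anchors), m)] + rng.integers(-200, 201, m)
        return np.clip(starts, lo, hi - 1 if hi > lo else lo)

    def _anchors(self, g: GeneModel) -> np.ndarray:
        """Gene-specific internal priming anchors (A-rich-stretch stand-ins).

        Seeded per gene from a stable digest of the gene id, so anchors are
        reproducible across libraries and replicates.
        """
        lo, hi = g.span.start, max(g.span.end - self.config.read_length, g.span.start + 1)
        n_anchors = max(2, len(g.span) // 2_000)
        gene_key = int.from_bytes(
            hashlib.sha256(g.gene_id.encode()).digest()[:4], "little"
        )
        arng = np.random.default_rng([self.seed, 2_000, gene_key])
        return arng.integers(lo, hi, n_anchors)

    def _assayed_positions(self, g: GeneModel, start: int) -> np.ndarray:
        """Transcribed-strand reference T positions covered by a read,
        excluding planted variant sites."""
        L = self.config.read_length
        mod = 0 if g.strand != "-" else 2  # ref T lattice vs ref A lattice
        first = start + ((mod - start) % 5)
        pos = np.arange(first, start + L, 5)
        snp = self._snps_by_chrom.get(g.chrom)
        if snp:
            pos = np.array([p for p in pos if p not in snp], dtype=int)
        return pos

    def sam_header_lines(self) -> list[str]:
        lines = ["@HD\tVN:1.6\tSO:coordinate"]
        for chrom, size in self.chrom_sizes.items():
            lines.append(f"@SQ\tSN:{chrom}\tLN:{size}")
        return lines

    def write_sam(self, library: str, replicate: int, path: str | Path,
                  obs: pd.DataFrame | None = None) -> pd.DataFrame:
        """Write one replicate library as plain-text SAM with MD/NM tags.

        Reads are emitted coordinate-sorted; the read sequence is the
        reference window with the drawn conversions (T>C on the transcribed
        strand, appearing as A>G on the reference top strand for - strand
        genes) and any covered homozygous variant applied.
        """
        if obs is None:
            obs = self.simulate_library(library, replicate)
        L = self.config.read_length
        refs = {chrom: self.reference(chrom) for chrom in self.chrom_sizes}
        snps_by_chrom: dict[str, list[int]] = {}
        for c, p in self.snp_positions:
            snps_by_chrom.setdefault(c, []).append(p)
        with open(path, "w") as fh:
            for line in self.sam_header_lines():
                fh.write(line + "\n")
            for row in obs.itertuples(index=False):
                s = row.pos
                ref_win = refs[row.chrom][s : s + L]
                seq = bytearray(ref_win)
                # conversions: transcribed-strand T>C == top-strand A>G on -
                sub = ord("C") if row.strand != "-" else ord("G")
                for p in row.conv:
                    seq[p - s] = sub
                for p in snps_by_chrom.get(row.chrom, ()):
                    if s <= p < s + L:
                        seq[p - s] = ord("C") if p % 5 == 0 else ord("G")
                md, nm = _md_tag(ref_win, bytes(seq))
                flag = 16 if row.strand == "-" else 0
                fh.write(
                    f"{row.read_name}\t{flag}\t{row.chrom}\t{s + 1}\t60\t{L}M\t*\t0\t0\t"
                    f"{bytes(seq).decode()}\t*\tNM:i:{nm}\tMD:Z:{md}\n"
                )
        return obs

    # -- truth / annotation output ----------------------------------------

    def write_truth(self, path: str | Path) -> None:
        write_truth(self.truth, path)


def _md_tag(ref: np.ndarray, seq: bytes) -> tuple[str, int]:
    """MD tag and NM count for an ungapped alignment."""
    parts: list[str] = []
    run = 0
    nm = 0
    ref_b = ref.tobytes()
    for r, q in zip(ref_b, seq):
        if r == q:
            run += 1
        else:
            parts.append(str(run))
            parts.append(chr(r))
            run = 0
            nm += 1
    parts.append(str(run))
    return "".join(parts), nm


# ---------------------------------------------------------------------------
# module-level API
# ---------------------------------------------------------------------------

def simulate_annotation(
    config: SimulationConfig, seed: int | None = None
) -> tuple[list[GeneModel], SegmentSet, SegmentSet]:
    """Sample (genes, peaks, states) for a config; see CompartmentSimulation."""
    sim = CompartmentSimulation(config, seed)
    return sim.genes, sim.peaks, sim.states


def simulate_library(
    sim: CompartmentSimulation, library: str, replicate: int
) -> pd.DataFrame:
    """Per-read truth table for one replicate of one library."""
    return sim.simulate_library(library, replicate)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Serialize the per-gene truth table as TSV (stable column order)."""
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
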