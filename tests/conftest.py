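import numpy as np
import pysam
import pytest
from hypothesis import HealthCheck, settings

from slamkin.simulate import CompartmentSimulation, SimulationConfig, default_classes

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def small_config(reads_per_library: int = 4000, **kwargs) -> SimulationConfig:
    """A scaled-down study design for fast unit tests."""
    classes = default_classes()
    classes["polycomb_adjacent"].n_genes = 6
    classes["speckle"].n_genes = 6
    classes["background"].n_genes = 18
    return SimulationConfig(
        classes=classes, reads_per_library=reads_per_library, n_snps=8, **kwargs
    )


@pytest.fixture(scope="session")
def small_sim() -> CompartmentSimulation:
    return CompartmentSimulation(small_config(), seed=11)


def make_read(
    ref_seq: str,
    read_seq: str,
    chrom: str = "chrT",
    pos: int = 0,
    reverse: bool = False,
    name: str = "toy",
) -> pysam.AlignedSegment:
    """Ungapped toy alignment carrying an MD tag derived from ref vs read."""
    assert len(ref_seq) == len(read_seq)
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": 10_000}]}
    )
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = read_seq
    a.flag = 16 if reverse else 0
    a.reference_id = 0
    a.reference_start = pos
    a.mapping_quality = 60
    a.cigarstring = f"{len(read_seq)}M"
    md_parts, run, nm = [], 0, 0
    for r, q in zip(ref_seq, read_seq):
        if r == q:
            run += 1
        else:
            md_parts += [str(run), r]
            run, nm = 0, nm + 1
    md_parts.append(str(run))
    a.set_tag("MD", "".join(md_parts))
    a.set_tag("NM", nm)
    return a


def brute_force_count(
    ref_seq: str,
    read_seq: str,
    pos: int = 0,
    reverse: bool = False,
    mask: set | None = None,
    chrom: str = "chrT",
) -> tuple[int, int]:
    """Independent per-position string-comparison oracle for (n_T, k)."""
    ref_base, conv_base = ("A", "G") if reverse else ("T", "C")
    n_T = k = 0
    for offset, (r, q) in enumerate(zip(ref_seq, read_seq)):
        if r != ref_base:
            continue
        if mask and (chrom, pos + offset) in mask:
            continue
        n_T += 1
        if q == conv_base:
            k += 1
    return n_T, k
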