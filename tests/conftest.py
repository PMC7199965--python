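import numpy as np
import pytest

from pirdisco.core import (
    AlignedRead,
    Annotation,
    AnnotationSet,
    GenomicInterval,
    Sample,
    SampleSheet,
)
from pirdisco.simulate import SimulationConfig, simulate


def make_read(chrom, start, end, strand, sample="s1", seq=None, name=None):
    return AlignedRead(
        GenomicInterval(chrom, start, end, strand),
        sample_id=sample, sequence=seq, name=name,
    )


def make_ann(chrom, start, end, strand, fid, cls):
    return Annotation(GenomicInterval(chrom, start, end, strand), fid, cls)


#: small, fast configuration shared by unit tests (not the acceptance
#: conditions; those use the generator defaults)
SMALL_SIM = dict(
    contigs=(("chr1", 40_000), ("chr2", 30_000), ("chrM", 16_000)),
    n_pirna_loci=60,
    n_chrm_pirna=8,
    n_mirna_loci=10,
    n_genes=12,
    gene_length_range=(800, 2_000),
    n_trna=6,
    n_rrna=2,
    n_snorna=4,
    mirna_mean_range=(30.0, 100.0),
)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(SimulationConfig(seed=42, **SMALL_SIM))


@pytest.fixture
def two_stage_sheet():
    samples = [
        Sample(f"{st}_{r}", st, r) for st in ("A", "B") for r in (1, 2, 3)
    ]
    return SampleSheet(samples, stages=["A", "B"])


def random_reads(rng, n, contigs, sample="s1", len_range=(15, 45)):
    """Random reads over the given contig-length mapping."""
    names = sorted(contigs)
    out = []
    for i in range(n):
        chrom = names[rng.integers(len(names))]
        L = int(rng.integers(*len_range))
        start = int(rng.integers(0, contigs[chrom] - L))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(make_read(chrom, start, start + L, strand, sample, name=f"r{i}"))
    return out
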