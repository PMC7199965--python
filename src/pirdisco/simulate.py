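"""Synthetic small RNA-seq data with planted ground truth.

The generator emulates the input layers of a staged small-RNA differentiation
experiment: a toy genome, a piRBase-like piRNA locus BED, a DASHR-like ncRNA
exclusion BED, a GENCODE-like gene GTF, and per-sample aligned reads composed
of miRNA-length background (20-23 nt), planted piRNA reads (24-34 nt with a
tunable 5'U probability and negative-binomial counts following stage-specific
temporal patterns), ncRNA/mRNA degradation fragments, and optional antisense
ping-pong partners.

One deliberate quirk is built in: the chrM-like contig carries tRNA/rRNA
genes that appear in the gene models but are absent from the ncRNA exclusion
set, so piRNA loci planted inside them leak through the filtering cascade --
the mitochondrial leak-through scenario observed with real annotation
databases, reproduced here as a testable condition.

All randomness flows from a single ``numpy`` generator seeded from
``SimulationConfig.seed``; identical configs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    AlignedRead,
    Annotation,
    AnnotationSet,
    GenomicInterval,
    Sample,
    SampleSheet,
    revcomp,
)
from . import io as pio

#: Eight stage-specific multiplicative trajectories over (PSC, MPC, CPC).
#: "On" stages sit at the locus baseline, "off" stages at 1% of it; the
#: shapes cover monotone down/up, single-stage, and two-stage patterns.
DEFAULT_CLUSTER_PATTERNS: Tuple[Tuple[float, ...], ...] = (
    (1.0, 0.1, 0.01),   # 1: monotone down
    (0.01, 0.1, 1.0),   # 2: monotone up
    (1.0, 0.01, 0.01),  # 3: PSC-specific
    (0.01, 1.0, 0.01),  # 4: MPC-specific (transient)
    (0.01, 0.01, 1.0),  # 5: CPC-specific
    (1.0, 0.01, 1.0),   # 6: PSC+CPC
    (1.0, 1.0, 0.01),   # 7: PSC+MPC
    (0.01, 1.0, 1.0),   # 8: MPC+CPC
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults describe a three-stage differentiation time course with three
    replicates per stage, 300 piRNA loci following eight temporal patterns,
    a strong (0.8) 5' uridine bias, and no ping-pong amplification.
    """

    seed: int = 0
    contigs: Tuple[Tuple[str, int], ...] = (
        ("chr1", 120_000),
        ("chr2", 100_000),
        ("chr3", 80_000),
        ("chrM", 16_000),
    )
    chrm_name: str = "chrM"
    n_pirna_loci: int = 300
    n_chrm_pirna: int = 30
    pirna_length_range: Tuple[int, int] = (24, 34)
    pirna_locus_length_range: Tuple[int, int] = (30, 40)
    u5_bias: float = 0.8
    n_mirna_loci: int = 40
    mirna_length_range: Tuple[int, int] = (20, 23)
    mirna_mean_range: Tuple[float, float] = (50.0, 500.0)
    n_genes: int = 40
    lncrna_fraction: float = 0.3
    gene_length_range: Tuple[int, int] = (1_000, 4_000)
    n_trna: int = 20
    n_rrna: int = 4
    n_snorna: int = 10
    degradation_rate: float = 2.0  # expected fragments per kb of source per sample
    chrm_degradation_boost: float = 20.0
    degradation_length_range: Tuple[int, int] = (18, 40)
    antisense_degradation_fraction: float = 0.1
    pingpong_fraction: float = 0.0
    stages: Tuple[str, ...] = ("PSC", "MPC", "CPC")
    replicates_per_stage: int = 3
    cluster_patterns: Tuple[Tuple[float, ...], ...] = DEFAULT_CLUSTER_PATTERNS
    nb_dispersion: float = 0.05  # variance = mu + alpha * mu^2
    mean_count_range: Tuple[float, float] = (20.0, 200.0)
    gene_fraction_hosting: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.u5_bias, self.pingpong_fraction, self.gene_fraction_hosting):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if len(self.cluster_patterns) != 8:
            raise ValueError("cluster_patterns must contain 8 templates")
        for t in self.cluster_patterns:
            if len(t) != len(self.stages):
                raise ValueError("each cluster template must have one value per stage")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        names = [c[0] for c in self.contigs]
        if self.chrm_name not in names:
            raise ValueError(f"contigs must include the chrM-like {self.chrm_name!r}")

    def sample_sheet(self) -> SampleSheet:
        samples = [
            Sample(sample_id=f"{stage}_{rep}", stage=stage, replicate=rep)
            for stage in self.stages
            for rep in range(1, self.replicates_per_stage + 1)
        ]
        return SampleSheet(samples, stages=list(self.stages))


@dataclass
class SimulatedGenome:
    """Toy genome plus annotation layers and per-locus ground truth."""

    genome: Dict[str, str]
    pirnas: AnnotationSet
    ncrna: AnnotationSet          # exclusion layer: nuclear small ncRNAs only
    genes: AnnotationSet          # gene models incl. chrM tRNA/rRNA
    locus_truth: pd.DataFrame     # per piRNA locus: cluster, host, stage means
    mirna_means: Dict[str, float]

    @property
    def contig_lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: SimulatedGenome
    reads: Dict[str, List[AlignedRead]]   # sample_id -> reads
    read_truth: pd.DataFrame              # sample_id, read_name, component, source_id
    sheet: SampleSheet


class PlacementError(RuntimeError):
    """Raised when non-overlapping feature placement fails after retries."""


def _place_nonoverlapping(
    rng: np.random.Generator,
    length: int,
    contig: str,
    contig_len: int,
    occupied: Dict[str, List[Tuple[int, int]]],
    within: Optional[Tuple[int, int]] = None,
    max_tries: int = 1000,
) -> Tuple[int, int]:
    lo, hi = (0, contig_len) if within is None else within
    if hi - lo < length:
        raise PlacementError(
            f"window of {hi - lo} bp on {contig} cannot hold a {length} bp feature"
        )
    taken = occupied.setdefault(contig, [])
    for _ in range(max_tries):
        start = int(rng.integers(lo, hi - length + 1))
        end = start + length
        if all(not (start < e and s < end) for s, e in taken):
            taken.append((start, end))
            return start, end
    raise PlacementError(
        f"could not place a {length} bp feature on {contig} after {max_tries} tries"
    )


def build_toy_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate the genome FASTA content, annotation layers and locus truth.

    piRNA loci are non-overlapping; ``gene_fraction_hosting`` of the nuclear
    ones sit fully inside protein_coding/lncRNA gene bodies in sense
    orientation; ``n_chrm_pirna`` sit inside chrM tRNA/rRNA bodies. The
    ncRNA exclusion layer covers nuclear tRNA/rRNA/miRNA/snoRNA only.
    """
    rng = np.random.default_rng(config.seed)
    genome = {
        name: "".join(rng.choice(list("ACGT"), size=length))
        for name, length in config.contigs
    }
    contig_len = {name: length for name, length in config.contigs}
    nuclear = [n for n, _ in config.contigs if n != config.chrm_name]
    chrm = config.chrm_name

    occupied: Dict[str, List[Tuple[int, int]]] = {}
    genes: List[Annotation] = []
    ncrna: List[Annotation] = []

    def _pick_contig(names: Sequence[str]) -> str:
        weights = np.array([contig_len[n] for n in names], dtype=float)
        return str(rng.choice(names, p=weights / weights.sum()))

    # protein-coding and lncRNA genes on nuclear contigs
    n_lnc = int(round(config.n_genes * config.lncrna_fraction))
    for i in range(config.n_genes):
        cls = "lncRNA" if i < n_lnc else "protein_coding"
        contig = _pick_contig(nuclear)
        length = int(rng.integers(*config.gene_length_range))
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = _place_nonoverlapping(rng, length, contig, contig_len[contig], occupied)
        genes.append(
            Annotation(GenomicInterval(contig, start, end, strand), f"GENE{i:04d}", cls)
        )

    # nuclear small ncRNAs: in BOTH the gene models and the exclusion layer
    ncrna_spec = (
        [("tRNA", 75)] * config.n_trna
        + [("rRNA", 1500)] * config.n_rrna
        + [("snoRNA", 120)] * config.n_snorna
    )
    for i, (cls, length) in enumerate(ncrna_spec):
        contig = _pick_contig(nuclear)
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = _place_nonoverlapping(rng, length, contig, contig_len[contig], occupied)
        ann = Annotation(
            GenomicInterval(contig, start, end, strand), f"{cls}-N{i:03d}", cls
        )
        ncrna.append(ann)
        genes.append(ann)

    # miRNA loci: exclusion layer + gene models; read lengths 20-23 fit inside
    mirna_loci: List[Annotation] = []
    lo_m, hi_m = config.mirna_mean_range
    log_mu_m = rng.uniform(np.log(lo_m), np.log(hi_m), size=config.n_mirna_loci)
    mirna_means: Dict[str, float] = {}
    for i in range(config.n_mirna_loci):
        contig = _pick_contig(nuclear)
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = _place_nonoverlapping(rng, 23, contig, contig_len[contig], occupied)
        ann = Annotation(
            GenomicInterval(contig, start, end, strand), f"miR-{i:03d}", "miRNA"
        )
        mirna_loci.append(ann)
        ncrna.append(ann)
        genes.append(ann)
        mirna_means[ann.feature_id] = float(np.exp(log_mu_m[i]))

    # chrM tRNA/rRNA: present in the gene models, ABSENT from the exclusion set
    chrm_features: List[Annotation] = []
    # large features first, so rRNAs always find a free window
    chrm_spec = [("rRNA", 1550), ("rRNA", 950)] + [("tRNA", 70)] * 22
    for i, (cls, length) in enumerate(chrm_spec):
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = _place_nonoverlapping(rng, length, chrm, contig_len[chrm], occupied)
        ann = Annotation(
            GenomicInterval(chrm, start, end, strand), f"{cls}-M{i:03d}", cls
        )
        chrm_features.append(ann)
        genes.append(ann)

    # piRNA loci
    if config.n_chrm_pirna > config.n_pirna_loci:
        raise ValueError("n_chrm_pirna cannot exceed n_pirna_loci")
    host_candidates = [g for g in genes if g.feature_class in ("protein_coding", "lncRNA")]
    pirna_occupied: Dict[str, List[Tuple[int, int]]] = {}
    pirnas: List[Annotation] = []
    truth_rows: List[dict] = []
    n_nuclear_pirna = config.n_pirna_loci - config.n_chrm_pirna
    n_hosted = int(round(n_nuclear_pirna * config.gene_fraction_hosting))
    lo, hi = config.mean_count_range
    baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_pirna_loci))
    clusters = rng.integers(1, 9, size=config.n_pirna_loci)

    for i in range(config.n_pirna_loci):
        length = int(rng.integers(*config.pirna_locus_length_range))
        host_id, host_class, orientation = "", "", "intergenic"
        if i < config.n_chrm_pirna:
            # inside a chrM tRNA/rRNA body, sense; choice weighted by length
            # so the long rRNAs absorb most loci, retrying full features
            w = np.array([len(f.interval) for f in chrm_features], dtype=float)
            for _ in range(100):
                feat = chrm_features[int(rng.choice(len(chrm_features), p=w / w.sum()))]
                iv = feat.interval
                try:
                    start, end = _place_nonoverlapping(
                        rng, length, chrm, contig_len[chrm], pirna_occupied,
                        within=(iv.start, iv.end), max_tries=50,
                    )
                    break
                except PlacementError:
                    continue
            else:
                raise PlacementError("could not place a chrM piRNA locus")
            strand = iv.strand
            host_id, host_class, orientation = feat.feature_id, feat.feature_class, "sense"
            contig = chrm
        elif i < config.n_chrm_pirna + n_hosted and host_candidates:
            w = np.array([len(g.interval) for g in host_candidates], dtype=float)
            for _ in range(100):
                gene = host_candidates[int(rng.choice(len(host_candidates), p=w / w.sum()))]
                iv = gene.interval
                contig = iv.chrom
                try:
                    start, end = _place_nonoverlapping(
                        rng, length, contig, contig_len[contig], pirna_occupied,
                        within=(iv.start, iv.end), max_tries=50,
                    )
                    break
                except PlacementError:
                    continue
            else:
                raise PlacementError("could not place a hosted piRNA locus")
            strand = iv.strand
            host_id, host_class, orientation = gene.feature_id, gene.feature_class, "sense"
        else:
            contig = _pick_contig(nuclear)
            strand = "+" if rng.random() < 0.5 else "-"
            # keep intergenic loci clear of genes and ncRNAs so host truth is exact
            for _ in range(1000):
                start, end = _place_nonoverlapping(
                    rng, length, contig, contig_len[contig], pirna_occupied
                )
                clash = any(
                    g.interval.start < end and start < g.interval.end
                    for g in genes
                    if g.interval.chrom == contig
                )
                if not clash:
                    break
                pirna_occupied[contig].remove((start, end))
            else:
                raise PlacementError("could not place an intergenic piRNA locus")
        locus_id = f"piR-{i:04d}"
        pirnas.append(
            Annotation(GenomicInterval(contig, start, end, strand), locus_id, "piRNA")
        )
        template = config.cluster_patterns[clusters[i] - 1]
        row = {
            "locus_id": locus_id,
            "chrom": contig,
            "start": start,
            "end": end,
            "strand": strand,
            "cluster": int(clusters[i]),
            "baseline_mean": float(baselines[i]),
            "host_gene": host_id,
            "host_class": host_class,
            "orientation": orientation,
        }
        for stage, mult in zip(config.stages, template):
            row[f"mean_{stage}"] = float(baselines[i] * mult)
        truth_rows.append(row)

    truth_cols = [
        "locus_id", "chrom", "start", "end", "strand", "cluster",
        "baseline_mean", "host_gene", "host_class", "orientation",
        *[f"mean_{s}" for s in config.stages],
    ]
    locus_truth = pd.DataFrame(truth_rows, columns=truth_cols)
    return SimulatedGenome(
        genome=genome,
        pirnas=AnnotationSet(pirnas),
        ncrna=AnnotationSet(ncrna),
        genes=AnnotationSet(genes),
        locus_truth=locus_truth,
        mirna_means=mirna_means,
    )


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, alpha: float
) -> np.ndarray:
    """Negative binomial draws with variance mu + alpha*mu^2 (gamma-Poisson)."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def _read_sequence(genome: Dict[str, str], iv: GenomicInterval) -> str:
    seq = genome[iv.chrom][iv.start : iv.end]
    return seq if iv.strand == "+" else revcomp(seq)


def simulate_reads(
    config: SimulationConfig, sim: SimulatedGenome
) -> Tuple[Dict[str, List[AlignedRead]], pd.DataFrame]:
    """Draw per-sample reads from the planted loci.

    piRNA read counts per locus follow NB(mean = baseline x template[stage],
    dispersion alpha); read lengths are uniform in ``pirna_length_range``
    truncated to the locus length, and the 5' base is rewritten to U (T on
    the read strand) with probability ``u5_bias``. With probability
    ``pingpong_fraction`` a read gains an antisense partner whose 5' end
    overlaps the read's 5' end by exactly 10 nt.
    """
    rng = np.random.default_rng(config.seed + 1)
    sheet = config.sample_sheet()
    genome = sim.genome
    contig_len = sim.contig_lengths
    lmin, lmax = config.pirna_length_range
    reads: Dict[str, List[AlignedRead]] = {}
    truth_rows: List[tuple] = []

    # degradation sources: gene bodies and all ncRNA-like features (including
    # the chrM tRNA/rRNA, boosted to emulate heavy mitochondrial turnover)
    deg_sources: List[Annotation] = list(sim.genes)
    deg_weights = np.array(
        [
            len(a.interval)
            * (config.chrm_degradation_boost if a.interval.chrom == config.chrm_name else 1.0)
            for a in deg_sources
        ],
        dtype=float,
    )
    deg_total = float(
        sum(len(a.interval) for a in deg_sources) / 1000.0 * config.degradation_rate
        + sum(
            len(a.interval) for a in deg_sources if a.interval.chrom == config.chrm_name
        )
        / 1000.0
        * config.degradation_rate
        * (config.chrm_degradation_boost - 1.0)
    )

    locus_truth = sim.locus_truth
    for sample in sheet.samples:
        sid = sample.sample_id
        out: List[AlignedRead] = []
        serial = 0

        def _emit(iv: GenomicInterval, seq: str, component: str, source: str) -> None:
            nonlocal serial
            name = f"{sid}.{serial:06d}"
            serial += 1
            out.append(AlignedRead(iv, sample_id=sid, sequence=seq, name=name))
            truth_rows.append((sid, name, component, source))

        # piRNA reads (+ optional ping-pong partners). Reads share the locus
        # 5' end -- piRNA 5' ends are precisely defined, length variation is
        # 3'-trimming -- so the ping-pong geometry stays sharp.
        mus = locus_truth[f"mean_{sample.stage}"].to_numpy()
        counts = _nb_counts(rng, mus, config.nb_dispersion)
        for row, n in zip(locus_truth.itertuples(index=False), counts):
            if n == 0:
                continue
            locus_len = row.end - row.start
            hi = min(lmax, locus_len)
            lengths = rng.integers(lmin, hi + 1, size=n)
            for L in lengths:
                L = int(L)
                if row.strand == "+":
                    iv = GenomicInterval(row.chrom, row.start, row.start + L, "+")
                else:
                    iv = GenomicInterval(row.chrom, row.end - L, row.end, "-")
                seq = _read_sequence(genome, iv)
                # 5' base drawn with P(U) = u5_bias so the empirical 5'U
                # fraction is an unbiased estimate of the planted bias
                if rng.random() < config.u5_bias:
                    seq = "T" + seq[1:]
                else:
                    seq = "ACG"[int(rng.integers(3))] + seq[1:]
                _emit(iv, seq, "piRNA", row.locus_id)
                if config.pingpong_fraction > 0 and rng.random() < config.pingpong_fraction:
                    pl = int(rng.integers(lmin, lmax + 1))
                    piv = _pingpong_partner(iv, pl, contig_len[row.chrom])
                    if piv is not None:
                        _emit(piv, _read_sequence(genome, piv), "pingpong", row.locus_id)

        # miRNA background: precise 5' ends as well, 20-23 nt
        for ann in (a for a in sim.ncrna if a.feature_class == "miRNA"):
            n = int(_nb_counts(rng, np.array([sim.mirna_means[ann.feature_id]]),
                               config.nb_dispersion)[0])
            iv0 = ann.interval
            for _ in range(n):
                L = int(rng.integers(config.mirna_length_range[0],
                                     min(config.mirna_length_range[1], len(iv0)) + 1))
                if iv0.strand == "+":
                    iv = GenomicInterval(iv0.chrom, iv0.start, iv0.start + L, "+")
                else:
                    iv = GenomicInterval(iv0.chrom, iv0.end - L, iv0.end, "-")
                _emit(iv, _read_sequence(genome, iv), "miRNA", ann.feature_id)

        # degradation fragments: uniform over source bodies, 18-40 nt; a
        # small fraction lands antisense (spurious second-strand material)
        n_deg = int(rng.poisson(deg_total))
        picks = rng.choice(len(deg_sources), size=n_deg, p=deg_weights / deg_weights.sum())
        for k in picks:
            src = deg_sources[int(k)]
            iv0 = src.interval
            L = int(rng.integers(config.degradation_length_range[0],
                                 min(config.degradation_length_range[1], len(iv0)) + 1))
            offset = int(rng.integers(0, len(iv0) - L + 1))
            strand = iv0.strand
            if rng.random() < config.antisense_degradation_fraction:
                strand = "-" if strand == "+" else "+"
            iv = GenomicInterval(iv0.chrom, iv0.start + offset, iv0.start + offset + L,
                                 strand)
            _emit(iv, _read_sequence(genome, iv), "degradation", src.feature_id)

        reads[sid] = out

    read_truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "read_name", "component", "source_id"]
    )
    return reads, read_truth


def _pingpong_partner(
    iv: GenomicInterval, length: int, contig_length: int
) -> Optional[GenomicInterval]:
    """Antisense partner with an exact 10-nt 5'-5' overlap."""
    if iv.strand == "+":
        # sense 5' at p = start; partner minus 5' at p+9 -> end = p+10
        end = iv.start + 10
        start = end - length
    else:
        # sense 5' at q = end-1; partner plus 5' at q-9 -> start = q-9
        start = iv.end - 10
        end = start + length
    if start < 0 or end > contig_length:
        return None
    return GenomicInterval(iv.chrom, start, end, "-" if iv.strand == "+" else "+")


def simulate(config: SimulationConfig) -> SimulationResult:
    """Build the toy genome and draw reads for every sample."""
    sim = build_toy_genome(config)
    reads, read_truth = simulate_reads(config, sim)
    return SimulationResult(
        config=config, genome=sim, reads=reads, read_truth=read_truth,
        sheet=config.sample_sheet(),
    )


def write_simulation(result: SimulationResult, outdir) -> Dict[str, Path]:
    """Write FASTA, BED/GTF annotation layers, per-sample read BEDs and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    pio.write_fasta(result.genome.genome, paths["genome"])

    paths["pirna_bed"] = outdir / "pirna.bed"
    pio.write_annotations_bed(result.genome.pirnas, paths["pirna_bed"])
    paths["ncrna_bed"] = outdir / "ncrna.bed"
    _write_classed_bed(result.genome.ncrna, paths["ncrna_bed"])
    paths["genes_gtf"] = outdir / "genes.gtf"
    _write_gtf(result.genome.genes, paths["genes_gtf"])

    for sid, rds in result.reads.items():
        p = outdir / f"reads_{sid}.bed"
        pio.write_alignments_bed(rds, p)
        paths[f"reads_{sid}"] = p

    paths["locus_truth"] = outdir / "truth_loci.tsv"
    result.genome.locus_truth.to_csv(paths["locus_truth"], sep="\t", index=False)
    paths["read_truth"] = outdir / "truth_reads.tsv"
    result.read_truth.to_csv(paths["read_truth"], sep="\t", index=False)

    # read paths are stored relative to the sheet so the tree is relocatable
    sheet_rows = [
        {
            "sample_id": s.sample_id,
            "stage": s.stage,
            "replicate": s.replicate,
            "path": f"reads_{s.sample_id}.bed",
        }
        for s in result.sheet.samples
    ]
    paths["sample_sheet"] = outdir / "samples.tsv"
    pd.DataFrame(sheet_rows).to_csv(paths["sample_sheet"], sep="\t", index=False)
    return paths


def _write_classed_bed(annotations: AnnotationSet, path) -> None:
    # name column carries "<class>:<id>" so the class round-trips through BED
    rows = sorted(
        annotations, key=lambda a: (a.interval.chrom, a.interval.start, a.feature_id)
    )
    with open(path, "w") as fh:
        for a in rows:
            iv = a.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{a.feature_class}:{a.feature_id}\t0\t{iv.strand}\n"
            )


def classed_bed_class_map(name: str) -> Optional[str]:
    """class_map for BEDs written by :func:`_write_classed_bed`."""
    cls, _, _ = name.partition(":")
    return cls or None


def _write_gtf(annotations: AnnotationSet, path) -> None:
    rows = sorted(
        annotations, key=lambda a: (a.interval.chrom, a.interval.start, a.feature_id)
    )
    with open(path, "w") as fh:
        for a in rows:
            iv = a.interval
            attrs = f'gene_id "{a.feature_id}"; gene_type "{a.feature_class}";'
            fh.write(
                f"{iv.chrom}\tpirdisco_sim\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
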