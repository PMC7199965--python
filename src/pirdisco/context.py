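"""Genomic context of identified piRNA loci.

Covers gene intersection with orientation (sense = piRNA strand equals gene
strand), per-chromosome tallies, a shuffle (bootstrap) null for gene-origin
enrichment, percent coverage of host-gene bodies by oriented reads,
piRNAs-per-gene tallies, and generic hypergeometric gene-set
overrepresentation.

The shuffle null relocates every piRNA to a uniform random start on its own
contig, preserving length and strand, and recomputes the intersection
counts; fold enrichment is observed / null mean on a log2 scale with an
empirical p-value using the +1/(n+1) correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import AlignedRead, Annotation, AnnotationSet, GENE_CLASSES
from .diffexp import bh_adjust


@dataclass
class HostAssignment:
    """Per-piRNA host genes: (gene_id, gene_class, orientation) lists."""

    hosts: Dict[str, List[Tuple[str, str, str]]]  # empty list = intergenic
    fraction_genic: float                          # >= 1 gene overlap, any class

    def intergenic(self) -> Set[str]:
        return {pid for pid, h in self.hosts.items() if not h}


def assign_hosts(
    pirnas: AnnotationSet,
    genes: AnnotationSet,
    classes: Optional[Set[str]] = None,
) -> HostAssignment:
    """Intersect piRNA loci with gene bodies (>= 1 bp, strand-aware labels).

    ``classes`` restricts which gene classes count (default: protein_coding
    and lncRNA for the enrichment summaries; pass None explicitly computed
    against the full set by the caller when needed).
    """
    wanted = GENE_CLASSES if classes is None else classes
    hosts: Dict[str, List[Tuple[str, str, str]]] = {}
    n_genic = 0
    for p in pirnas:
        iv = p.interval
        hits = [
            g
            for g in genes.overlapping(iv.chrom, iv.start, iv.end)
            if g.feature_class in wanted
        ]
        entries = [
            (
                g.feature_id,
                g.feature_class,
                "sense" if g.interval.strand == iv.strand else "antisense",
            )
            for g in hits
        ]
        entries.sort()
        hosts[p.feature_id] = entries
        if entries:
            n_genic += 1
    frac = n_genic / len(pirnas) if len(pirnas) else 0.0
    return HostAssignment(hosts=hosts, fraction_genic=frac)


def intersection_counts(
    assignment: HostAssignment, classes: Iterable[str] = tuple(sorted(GENE_CLASSES))
) -> Dict[Tuple[str, str], int]:
    """Number of piRNAs with >= 1 host of each (gene_class, orientation)."""
    out: Dict[Tuple[str, str], int] = {}
    for cls in classes:
        for orient in ("sense", "antisense"):
            out[(cls, orient)] = sum(
                1
                for entries in assignment.hosts.values()
                if any(c == cls and o == orient for _, c, o in entries)
            )
    return out


def _merged_intervals(
    genes: AnnotationSet, chrom: str, strand: str, cls: str
) -> Tuple[np.ndarray, np.ndarray]:
    ivs = sorted(
        (g.interval.start, g.interval.end)
        for g in genes
        if g.feature_class == cls
        and g.interval.chrom == chrom
        and g.interval.strand == strand
    )
    starts: List[int] = []
    ends: List[int] = []
    for s, e in ivs:
        if starts and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts), np.asarray(ends)


def shuffle_null(
    pirnas: AnnotationSet,
    genes: AnnotationSet,
    contig_lengths: Mapping[str, int],
    n_shuffles: int = 1500,
    seed: int = 0,
    classes: Iterable[str] = tuple(sorted(GENE_CLASSES)),
    preserve_contig: bool = True,
) -> Dict[Tuple[str, str], np.ndarray]:
    """Null distribution of gene-intersection counts under random placement.

    Each shuffle relocates every piRNA to a uniform random start on its
    original contig (length- and strand-preserving, fully inside the
    contig); per shuffle and per (gene_class, orientation) the number of
    piRNAs overlapping >= 1 gene is recorded. With
    ``preserve_contig=False`` placement is uniform over the whole genome
    (contigs weighted by length).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    classes = tuple(classes)
    rng = np.random.default_rng(seed)
    plist = list(pirnas)
    for p in plist:
        if len(p.interval) > contig_lengths[p.interval.chrom]:
            raise ValueError(f"{p.feature_id} longer than its contig")
    lengths = np.array([len(p.interval) for p in plist])
    contigs = np.array([p.interval.chrom for p in plist])
    strands = np.array([p.interval.strand for p in plist])
    null: Dict[Tuple[str, str], np.ndarray] = {
        (cls, o): np.zeros(n_shuffles, dtype=int)
        for cls in classes
        for o in ("sense", "antisense")
    }
    if not preserve_contig:
        names = sorted(contig_lengths)
        weights = np.array([contig_lengths[n] for n in names], dtype=float)
        contig_idx = rng.choice(len(names), size=(n_shuffles, len(plist)),
                                p=weights / weights.sum())

    def _accumulate(chrom: str, strand: str, starts: np.ndarray,
                    ends: np.ndarray, which: np.ndarray) -> None:
        # starts/ends: (n_shuffles, k); which: boolean (n_shuffles, k) validity
        for cls in classes:
            for orient in ("sense", "antisense"):
                gstrand = strand if orient == "sense" else ("-" if strand == "+" else "+")
                gs, ge = _merged_intervals(genes, chrom, gstrand, cls)
                if len(gs) == 0:
                    continue
                pos = np.searchsorted(gs, ends, side="left")
                hit = (pos > 0) & (np.take(ge, pos - 1, mode="clip") > starts) & which
                null[(cls, orient)] += hit.sum(axis=1)

    for strand in ("+", "-"):
        smask = strands == strand
        if not smask.any():
            continue
        if preserve_contig:
            for chrom in sorted(set(contigs[smask])):
                mask = smask & (contigs == chrom)
                ls = lengths[mask]
                clen = contig_lengths[chrom]
                starts = rng.integers(0, clen - ls + 1, size=(n_shuffles, mask.sum()))
                _accumulate(chrom, strand, starts, starts + ls,
                            np.ones_like(starts, dtype=bool))
        else:
            ls = lengths[smask]
            cidx = contig_idx[:, smask]
            clens = np.array([contig_lengths[n] for n in names])[cidx]
            valid_high = np.maximum(clens - ls + 1, 1)
            starts = (rng.random(size=cidx.shape) * valid_high).astype(np.int64)
            ends = starts + ls
            for j, chrom in enumerate(names):
                which = (cidx == j) & (ends <= contig_lengths[chrom])
                if which.any():
                    _accumulate(chrom, strand, starts, ends, which)
    return null


@dataclass
class EnrichmentResult:
    gene_class: str
    orientation: str
    observed: int
    null_mean: float
    null_sd: float
    log2_fold_enrichment: float   # -inf sentinel when observed == 0
    p_empirical: float
    n_shuffles: int


def fold_enrichment(
    observed: Mapping[Tuple[str, str], int],
    null: Mapping[Tuple[str, str], np.ndarray],
) -> List[EnrichmentResult]:
    """log2(observed / null mean) with +1-corrected empirical p per key."""
    out: List[EnrichmentResult] = []
    for key in sorted(observed):
        obs = observed[key]
        dist = np.asarray(null[key])
        n = len(dist)
        mean = float(dist.mean())
        sd = float(dist.std(ddof=0))
        if mean <= 0:
            lfe = float("nan")
        elif obs == 0:
            lfe = float("-inf")
        else:
            lfe = float(np.log2(obs / mean))
        p = (int((dist >= obs).sum()) + 1) / (n + 1)
        out.append(
            EnrichmentResult(
                gene_class=key[0], orientation=key[1], observed=int(obs),
                null_mean=mean, null_sd=sd, log2_fold_enrichment=lfe,
                p_empirical=float(p), n_shuffles=n,
            )
        )
    return out


def enrichment_table(results: List[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def gene_coverage(
    reads: Iterable[AlignedRead],
    genes: AnnotationSet,
    orientation: str = "sense",
) -> pd.DataFrame:
    """Percent of each gene body covered by oriented reads (union semantics).

    ``orientation`` selects reads on the gene's strand ("sense") or the
    opposite one ("antisense"); overlapping reads count each base once.
    Returns a frame (gene_id, percent_covered) sorted by gene_id.
    """
    if orientation not in ("sense", "antisense"):
        raise ValueError("orientation must be 'sense' or 'antisense'")
    by_key: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for r in reads:
        iv = r.interval
        by_key.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))
    for key in by_key:
        by_key[key].sort()
    rows = []
    for g in sorted(genes, key=lambda a: a.feature_id):
        iv = g.interval
        want_strand = iv.strand if orientation == "sense" else ("-" if iv.strand == "+" else "+")
        covered = 0
        cur_s, cur_e = None, None
        for s, e in by_key.get((iv.chrom, want_strand), []):
            s, e = max(s, iv.start), min(e, iv.end)
            if e <= s:
                continue
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
        if cur_s is not None:
            covered += cur_e - cur_s
        rows.append({"gene_id": g.feature_id,
                     "percent_covered": 100.0 * covered / len(iv)})
    return pd.DataFrame(rows, columns=["gene_id", "percent_covered"])


def pirnas_per_gene(assignment: HostAssignment) -> Tuple[pd.Series, pd.Series]:
    """Sense piRNAs per host gene, plus a histogram binned 1 / 2 / 3 / >=4."""
    counts: Dict[str, int] = {}
    for entries in assignment.hosts.values():
        for gene_id, _cls, orient in entries:
            if orient == "sense":
                counts[gene_id] = counts.get(gene_id, 0) + 1
    per_gene = pd.Series(counts, dtype=int).sort_index()
    bins = {"1": 0, "2": 0, "3": 0, ">=4": 0}
    for n in per_gene:
        key = str(n) if n < 4 else ">=4"
        bins[key] += 1
    return per_gene, pd.Series(bins)


def chromosome_distribution(pirnas: AnnotationSet) -> pd.Series:
    """piRNA locus count per contig; sums to the total number of loci."""
    out: Dict[str, int] = {}
    for p in pirnas:
        out[p.interval.chrom] = out.get(p.interval.chrom, 0) + 1
    return pd.Series(out, dtype=int).sort_index()


def overrepresentation(
    query: Set[str],
    gene_sets: Mapping[str, Set[str]],
    universe: Set[str],
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of named gene sets in a query.

    Per set: k hits among n query genes, K set members among N universe
    genes, upper-tail p = P[X >= k]; BH across sets; rows sorted by padj
    then set id.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n = len(query)
    N = len(universe)
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"gene_set_id": name, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows)
    df["padj"] = bh_adjust(df["p"])
    return df.sort_values(["padj", "gene_set_id"], kind="mergesort").reset_index(drop=True)


def read_gmt(path) -> Dict[str, Set[str]]:
    """Read GMT gene sets: name <tab> description <tab> gene1 <tab> ..."""
    sets: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3:
                sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets
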