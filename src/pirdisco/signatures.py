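"""Biogenesis-signature statistics.

Primary piRNAs carry a 5' uridine bias, and the secondary (ping-pong)
amplification loop leaves an excess of sense/antisense read pairs whose 5'
ends overlap by exactly 10 nt. This module measures both: per-position base
composition over reads, and the 5'-5' overlap histogram with a z-score of
the 10-nt bin against the other overlap sizes. It also computes scaled
coverage meta-profiles over locus sets.

The biological 5' end of a minus-strand read is its highest genomic
coordinate (end - 1); read sequences are kept read-strand oriented, so
position 1 of every sequence is the biological 5' base.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .core import AlignedRead, AnnotationSet

BASES = ("A", "C", "G", "U")


def base_frequency(
    reads: Iterable[AlignedRead], n_positions: int = 34
) -> pd.DataFrame:
    """Per-position base frequencies from the 5' end (T reported as U).

    Position p (1-based) is computed over reads of length >= p. Returns a
    frame with columns position, A, C, G, U, n_reads; at every position with
    n_reads > 0 the four frequencies sum to 1 (N bases are ignored).
    """
    counts = np.zeros((n_positions, 4), dtype=np.int64)
    n_reads = np.zeros(n_positions, dtype=np.int64)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    any_seq = False
    for r in reads:
        if r.sequence is None:
            continue
        any_seq = True
        seq = r.sequence[:n_positions]
        for p, base in enumerate(seq):
            n_reads[p] += 1
            if base in idx:
                counts[p, idx[base]] += 1
    if not any_seq:
        raise ValueError("base_frequency requires reads with sequences")
    rows = []
    for p in range(n_positions):
        total = counts[p].sum()
        row = {"position": p + 1, "n_reads": int(n_reads[p])}
        for b, j in zip(BASES, range(4)):
            row[b] = counts[p, j] / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows, columns=["position", "A", "C", "G", "U", "n_reads"])


@dataclass
class PingPongProfile:
    """5'-5' overlap histogram h(s) and the 10-nt bin z-score."""

    histogram: Dict[int, int]     # overlap s -> pair count
    z10: Optional[float]          # None when undefined (degenerate background)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"overlap": list(self.histogram), "pairs": list(self.histogram.values())}
        )


def pingpong_profile(
    reads: Iterable[AlignedRead], max_overlap: int = 20
) -> PingPongProfile:
    """Count sense/antisense read pairs by 5'-5' overlap length.

    For a plus-strand read with 5' end at p and a minus-strand read with 5'
    end at q on the same contig, the overlap is s = q - p + 1; every pair
    with 1 <= s <= max_overlap increments h(s). Pairs are enumerated per
    contig by multiplicity of distinct 5' positions, which is exactly
    equivalent to the quadratic all-pairs count. z10 compares h(10) with the
    mean and (n-1 denominator) standard deviation of the other bins; it is
    undefined when the background has fewer than 2 distinct values.
    """
    plus: Dict[str, Counter] = {}
    minus: Dict[str, Counter] = {}
    for r in reads:
        iv = r.interval
        side = plus if iv.strand == "+" else minus
        side.setdefault(iv.chrom, Counter())[r.five_prime] += 1
    hist = {s: 0 for s in range(1, max_overlap + 1)}
    for chrom, pcounts in plus.items():
        mcounts = minus.get(chrom)
        if not mcounts:
            continue
        for p, np_ in pcounts.items():
            for s in range(1, max_overlap + 1):
                nm = mcounts.get(p + s - 1)
                if nm:
                    hist[s] += np_ * nm
    off = np.array([hist[s] for s in hist if s != 10], dtype=float)
    z10: Optional[float] = None
    if len(np.unique(off)) >= 2:
        sd = off.std(ddof=1)
        if sd > 0:
            z10 = float((hist[10] - off.mean()) / sd)
    return PingPongProfile(histogram=hist, z10=z10)


def coverage_profile(
    reads: Iterable[AlignedRead],
    loci: AnnotationSet,
    grid: int = 100,
    library_size: Optional[int] = None,
) -> np.ndarray:
    """Mean CPM-scaled coverage over loci, rescaled to a fixed-length grid.

    Per locus, base-wise depth from same-strand reads is divided by
    (library_size / 1e6), linearly rescaled to ``grid`` positions (5'->3'
    in locus orientation), then averaged across loci.
    """
    if len(loci) == 0:
        raise ValueError("coverage_profile requires a non-empty locus set")
    read_list: List[AlignedRead] = list(reads)
    if library_size is None:
        library_size = len(read_list)
    scale = library_size / 1e6 if library_size > 0 else 1.0
    by_key: Dict[tuple, List[AlignedRead]] = {}
    for r in read_list:
        by_key.setdefault((r.interval.chrom, r.interval.strand), []).append(r)
    profiles = np.zeros((len(loci), grid))
    for i, ann in enumerate(sorted(loci, key=lambda a: a.feature_id)):
        iv = ann.interval
        depth = np.zeros(len(iv))
        for r in by_key.get((iv.chrom, iv.strand), []):
            s = max(r.interval.start, iv.start) - iv.start
            e = min(r.interval.end, iv.end) - iv.start
            if e > s:
                depth[s:e] += 1
        depth /= scale
        if iv.strand == "-":
            depth = depth[::-1]
        src = np.linspace(0, 1, len(depth))
        dst = np.linspace(0, 1, grid)
        profiles[i] = np.interp(dst, src, depth)
    return profiles.mean(axis=0)
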