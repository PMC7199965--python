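"""The two-step filtering cascade from mapped reads to putative-piRNA reads.

Step 1 keeps reads in the piRNA length band (inclusive 24-34 nt by default).
Step 2 removes reads that overlap, on the same strand, any annotation from
the ncRNA exclusion layer (everything small-ncRNA-like except piRNA). Both
steps are pure functions over read collections; per-step accounting is
assembled separately by :func:`filter_report`.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Set

import pandas as pd

from .core import AlignedRead, AnnotationSet, NCRNA_EXCLUDED_CLASSES

DEFAULT_MIN_LEN = 24
DEFAULT_MAX_LEN = 34


def filter_by_length(
    reads: Iterable[AlignedRead],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> List[AlignedRead]:
    """Retain exactly the reads with min_len <= RL <= max_len, in order."""
    if min_len <= 0 or max_len <= 0 or min_len > max_len:
        raise ValueError(f"invalid length bounds [{min_len}, {max_len}]")
    return [r for r in reads if min_len <= r.length <= max_len]


def subtract_ncrna(
    reads: Iterable[AlignedRead],
    ncrna: AnnotationSet,
    excluded_classes: Optional[Set[str]] = None,
    min_overlap: int = 1,
) -> List[AlignedRead]:
    """Remove reads overlapping same-strand excluded-class ncRNA annotations.

    A read is removed when it shares >= ``min_overlap`` bp with any
    annotation on the same strand whose class is in ``excluded_classes``
    (default: all ncRNA classes except piRNA). Opposite-strand overlap and
    piRNA-annotation overlap never remove a read.
    """
    if excluded_classes is None:
        excluded_classes = set(NCRNA_EXCLUDED_CLASSES)
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    kept: List[AlignedRead] = []
    for r in reads:
        iv = r.interval
        hits = ncrna.overlapping(iv.chrom, iv.start, iv.end, strand=iv.strand)
        removed = any(
            h.feature_class in excluded_classes
            and iv.overlap_length(h.interval) >= min_overlap
            for h in hits
        )
        if not removed:
            kept.append(r)
    return kept


def length_density(reads_by_sample: Dict[str, Iterable[AlignedRead]]) -> pd.DataFrame:
    """Per-sample relative frequency of read lengths.

    Returns a tidy frame (sample_id, length, frequency); frequencies sum to
    one within each non-empty sample, and empty samples contribute no rows.
    """
    rows = []
    for sid, reads in reads_by_sample.items():
        counts: Dict[int, int] = {}
        total = 0
        for r in reads:
            counts[r.length] = counts.get(r.length, 0) + 1
            total += 1
        for length in sorted(counts):
            rows.append(
                {"sample_id": sid, "length": length, "frequency": counts[length] / total}
            )
    return pd.DataFrame(rows, columns=["sample_id", "length", "frequency"])


def filter_report(
    unfiltered: Dict[str, int],
    after_length: Dict[str, int],
    after_ncrna: Dict[str, int],
) -> pd.DataFrame:
    """Per-sample read counts at each cascade step, with percent retained."""
    rows = []
    for sid in unfiltered:
        n0, n1, n2 = unfiltered[sid], after_length[sid], after_ncrna[sid]
        if not (n0 >= n1 >= n2 >= 0):
            raise ValueError(f"inconsistent cascade counts for {sid}: {n0}, {n1}, {n2}")
        rows.append(
            {
                "sample_id": sid,
                "n_unfiltered": n0,
                "n_after_length": n1,
                "n_after_ncrna": n2,
                "pct_after_length": 100.0 * n1 / n0 if n0 else 0.0,
                "pct_after_ncrna": 100.0 * n2 / n0 if n0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def run_cascade(
    reads_by_sample: Dict[str, List[AlignedRead]],
    ncrna: AnnotationSet,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    excluded_classes: Optional[Set[str]] = None,
) -> tuple[Dict[str, List[AlignedRead]], pd.DataFrame]:
    """Apply both filters per sample and assemble the FilterReport."""
    n0, n1, n2 = {}, {}, {}
    out: Dict[str, List[AlignedRead]] = {}
    for sid, reads in reads_by_sample.items():
        n0[sid] = len(reads)
        by_len = filter_by_length(reads, min_len, max_len)
        n1[sid] = len(by_len)
        final = subtract_ncrna(by_len, ncrna, excluded_classes)
        n2[sid] = len(final)
        out[sid] = final
    return out, filter_report(n0, n1, n2)
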