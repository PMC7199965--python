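"""Locus-level quantification: counting, CPM normalization, expressed sets.

Counting assigns each filtered read to the same-strand piRNA locus it
overlaps; a read overlapping several loci goes to the one with the largest
overlap (ties to the lexicographically smallest feature id), so counting is
deterministic. A stage's expressed set contains the loci whose mean raw
count across that stage's replicates meets the threshold (>= 3 by default);
the union over stages is the identified catalog.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Literal, Optional, Set

import pandas as pd

from .core import AlignedRead, AnnotationSet, SampleSheet

DEFAULT_MIN_MEAN = 3.0

CountingMode = Literal["largest_overlap", "drop_ambiguous"]


@dataclass
class CountMatrix:
    """Integer piRNA x sample counts plus per-sample library sizes."""

    values: pd.DataFrame            # features x samples, int
    sheet: SampleSheet
    library_sizes: Dict[str, int]   # filtered reads per sample (assigned + not)
    unassigned: Dict[str, int]

    def __post_init__(self) -> None:
        if list(self.values.columns) != self.sheet.sample_ids:
            raise ValueError("count matrix columns must match the sample sheet")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative counts")


def count_reads(
    reads_by_sample: Dict[str, List[AlignedRead]],
    pirnas: AnnotationSet,
    sheet: SampleSheet,
    mode: CountingMode = "largest_overlap",
) -> CountMatrix:
    """Count filtered reads per piRNA locus for every sample in the sheet."""
    missing = [sid for sid in sheet.sample_ids if sid not in reads_by_sample]
    if missing:
        raise ValueError(f"samples without reads: {missing}")
    feature_ids = sorted(a.feature_id for a in pirnas)
    counts = {sid: dict.fromkeys(feature_ids, 0) for sid in sheet.sample_ids}
    unassigned: Dict[str, int] = {}
    library_sizes: Dict[str, int] = {}
    for sid in sheet.sample_ids:
        n_un = 0
        reads = reads_by_sample[sid]
        library_sizes[sid] = len(reads)
        for r in reads:
            target = assign_read(r, pirnas, mode)
            if target is None:
                n_un += 1
            else:
                counts[sid][target] += 1
        unassigned[sid] = n_un
    values = pd.DataFrame(counts, columns=sheet.sample_ids).astype(int)
    values.index.name = "feature_id"
    return CountMatrix(values, sheet, library_sizes, unassigned)


def assign_read(
    read: AlignedRead, pirnas: AnnotationSet, mode: CountingMode = "largest_overlap"
) -> Optional[str]:
    """The feature id the read counts toward, or None if unassigned."""
    iv = read.interval
    hits = [
        h
        for h in pirnas.overlapping(iv.chrom, iv.start, iv.end, strand=iv.strand)
        if h.feature_class == "piRNA"
    ]
    if not hits:
        return None
    if len(hits) > 1 and mode == "drop_ambiguous":
        return None
    best = max(hits, key=lambda h: (iv.overlap_length(h.interval),))
    best_len = iv.overlap_length(best.interval)
    tied = [h for h in hits if iv.overlap_length(h.interval) == best_len]
    return min(t.feature_id for t in tied)


def cpm_normalize(
    counts: CountMatrix, library: Literal["filtered", "assigned"] = "filtered"
) -> pd.DataFrame:
    """Counts per million over the post-filter library (or assigned reads)."""
    totals = {}
    for sid in counts.values.columns:
        if library == "filtered":
            totals[sid] = counts.library_sizes[sid]
        else:
            totals[sid] = int(counts.values[sid].sum())
        if totals[sid] <= 0:
            raise ValueError(f"sample {sid}: zero library size, cannot CPM-normalize")
    return counts.values / pd.Series(totals) * 1e6


@dataclass
class ExpressedSets:
    by_stage: Dict[str, Set[str]]

    @property
    def union(self) -> Set[str]:
        out: Set[str] = set()
        for s in self.by_stage.values():
            out |= s
        return out


def call_expressed(
    counts: CountMatrix, min_mean: float = DEFAULT_MIN_MEAN
) -> ExpressedSets:
    """Stage sets of loci whose mean raw count across replicates >= min_mean."""
    by_stage: Dict[str, Set[str]] = {}
    for stage in counts.sheet.stages:
        sids = [s.sample_id for s in counts.sheet.samples_for_stage(stage)]
        means = counts.values[sids].mean(axis=1)
        by_stage[stage] = set(means.index[means >= min_mean])
    return ExpressedSets(by_stage)


def call_expressed_pooled(
    counts: CountMatrix, min_mean: float = DEFAULT_MIN_MEAN
) -> Set[str]:
    """Variant: loci whose mean raw count over ALL samples >= min_mean."""
    means = counts.values.mean(axis=1)
    return set(means.index[means >= min_mean])


def set_overlaps(sets: ExpressedSets) -> pd.DataFrame:
    """Per-stage sizes plus all pairwise and higher-order intersection counts."""
    stages = list(sets.by_stage)
    rows = [
        {"sets": stage, "count": len(sets.by_stage[stage])} for stage in stages
    ]
    for k in range(2, len(stages) + 1):
        for combo in combinations(stages, k):
            inter: Set[str] = set.intersection(*(sets.by_stage[s] for s in combo))
            rows.append({"sets": "&".join(combo), "count": len(inter)})
    rows.append({"sets": "union", "count": len(sets.union)})
    return pd.DataFrame(rows)


def expressed_table(sets: ExpressedSets) -> pd.DataFrame:
    """One row per catalog locus with a membership flag per stage."""
    stages = list(sets.by_stage)
    rows = []
    for fid in sorted(sets.union):
        row = {"feature_id": fid}
        for stage in stages:
            row[stage] = int(fid in sets.by_stage[stage])
        rows.append(row)
    return pd.DataFrame(rows, columns=["feature_id", *stages])
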