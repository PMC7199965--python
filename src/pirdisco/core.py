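"""Domain types shared by every stage of the pipeline.

All genomic coordinates are internally 0-based half-open (BED convention).
SAM and GTF coordinates are converted on ingest, so interval arithmetic
throughout the package never needs an off-by-one correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from intervaltree import IntervalTree

#: Closed vocabulary of annotation classes.
FEATURE_CLASSES = frozenset(
    {
        "piRNA",
        "miRNA",
        "tRNA",
        "rRNA",
        "snoRNA",
        "other_ncRNA",
        "protein_coding",
        "lncRNA",
    }
)

#: ncRNA classes subtracted from the read set by default (everything
#: small-ncRNA-like except piRNA itself).
NCRNA_EXCLUDED_CLASSES = frozenset({"miRNA", "tRNA", "rRNA", "snoRNA", "other_ncRNA"})

GENE_CLASSES = frozenset({"protein_coding", "lncRNA"})


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class AlignedRead:
    """A mapped small-RNA read.

    ``sequence`` is read-strand oriented (reverse complement already applied
    for minus-strand alignments) and optional; length-based operations only
    need the interval.
    """

    interval: GenomicInterval
    sample_id: str
    sequence: Optional[str] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != len(self.interval):
            raise ValueError(
                f"read {self.name or '?'}: sequence length {len(self.sequence)} "
                f"!= interval length {len(self.interval)}"
            )

    @property
    def length(self) -> int:
        """Read length RL = end - start."""
        return len(self.interval)

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the biological 5' end.

        For a minus-strand read this is the highest coordinate (end - 1).
        """
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


@dataclass(frozen=True)
class Annotation:
    """A strand-aware genomic feature with a class from the closed vocabulary."""

    interval: GenomicInterval
    feature_id: str
    feature_class: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"unknown feature_class {self.feature_class!r} for {self.feature_id}"
            )


class AnnotationSet:
    """A collection of annotations with a per-(chrom, strand) interval index.

    Overlap lookup uses half-open semantics: a query [s, e) returns exactly
    the annotations whose intervals intersect it by >= 1 bp.
    """

    def __init__(self, annotations: Iterable[Annotation]):
        self.annotations: List[Annotation] = list(annotations)
        seen: Dict[str, Annotation] = {}
        for ann in self.annotations:
            if ann.feature_id in seen:
                raise ValueError(f"duplicate feature_id: {ann.feature_id}")
            seen[ann.feature_id] = ann
        self._by_id = seen
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        for ann in self.annotations:
            iv = ann.interval
            key = (iv.chrom, iv.strand)
            self._trees.setdefault(key, IntervalTree()).addi(iv.start, iv.end, ann)

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self) -> Iterator[Annotation]:
        return iter(self.annotations)

    def __getitem__(self, feature_id: str) -> Annotation:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def overlapping(
        self,
        chrom: str,
        start: int,
        end: int,
        strand: Optional[str] = None,
    ) -> List[Annotation]:
        """All annotations intersecting [start, end) on chrom.

        With ``strand`` given, restrict to annotations on that strand.
        """
        hits: List[Annotation] = []
        strands = (strand,) if strand is not None else ("+", "-")
        for s in strands:
            tree = self._trees.get((chrom, s))
            if tree is not None:
                hits.extend(h.data for h in tree.overlap(start, end))
        hits.sort(key=lambda a: (a.interval.start, a.feature_id))
        return hits

    def subset(self, classes: Iterable[str]) -> "AnnotationSet":
        wanted = set(classes)
        return AnnotationSet(a for a in self.annotations if a.feature_class in wanted)

    def class_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for a in self.annotations:
            out[a.feature_class] = out.get(a.feature_class, 0) + 1
        return out


@dataclass
class Sample:
    sample_id: str
    stage: str
    replicate: int
    path: Optional[str] = None


@dataclass
class SampleSheet:
    """Stage x replicate layout of the experiment.

    ``stages`` is the ordered list of differentiation stages (e.g.
    PSC -> MPC -> CPC); contrasts are derived from this order.
    """

    samples: List[Sample]
    stages: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.stages:
            seen: List[str] = []
            for s in self.samples:
                if s.stage not in seen:
                    seen.append(s.stage)
            self.stages = seen
        pairs = [(s.stage, s.replicate) for s in self.samples]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (stage, replicate) pair in sample sheet")
        for stage in self.stages:
            if not any(s.stage == stage for s in self.samples):
                raise ValueError(f"stage {stage} has no samples")
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample_id in sample sheet")

    @property
    def sample_ids(self) -> List[str]:
        return [s.sample_id for s in self.samples]

    def samples_for_stage(self, stage: str) -> List[Sample]:
        return [s for s in self.samples if s.stage == stage]

    def stage_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.stage
        raise KeyError(sample_id)

    def contrasts(self) -> List[Tuple[str, str]]:
        """All ordered later-vs-earlier stage pairs (B over A as (A, B))."""
        out = []
        for i, a in enumerate(self.stages):
            for b in self.stages[i + 1 :]:
                out.append((a, b))
        return out


REV = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(REV)[::-1]
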