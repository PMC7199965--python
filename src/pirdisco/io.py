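"""Readers and writers for the standard formats the pipeline consumes.

Alignments come in as SAM/BAM (via pysam) or BED6 with the read sequence in
an optional seventh column (or a FASTA sidecar keyed by read name).
Annotations come in as BED6 or GENCODE-dialect GTF. All coordinates are
converted to 0-based half-open on ingest.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Union

import pandas as pd
import pysam

from .core import (
    AlignedRead,
    Annotation,
    AnnotationSet,
    GenomicInterval,
    FEATURE_CLASSES,
    revcomp,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A record that does not parse under the named standard."""


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def read_alignments(
    path: PathLike,
    format: Optional[str] = None,
    sample_id: Optional[str] = None,
    sequence_sidecar: Optional[PathLike] = None,
) -> List[AlignedRead]:
    """Read mapped, primary alignments into :class:`AlignedRead` records.

    Unmapped, secondary and supplementary records are skipped. ``format``
    is inferred from the suffix when not given. For BED input the sequence
    is taken from column 7 when present, else from ``sequence_sidecar``
    (FASTA keyed by read name), else left as None.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".bam": "BAM", ".sam": "SAM", ".bed": "BED"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer alignment format from {path.name}")
    format = format.upper()
    sid = sample_id if sample_id is not None else path.stem
    if format in ("SAM", "BAM"):
        return _read_sam(path, format, sid)
    if format == "BED":
        return _read_bed_reads(path, sid, sequence_sidecar)
    raise ValueError(f"unsupported alignment format: {format}")


def _read_sam(path: Path, format: str, sample_id: str) -> List[AlignedRead]:
    mode = "rb" if format == "BAM" else "r"
    reads: List[AlignedRead] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            strand = "-" if rec.is_reverse else "+"
            seq = rec.query_sequence
            # pysam reports the sequence as stored (reference-forward); a
            # minus-strand read's biological sequence is its reverse complement
            if seq is not None and strand == "-":
                seq = revcomp(seq)
            iv = GenomicInterval(
                rec.reference_name, rec.reference_start, rec.reference_end, strand
            )
            if seq is not None and len(seq) != len(iv):
                seq = None  # indels/clips: keep the interval, drop the sequence
            reads.append(
                AlignedRead(iv, sample_id=sample_id, sequence=seq, name=rec.query_name)
            )
    return reads


def _read_bed_reads(
    path: Path, sample_id: str, sidecar: Optional[PathLike]
) -> List[AlignedRead]:
    seq_by_name: Dict[str, str] = {}
    if sidecar is not None:
        seq_by_name = _read_fasta(sidecar)
    reads: List[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path.name}:{lineno}: BED6 needs >= 6 columns")
            try:
                chrom, start, end, name, _score, strand = fields[:6]
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
            seq = fields[6] if len(fields) > 6 and fields[6] not in (".", "") else None
            if seq is None and name in seq_by_name:
                seq = seq_by_name[name]
            reads.append(AlignedRead(iv, sample_id=sample_id, sequence=seq, name=name))
    return reads


def write_alignments_bed(reads: Iterable[AlignedRead], path: PathLike) -> None:
    """Write reads as BED6 plus sequence in column 7 ('.' when absent)."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            iv = r.interval
            name = r.name if r.name is not None else f"read{i}"
            seq = r.sequence if r.sequence is not None else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\t{seq}\n"
            )


def _read_fasta(path: PathLike) -> Dict[str, str]:
    seqs: Dict[str, str] = {}
    name = None
    chunks: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read a (small) FASTA file into a name -> sequence dict."""
    return _read_fasta(path)


def write_fasta(seqs: Mapping[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

ClassMap = Union[Mapping[str, str], Callable[[str], Optional[str]]]


def _resolve_class(name: str, class_map: Optional[ClassMap]) -> str:
    cls: Optional[str] = None
    if class_map is None:
        cls = name if name in FEATURE_CLASSES else None
    elif callable(class_map):
        cls = class_map(name)
    else:
        cls = class_map.get(name)
        if cls is None:  # prefix matching, piRBase-style ids like piR-0001
            for prefix, mapped in class_map.items():
                if name.startswith(prefix):
                    cls = mapped
                    break
    if cls is None:
        logger.warning("unknown feature class for %r; mapping to other_ncRNA", name)
        cls = "other_ncRNA"
    if cls not in FEATURE_CLASSES:
        raise ValueError(f"class_map produced unknown class {cls!r} for {name!r}")
    return cls


def read_annotations(
    path: PathLike,
    format: Optional[str] = None,
    class_map: Optional[ClassMap] = None,
    default_class: Optional[str] = None,
) -> AnnotationSet:
    """Read a BED6 or GTF annotation file into an :class:`AnnotationSet`.

    For GTF, one annotation per ``gene`` row (gene-body interval), classed
    by the ``gene_type`` attribute through ``class_map``. For BED, the name
    column maps through ``class_map``; ``default_class`` short-circuits the
    mapping when the whole file is one class (e.g. a piRBase-style BED).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"gtf": "GTF", ".gtf": "GTF", ".bed": "BED"}.get(suffix, None)
        if format is None:
            raise ValueError(f"cannot infer annotation format from {path.name}")
    format = format.upper()
    if format == "BED":
        anns = _read_bed_annotations(path, class_map, default_class)
    elif format == "GTF":
        anns = _read_gtf_genes(path, class_map)
    else:
        raise ValueError(f"unsupported annotation format: {format}")
    if not anns:
        raise ValueError(f"{path}: zero features after parsing")
    return AnnotationSet(anns)


def _read_bed_annotations(
    path: Path, class_map: Optional[ClassMap], default_class: Optional[str]
) -> List[Annotation]:
    anns: List[Annotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path.name}:{lineno}: BED6 needs >= 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
            cls = default_class or _resolve_class(name, class_map)
            anns.append(Annotation(iv, feature_id=name, feature_class=cls))
    return anns


def _parse_gtf_attributes(attr: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for part in attr.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _read_gtf_genes(path: Path, class_map: Optional[ClassMap]) -> List[Annotation]:
    anns: List[Annotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path.name}:{lineno}: GTF needs 9 columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "gene":
                continue
            attributes = _parse_gtf_attributes(attrs)
            gene_id = attributes.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path.name}:{lineno}: gene row without gene_id")
            biotype = attributes.get("gene_type", attributes.get("gene_biotype", ""))
            cls = _resolve_class(biotype, class_map)
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
            anns.append(Annotation(iv, feature_id=gene_id, feature_class=cls))
    return anns


def write_annotations_bed(annotations: AnnotationSet, path: PathLike) -> None:
    """Write an AnnotationSet as BED6; round-trips through read_annotations
    when a class_map recovers each feature's class from its id."""
    rows = sorted(
        annotations,
        key=lambda a: (a.interval.chrom, a.interval.start, a.feature_id),
    )
    with open(path, "w") as fh:
        for a in rows:
            iv = a.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{a.feature_id}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def _format_value(v: object, col: str) -> str:
    if isinstance(v, float):
        if col in ("p", "pvalue", "padj", "p_empirical"):
            return repr(v)
        return f"{v:.6g}"
    return str(v)


def write_table(
    rows: pd.DataFrame,
    path: PathLike,
    sort_by: Optional[List[str]] = None,
    allow_empty: bool = False,
) -> None:
    """Write a result table as TSV with deterministic formatting.

    p-value-like columns keep full precision; other floats are rendered with
    6 significant digits. Rows are sorted by ``sort_by`` (default: all
    columns) so repeated runs produce byte-identical files.
    """
    if rows.empty and not allow_empty:
        raise ValueError(f"refusing to write empty table to {path}")
    df = rows.copy()
    if not df.empty:
        keys = sort_by if sort_by else list(df.columns)
        df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for _, row in df.iterrows():
            fh.write(
                "\t".join(_format_value(v, c) for c, v in zip(df.columns, row)) + "\n"
            )


def read_sample_sheet(path: PathLike):
    """Read a sample sheet TSV with columns sample_id, stage, replicate, path.

    Relative read paths are resolved against the sheet's own directory.
    """
    from .core import Sample, SampleSheet

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "stage", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    samples = []
    for _, r in df.iterrows():
        p = r.get("path")
        if p is not None and not Path(p).is_absolute():
            p = str(path.parent / p)
        samples.append(
            Sample(
                sample_id=r["sample_id"],
                stage=r["stage"],
                replicate=int(r["replicate"]),
                path=p,
            )
        )
    return SampleSheet(samples)
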