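import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pirdisco.core import Annotation, AnnotationSet, GenomicInterval, SampleSheet, Sample
from pirdisco import io as pio
from .conftest import make_ann, make_read


class TestGenomicInterval:
    def test_rejects_inverted_and_empty(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10, "+")
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5, "+")
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 5, "*")

    def test_half_open_overlap(self):
        a = GenomicInterval("chr1", 0, 10, "+")
        assert not a.overlaps(GenomicInterval("chr1", 10, 20, "+"))  # abutting
        assert a.overlaps(GenomicInterval("chr1", 9, 20, "-"))
        assert not a.overlaps(GenomicInterval("chr2", 0, 10, "+"))
        assert a.overlap_length(GenomicInterval("chr1", 5, 20, "+")) == 5


class TestAnnotationSet:
    def test_duplicate_id_rejected(self):
        anns = [make_ann("chr1", 0, 10, "+", "x", "piRNA"),
                make_ann("chr1", 20, 30, "+", "x", "piRNA")]
        with pytest.raises(ValueError, match="duplicate"):
            AnnotationSet(anns)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_overlap_lookup_matches_linear_scan(self, seed):
        rng = np.random.default_rng(seed)
        anns = []
        for i in range(60):
            start = int(rng.integers(0, 900))
            end = start + int(rng.integers(1, 120))
            strand = "+" if rng.random() < 0.5 else "-"
            anns.append(make_ann("c", start, end, strand, f"a{i}", "piRNA"))
        aset = AnnotationSet(anns)
        qs = int(rng.integers(0, 950))
        qe = qs + int(rng.integers(1, 80))
        for strand in (None, "+", "-"):
            got = {a.feature_id for a in aset.overlapping("c", qs, qe, strand)}
            want = {
                a.feature_id for a in anns
                if a.interval.start < qe and qs < a.interval.end
                and (strand is None or a.interval.strand == strand)
            }
            assert got == want


class TestSampleSheet:
    def test_duplicate_stage_replicate_rejected(self):
        with pytest.raises(ValueError):
            SampleSheet([Sample("a", "PSC", 1), Sample("b", "PSC", 1)])

    def test_contrasts_follow_stage_order(self):
        sheet = SampleSheet(
            [Sample(f"{s}_1", s, 1) for s in ("PSC", "MPC", "CPC")],
            stages=["PSC", "MPC", "CPC"],
        )
        assert sheet.contrasts() == [("PSC", "MPC"), ("PSC", "CPC"), ("MPC", "CPC")]


class TestReadAlignments:
    def test_bed_with_sequence_column(self, tmp_path):
        p = tmp_path / "reads.bed"
        p.write_text("chr1\t100\t125\tr1\t0\t+\t" + "A" * 25 + "\n")
        reads = pio.read_alignments(p, format="BED", sample_id="s1")
        (r,) = reads
        assert (r.interval.chrom, r.interval.start, r.interval.end) == ("chr1", 100, 125)
        assert r.length == 25 and r.sequence == "A" * 25

    def test_bed_fasta_sidecar(self, tmp_path):
        bed = tmp_path / "reads.bed"
        bed.write_text("chr1\t0\t4\trx\t0\t-\n")
        fa = tmp_path / "reads.fa"
        fa.write_text(">rx\nACGT\n")
        (r,) = pio.read_alignments(bed, format="BED", sequence_sidecar=fa)
        assert r.sequence == "ACGT"

    def test_sam_skips_unmapped_and_secondary(self, tmp_path):
        sam = tmp_path / "a.sam"
        lines = [
            "@HD\tVN:1.6\tSO:unsorted",
            "@SQ\tSN:chr1\tLN:1000",
            # mapped primary, plus strand: 1-based POS 101 -> 0-based 100
            "r1\t0\tchr1\t101\t255\t25M\t*\t0\t0\t" + "A" * 25 + "\t*",
            # unmapped (flag 4)
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*",
            # secondary (flag 256)
            "r3\t256\tchr1\t201\t255\t25M\t*\t0\t0\t" + "C" * 25 + "\t*",
            # reverse strand (flag 16): stored sequence is reverse-complemented
            "r4\t16\tchr1\t301\t255\t4M\t*\t0\t0\tACGT\t*",
        ]
        sam.write_text("\n".join(lines) + "\n")
        reads = pio.read_alignments(sam, format="SAM", sample_id="s")
        assert [r.name for r in reads] == ["r1", "r4"]
        assert reads[0].interval.start == 100  # SAM 1-based -> internal 0-based
        assert reads[1].interval.strand == "-"
        assert reads[1].sequence == "ACGT"[::-1].translate(str.maketrans("ACGT", "TGCA"))

    def test_primary_count_matches_flag_scan(self, tmp_path):
        rng = np.random.default_rng(0)
        sam = tmp_path / "b.sam"
        lines = ["@SQ\tSN:chr1\tLN:100000"]
        n_primary = 0
        for i in range(300):
            secondary = rng.random() < 0.2
            flag = 256 if secondary else 0
            n_primary += not secondary
            pos = int(rng.integers(1, 90_000))
            lines.append(f"q{i}\t{flag}\tchr1\t{pos}\t255\t30M\t*\t0\t0\t{'A'*30}\t*")
        sam.write_text("\n".join(lines) + "\n")
        assert len(pio.read_alignments(sam, format="SAM")) == n_primary

    def test_malformed_bed_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t5\t1\tr\t0\t+\n")
        with pytest.raises(pio.ParseError, match="bad.bed:1"):
            pio.read_alignments(p, format="BED")


class TestReadAnnotations:
    def test_gtf_gene_rows_with_biotypes(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        rows = []
        classes = ["protein_coding", "lncRNA", "tRNA"]
        for i in range(10):
            cls = classes[i % 3]
            rows.append(
                f"chr1\tsrc\tgene\t{100*i+1}\t{100*i+90}\t.\t+\t.\t"
                f'gene_id "G{i}"; gene_type "{cls}";'
            )
            rows.append(  # exon rows must be ignored
                f"chr1\tsrc\texon\t{100*i+1}\t{100*i+50}\t.\t+\t.\t"
                f'gene_id "G{i}"; gene_type "{cls}";'
            )
        gtf.write_text("\n".join(rows) + "\n")
        aset = pio.read_annotations(gtf, format="GTF",
                                    class_map={c: c for c in classes})
        assert len(aset) == 10
        assert aset.class_counts() == {"protein_coding": 4, "lncRNA": 3, "tRNA": 3}
        assert aset["G0"].interval.start == 0  # GTF 1-based -> 0-based

    def test_bed_prefix_class_map(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr1\t10\t40\tpiR-0001\t0\t+\n")
        aset = pio.read_annotations(bed, format="BED", class_map={"piR-": "piRNA"})
        assert aset["piR-0001"].feature_class == "piRNA"

    def test_unknown_class_maps_to_other_ncrna(self, tmp_path):
        bed = tmp_path / "u.bed"
        bed.write_text("chr1\t10\t40\tmystery\t0\t+\n")
        aset = pio.read_annotations(bed, format="BED", class_map={})
        assert aset["mystery"].feature_class == "other_ncRNA"

    def test_empty_file_is_an_error(self, tmp_path):
        bed = tmp_path / "e.bed"
        bed.write_text("")
        with pytest.raises(ValueError, match="zero features"):
            pio.read_annotations(bed, format="BED")

    def test_bed_round_trip(self, tmp_path):
        anns = [make_ann("chr2", 5, 50, "-", "piR-x", "piRNA"),
                make_ann("chr1", 0, 30, "+", "piR-y", "piRNA")]
        aset = AnnotationSet(anns)
        p = tmp_path / "rt.bed"
        pio.write_annotations_bed(aset, p)
        back = pio.read_annotations(p, format="BED", default_class="piRNA")
        assert {
            (a.feature_id, a.interval.chrom, a.interval.start,
             a.interval.end, a.interval.strand, a.feature_class)
            for a in back
        } == {
            (a.feature_id, a.interval.chrom, a.interval.start,
             a.interval.end, a.interval.strand, a.feature_class)
            for a in aset
        }


class TestWriteTable:
    def test_empty_allowed_writes_header_only(self, tmp_path):
        p = tmp_path / "t.tsv"
        pio.write_table(pd.DataFrame(columns=["a", "b"]), p, allow_empty=True)
        assert p.read_text() == "a\tb\n"

    def test_byte_identical_on_repeat(self, tmp_path):
        df = pd.DataFrame({"feature_id": [f"f{i}" for i in range(20)],
                           "p": np.random.default_rng(1).random(20)})
        p1, p2 = tmp_path / "1.tsv", tmp_path / "2.tsv"
        pio.write_table(df, p1, sort_by=["feature_id"])
        pio.write_table(df.sample(frac=1, random_state=7), p2, sort_by=["feature_id"])
        assert p1.read_bytes() == p2.read_bytes()

    def test_line_count_is_rows_plus_header(self, tmp_path):
        df = pd.DataFrame({"k": range(447), "v": range(447)})
        p = tmp_path / "t.tsv"
        pio.write_table(df, p, sort_by=["k"])
        assert len(p.read_text().splitlines()) == 448
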