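import numpy as np
import pytest
from scipy import stats

from pirdisco.core import AnnotationSet
from pirdisco.context import (
    assign_hosts,
    chromosome_distribution,
    fold_enrichment,
    gene_coverage,
    intersection_counts,
    overrepresentation,
    pirnas_per_gene,
    read_gmt,
    shuffle_null,
)
from .conftest import make_ann, make_read


class TestAssignHosts:
    def test_orientation_labels(self):
        genes = AnnotationSet([make_ann("c", 0, 1000, "+", "G1", "protein_coding")])
        sense = AnnotationSet([make_ann("c", 100, 130, "+", "p1", "piRNA")])
        anti = AnnotationSet([make_ann("c", 100, 130, "-", "p2", "piRNA")])
        assert assign_hosts(sense, genes).hosts["p1"] == [
            ("G1", "protein_coding", "sense")]
        assert assign_hosts(anti, genes).hosts["p2"] == [
            ("G1", "protein_coding", "antisense")]

    def test_intersection_counts_by_class_and_orientation(self):
        genes = AnnotationSet([
            make_ann("c", 0, 1_000, "+", "G1", "protein_coding"),
            make_ann("c", 2_000, 3_000, "-", "L1", "lncRNA"),
        ])
        pirnas = AnnotationSet([
            make_ann("c", 100, 130, "+", "p1", "piRNA"),    # sense pc
            make_ann("c", 200, 230, "-", "p2", "piRNA"),    # antisense pc
            make_ann("c", 2_100, 2_130, "-", "p3", "piRNA"),  # sense lnc
        ])
        counts = intersection_counts(assign_hosts(pirnas, genes))
        assert counts[("protein_coding", "sense")] == 1
        assert counts[("protein_coding", "antisense")] == 1
        assert counts[("lncRNA", "sense")] == 1
        assert counts[("lncRNA", "antisense")] == 0

    def test_gene_free_contig_is_intergenic(self):
        genes = AnnotationSet([make_ann("c", 0, 1000, "+", "G1", "protein_coding")])
        p = AnnotationSet([make_ann("c2", 100, 130, "+", "p1", "piRNA")])
        res = assign_hosts(p, genes)
        assert res.intergenic() == {"p1"}
        assert res.fraction_genic == 0.0

    def test_truth_recovered_on_simulation(self, small_sim):
        """Host assignment matches the generator's planted hosting truth for
        nuclear loci (chrM hosts are tRNA/rRNA, outside the gene classes)."""
        lt = small_sim.genome.locus_truth
        gene_models = small_sim.genome.genes.subset(["protein_coding", "lncRNA"])
        res = assign_hosts(small_sim.genome.pirnas, gene_models)
        for row in lt.itertuples():
            hosted = row.host_class in ("protein_coding", "lncRNA")
            got = res.hosts[row.locus_id]
            if hosted:
                assert (row.host_gene, row.host_class, "sense") in got
            elif row.chrom != "chrM":
                assert got == []


class TestShuffleNull:
    def test_zero_shuffles_rejected(self):
        p = AnnotationSet([make_ann("c", 0, 30, "+", "p", "piRNA")])
        g = AnnotationSet([make_ann("c", 0, 50, "+", "G", "protein_coding")])
        with pytest.raises(ValueError):
            shuffle_null(p, g, {"c": 1000}, n_shuffles=0)

    def test_full_tiling_forces_every_pirna_to_intersect(self):
        genes = AnnotationSet([
            make_ann("c", 0, 10_000, "+", "Gp", "protein_coding"),
            make_ann("c", 0, 10_000, "-", "Gm", "protein_coding"),
        ])
        pirnas = AnnotationSet([
            make_ann("c", i * 40, i * 40 + 30, "+", f"p{i}", "piRNA")
            for i in range(20)
        ])
        null = shuffle_null(pirnas, genes, {"c": 10_000}, n_shuffles=50, seed=0)
        assert (null[("protein_coding", "sense")] == 20).all()
        assert (null[("protein_coding", "antisense")] == 20).all()

    def test_null_mean_matches_binomial_placement_oracle(self):
        """Genes covering fraction f -> null mean ~ f * n within 3 SE."""
        clen, glen, n, L = 100_000, 10_000, 200, 31
        genes = AnnotationSet([make_ann("c", 20_000, 20_000 + glen, "+",
                                        "G", "protein_coding")])
        pirnas = AnnotationSet([
            make_ann("c", i * 45, i * 45 + L, "+", f"p{i}", "piRNA")
            for i in range(n)
        ])
        n_shuffles = 400
        null = shuffle_null(pirnas, genes, {"c": clen},
                            n_shuffles=n_shuffles, seed=1)
        p_hit = (glen + L - 1) / (clen - L + 1)
        expect = n * p_hit
        se = np.sqrt(n * p_hit * (1 - p_hit) / n_shuffles)
        got = null[("protein_coding", "sense")].mean()
        assert abs(got - expect) < 3 * se

    def test_shuffling_a_shuffle_is_exchangeable(self):
        """Intersection-count distributions from a piRNA set and from an
        already-relocated copy are statistically indistinguishable."""
        rng = np.random.default_rng(7)
        clen = 50_000
        genes = AnnotationSet([
            make_ann("c", int(s), int(s) + 800, "+", f"G{i}", "protein_coding")
            for i, s in enumerate(range(1000, 40_000, 5_000))
        ])
        orig = AnnotationSet([
            make_ann("c", int(s), int(s) + 30, "+", f"p{i}", "piRNA")
            for i, s in enumerate(rng.integers(0, clen - 30, size=100))
        ])
        moved = AnnotationSet([
            make_ann("c", int(s), int(s) + 30, "+", f"q{i}", "piRNA")
            for i, s in enumerate(rng.integers(0, clen - 30, size=100))
        ])
        d1 = shuffle_null(orig, genes, {"c": clen}, n_shuffles=300, seed=2)
        d2 = shuffle_null(moved, genes, {"c": clen}, n_shuffles=300, seed=3)
        ks = stats.ks_2samp(d1[("protein_coding", "sense")],
                            d2[("protein_coding", "sense")])
        assert ks.pvalue > 0.01


class TestFoldEnrichment:
    def test_observed_equal_to_null_mean_is_zero(self):
        null = {("protein_coding", "sense"): np.full(100, 40)}
        (res,) = fold_enrichment({("protein_coding", "sense"): 40}, null)
        assert res.log2_fold_enrichment == pytest.approx(0.0)
        # every null draw >= observed -> p = (100+1)/(100+1)
        assert res.p_empirical == pytest.approx(1.0)

    def test_zero_observed_gives_sentinel(self):
        null = {("lncRNA", "sense"): np.full(50, 10)}
        (res,) = fold_enrichment({("lncRNA", "sense"): 0}, null)
        assert res.log2_fold_enrichment == float("-inf")
        assert res.p_empirical == pytest.approx(1.0)

    def test_empirical_p_plus_one_correction(self):
        null = {("lncRNA", "sense"): np.arange(100)}  # 0..99
        (res,) = fold_enrichment({("lncRNA", "sense"): 1000}, null)
        assert res.p_empirical == pytest.approx(1 / 101)


class TestGeneCoverage:
    def test_five_percent_single_read(self):
        genes = AnnotationSet([make_ann("c", 0, 1000, "+", "G", "protein_coding")])
        reads = [make_read("c", 100, 150, "+")]
        df = gene_coverage(reads, genes, "sense")
        assert df.percent_covered.item() == pytest.approx(5.0)
        assert gene_coverage(reads, genes, "antisense").percent_covered.item() == 0.0

    def test_duplicate_read_does_not_change_percent(self):
        genes = AnnotationSet([make_ann("c", 0, 1000, "+", "G", "protein_coding")])
        reads = [make_read("c", 100, 150, "+")]
        once = gene_coverage(reads, genes, "sense").percent_covered.item()
        twice = gene_coverage(reads * 2, genes, "sense").percent_covered.item()
        assert once == twice

    def test_matches_bitmap_oracle(self):
        rng = np.random.default_rng(8)
        glen = 5_000
        genes = AnnotationSet([make_ann("c", 100, 100 + glen, "-", "G",
                                        "lncRNA")])
        reads = []
        mask = np.zeros(glen, dtype=bool)
        for _ in range(300):
            start = int(rng.integers(0, 5_300))
            L = int(rng.integers(18, 41))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(make_read("c", start, start + L, strand))
            if strand == "-":  # sense for a minus-strand gene
                s = max(start, 100) - 100
                e = min(start + L, 100 + glen) - 100
                if e > s:
                    mask[s:e] = True
        df = gene_coverage(reads, genes, "sense")
        assert df.percent_covered.item() == pytest.approx(100 * mask.mean())


class TestPerGeneTallies:
    def test_sense_only_counting(self):
        genes = AnnotationSet([make_ann("c", 0, 5_000, "+", "G", "protein_coding")])
        pirnas = AnnotationSet(
            [make_ann("c", 100 * i, 100 * i + 30, "+", f"s{i}", "piRNA")
             for i in range(12)]
            + [make_ann("c", 3_000, 3_030, "-", "anti", "piRNA")]
        )
        hosts = assign_hosts(pirnas, genes)
        per_gene, hist = pirnas_per_gene(hosts)
        assert per_gene["G"] == 12
        assert hist[">=4"] == 1 and hist["1"] == 0

    def test_antisense_only_gene_absent(self):
        genes = AnnotationSet([make_ann("c", 0, 1_000, "+", "G", "protein_coding")])
        pirnas = AnnotationSet([make_ann("c", 10, 40, "-", "a", "piRNA")])
        per_gene, _ = pirnas_per_gene(assign_hosts(pirnas, genes))
        assert "G" not in per_gene.index

    def test_histogram_matches_group_by(self):
        rng = np.random.default_rng(9)
        genes = AnnotationSet([
            make_ann("c", 2_000 * i, 2_000 * i + 1_500, "+", f"G{i}",
                     "protein_coding") for i in range(10)
        ])
        pirnas = []
        expect = {}
        for i in range(60):
            g = int(rng.integers(10))
            start = 2_000 * g + int(rng.integers(0, 1_400))
            pirnas.append(make_ann("c", start, start + 30, "+", f"p{i}", "piRNA"))
            expect[f"G{g}"] = expect.get(f"G{g}", 0) + 1
        per_gene, _ = pirnas_per_gene(
            assign_hosts(AnnotationSet(pirnas), genes))
        assert per_gene.to_dict() == expect

    def test_chromosome_tallies_sum_to_total(self, small_sim):
        dist = chromosome_distribution(small_sim.genome.pirnas)
        assert dist.sum() == len(small_sim.genome.pirnas)


class TestOverrepresentation:
    def test_closed_form_extreme_case(self):
        # N=20, K=5, n=5, k=5 -> p = 1/C(20,5)
        universe = {f"g{i}" for i in range(20)}
        sets = {"S": {f"g{i}" for i in range(5)}}
        query = {f"g{i}" for i in range(5)}
        res = overrepresentation(query, sets, universe)
        assert res.p.item() == pytest.approx(1 / 15504, rel=1e-9)

    def test_zero_hits_p_is_one(self):
        universe = {f"g{i}" for i in range(20)}
        res = overrepresentation({"g0"}, {"S": {"g10", "g11"}}, universe)
        assert res.p.item() == pytest.approx(1.0)

    def test_query_equals_universe_forces_p_one(self):
        universe = {f"g{i}" for i in range(15)}
        sets = {"A": {"g1", "g2"}, "B": {"g3"}}
        res = overrepresentation(universe, sets, universe)
        assert np.allclose(res.p, 1.0)
        assert (res.k == res.K).all()

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation({"x"}, {"S": {"a"}}, {"a", "b"})

    def test_gmt_round_trip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tdesc\tg1\tg2\nS2\tdesc\tg3\n")
        assert read_gmt(p) == {"S1": {"g1", "g2"}, "S2": {"g3"}}
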