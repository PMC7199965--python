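"""End-to-end orchestration: simulate/load -> filter -> count -> expressed
-> differential expression -> clustering -> signatures -> genomic context.

A run is driven by a :class:`RunConfig` (typically parsed from YAML), writes
every stage's tables into one output directory, and finishes with a JSON
manifest recording the configuration hash, the seed and a checksum per
output file, so two runs with the same config and seed can be verified
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import clustering, context, diffexp, filtering, quantify, signatures
from . import io as pio
from .core import AnnotationSet, SampleSheet
from .simulate import SimulationConfig, classed_bed_class_map, simulate, write_simulation

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters, defaulted to the reference analysis values:
    24-34 nt read length band, mean raw count >= 3 for expression,
    |log2FC| >= 1 with p < 0.05 and FDR < 0.1 for differential calls,
    c = 8 clusters at fuzzifier m = 1.15, and 1500 shuffles for the
    gene-origin enrichment null."""

    seed: int = 0
    simulation: Optional[Dict] = None      # SimulationConfig kwargs (synthetic run)
    sample_sheet: Optional[str] = None     # real-input run: TSV with read paths
    pirna_bed: Optional[str] = None
    ncrna_bed: Optional[str] = None
    genes_gtf: Optional[str] = None
    min_len: int = 24
    max_len: int = 34
    min_mean: float = 3.0
    lfc_cut: float = 1.0
    p_cut: float = 0.05
    fdr_cut: float = 0.1
    clusters: int = 8
    fuzzifier: float = 1.15
    min_membership: float = 0.5
    n_shuffles: int = 1500
    emit_c_diagnostic: bool = False

    _KNOWN = None  # populated after class creation

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> Dict:
        d = {k: v for k, v in asdict(self).items() if not k.startswith("_")}
        return d

    def validate(self) -> None:
        if self.simulation is None and self.sample_sheet is None:
            raise ValueError("config needs either 'simulation' or input paths")
        if self.simulation is None:
            for key in ("pirna_bed", "ncrna_bed", "genes_gtf"):
                if getattr(self, key) is None:
                    raise ValueError(f"real-input run requires {key}")
        if self.min_len > self.max_len or self.min_len <= 0:
            raise ValueError("invalid length band")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, outdir) -> Path:
    """Execute every stage in dependency order and write the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_order: List[str] = []

    def _stage(name: str):
        stage_order.append(name)
        logger.info("stage %s", name)

    # --- inputs -----------------------------------------------------------
    if config.simulation is not None:
        _stage("simulate")
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        sim_cfg = SimulationConfig(**sim_kwargs)
        result = simulate(sim_cfg)
        write_simulation(result, outdir / "sim")
        sheet = result.sheet
        reads_by_sample = result.reads
        pirnas = result.genome.pirnas
        ncrna = result.genome.ncrna
        genes = result.genome.genes
        contig_lengths = result.genome.contig_lengths
    else:
        _stage("load")
        sheet = pio.read_sample_sheet(config.sample_sheet)
        reads_by_sample = {
            s.sample_id: pio.read_alignments(s.path, sample_id=s.sample_id)
            for s in sheet.samples
        }
        pirnas = pio.read_annotations(
            config.pirna_bed, format="BED", default_class="piRNA"
        )
        ncrna = pio.read_annotations(
            config.ncrna_bed, format="BED", class_map=classed_bed_class_map
        )
        genes = pio.read_annotations(config.genes_gtf, format="GTF", class_map={
            c: c for c in ("protein_coding", "lncRNA", "miRNA", "tRNA", "rRNA",
                           "snoRNA", "piRNA")
        })
        contig_lengths = _infer_contig_lengths(reads_by_sample, pirnas, ncrna, genes)

    # --- filtering --------------------------------------------------------
    _stage("filter")
    density = filtering.length_density(reads_by_sample)
    pio.write_table(density, outdir / "length_density.tsv",
                    sort_by=["sample_id", "length"], allow_empty=True)
    filtered, report = filtering.run_cascade(
        reads_by_sample, ncrna, config.min_len, config.max_len
    )
    pio.write_table(report, outdir / "filter_report.tsv", sort_by=["sample_id"])

    # --- quantification ---------------------------------------------------
    _stage("count")
    counts = quantify.count_reads(filtered, pirnas, sheet)
    counts_out = counts.values.reset_index()
    pio.write_table(counts_out, outdir / "counts.tsv", sort_by=["feature_id"])
    cpm = quantify.cpm_normalize(counts)
    pio.write_table(cpm.reset_index(), outdir / "cpm.tsv", sort_by=["feature_id"])

    _stage("expressed")
    sets = quantify.call_expressed(counts, config.min_mean)
    pio.write_table(quantify.expressed_table(sets), outdir / "expressed.tsv",
                    sort_by=["feature_id"], allow_empty=True)
    pio.write_table(quantify.set_overlaps(sets), outdir / "set_overlaps.tsv",
                    sort_by=["sets"])
    catalog = sorted(sets.union)

    # --- differential expression -----------------------------------------
    _stage("de")
    de_summaries = []
    correlations = []
    if catalog:
        sub = counts.values.loc[catalog]
        try:
            factors = diffexp.size_factors(sub)
        except ValueError:
            factors = pd.Series(1.0, index=sub.columns)
        for stage_a, stage_b in sheet.contrasts():
            res = diffexp.nb_test(sub, sheet, (stage_a, stage_b), factors=factors)
            res = diffexp.classify_de(res, config.lfc_cut, config.p_cut, config.fdr_cut)
            pio.write_table(res, outdir / f"de_{stage_b}_vs_{stage_a}.tsv",
                            sort_by=["feature_id"])
            up, down, ns = diffexp.de_summary(res)
            de_summaries.append({"contrast": f"{stage_b}_vs_{stage_a}",
                                 "n_up": up, "n_down": down, "n_ns": ns})
            corr = diffexp.stage_correlation(cpm, sheet, (stage_a, stage_b),
                                             features=catalog) \
                if len(catalog) >= 3 else None
            if corr is not None:
                correlations.append(corr)
    else:
        for stage_a, stage_b in sheet.contrasts():
            pio.write_table(
                pd.DataFrame(columns=["feature_id", "base_mean", "log2FC", "p",
                                      "padj", "tested", "call"]),
                outdir / f"de_{stage_b}_vs_{stage_a}.tsv", allow_empty=True)
    pio.write_table(pd.DataFrame(de_summaries,
                                 columns=["contrast", "n_up", "n_down", "n_ns"]),
                    outdir / "de_summary.tsv", sort_by=["contrast"], allow_empty=True)
    pio.write_table(pd.DataFrame(correlations,
                                 columns=["pair", "R", "p", "n", "defined"]),
                    outdir / "correlations.tsv", sort_by=["pair"], allow_empty=True)

    # --- clustering -------------------------------------------------------
    _stage("cluster")
    if len(catalog) >= config.clusters:
        traj, dropped = clustering.standardize(cpm, sheet, features=catalog)
        if len(traj) >= config.clusters:
            fit = clustering.fuzzy_cmeans(traj, c=config.clusters,
                                          m=config.fuzzifier, seed=config.seed)
            memb = fit.memberships.reset_index().rename(columns={"index": "feature_id"})
            pio.write_table(memb, outdir / "memberships.tsv", sort_by=["feature_id"])
            centers = pd.DataFrame(fit.centers, columns=list(sheet.stages))
            centers.insert(0, "cluster", range(1, config.clusters + 1))
            pio.write_table(centers, outdir / "centers.tsv", sort_by=["cluster"])
            labels = clustering.assign_clusters(fit, config.min_membership)
            pio.write_table(labels.reset_index().rename(
                columns={"index": "feature_id"}),
                outdir / "cluster_labels.tsv", sort_by=["feature_id"])
            if config.emit_c_diagnostic:
                diag = clustering.center_distance_diagnostic(traj, seed=config.seed)
                pio.write_table(diag, outdir / "c_diagnostic.tsv", sort_by=["c"])
    else:
        pio.write_table(pd.DataFrame(columns=["feature_id"]),
                        outdir / "memberships.tsv", allow_empty=True)

    # --- signatures -------------------------------------------------------
    _stage("signatures")
    pooled = [r for sid in sheet.sample_ids for r in filtered[sid]]
    assigned = [r for r in pooled if quantify.assign_read(r, pirnas) is not None]
    if assigned and any(r.sequence is not None for r in assigned):
        freq = signatures.base_frequency(assigned)
        pio.write_table(freq, outdir / "base_frequency.tsv", sort_by=["position"])
    pp_rows = []
    for sid in sheet.sample_ids:
        prof = signatures.pingpong_profile(filtered[sid])
        for s, h in prof.histogram.items():
            pp_rows.append({"sample_id": sid, "overlap": s, "pairs": h,
                            "z10": prof.z10 if prof.z10 is not None else float("nan")})
    pio.write_table(pd.DataFrame(pp_rows), outdir / "pingpong.tsv",
                    sort_by=["sample_id", "overlap"], allow_empty=True)
    if len(pirnas) > 0 and pooled:
        cov = signatures.coverage_profile(pooled, pirnas)
        pio.write_table(
            pd.DataFrame({"grid_position": np.arange(1, len(cov) + 1),
                          "mean_cpm_depth": cov}),
            outdir / "coverage_profile.tsv", sort_by=["grid_position"])

    # --- genomic context --------------------------------------------------
    _stage("context")
    if catalog:
        expressed_set = AnnotationSet([pirnas[fid] for fid in catalog])
        gene_models = genes.subset(["protein_coding", "lncRNA"])
        hosts_any = context.assign_hosts(
            expressed_set, genes, classes=set(genes.class_counts()))
        hosts = context.assign_hosts(expressed_set, gene_models)
        observed = context.intersection_counts(hosts)
        null = context.shuffle_null(expressed_set, gene_models, contig_lengths,
                                    n_shuffles=config.n_shuffles, seed=config.seed)
        enr = context.enrichment_table(context.fold_enrichment(observed, null))
        pio.write_table(enr, outdir / "enrichment.tsv",
                        sort_by=["gene_class", "orientation"])
        host_genes = sorted({g for e in hosts.hosts.values()
                             for g, _c, o in e if o == "sense"})
        if host_genes:
            host_set = AnnotationSet([gene_models[g] for g in host_genes])
            med_rows = []
            for stage in sheet.stages:
                stage_reads = [r for s in sheet.samples_for_stage(stage)
                               for r in filtered[s.sample_id]]
                for orient in ("sense", "antisense"):
                    covdf = context.gene_coverage(stage_reads, host_set, orient)
                    pio.write_table(covdf,
                                    outdir / f"gene_coverage_{stage}_{orient}.tsv",
                                    sort_by=["gene_id"], allow_empty=True)
                    med_rows.append({"stage": stage, "orientation": orient,
                                     "median_percent": float(covdf["percent_covered"].median())})
            pio.write_table(pd.DataFrame(med_rows),
                            outdir / "gene_coverage_medians.tsv",
                            sort_by=["stage", "orientation"])
        per_gene, hist = context.pirnas_per_gene(hosts)
        pio.write_table(per_gene.reset_index().rename(
            columns={"index": "gene_id", 0: "n_sense_pirnas"}),
            outdir / "pirnas_per_gene.tsv", sort_by=["gene_id"], allow_empty=True)
        pio.write_table(hist.reset_index().rename(
            columns={"index": "bin", 0: "n_genes"}),
            outdir / "pirnas_per_gene_hist.tsv", sort_by=["bin"])
        chrom = context.chromosome_distribution(expressed_set)
        pio.write_table(chrom.reset_index().rename(
            columns={"index": "chrom", 0: "n_pirnas"}),
            outdir / "chromosome_distribution.tsv", sort_by=["chrom"])
        summary = pd.DataFrame([
            {"metric": "n_expressed_union", "value": len(catalog)},
            {"metric": "fraction_genic_any_class", "value": hosts_any.fraction_genic},
            {"metric": "fraction_genic_pc_lnc", "value": hosts.fraction_genic},
        ])
        pio.write_table(summary, outdir / "context_summary.tsv", sort_by=["metric"])

    # --- manifest ---------------------------------------------------------
    _stage("manifest")
    config_blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    checksums = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "seed": config.seed,
        "stage_order": stage_order,
        "checksums": checksums,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def _infer_contig_lengths(reads_by_sample, *annotation_sets) -> Dict[str, int]:
    """Upper bounds from observed coordinates when no FASTA is supplied."""
    lengths: Dict[str, int] = {}
    for reads in reads_by_sample.values():
        for r in reads:
            iv = r.interval
            lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end)
    for aset in annotation_sets:
        for a in aset:
            iv = a.interval
            lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end)
    return lengths
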