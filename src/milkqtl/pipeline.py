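"""End-to-end orchestration: trait sets -> network -> DE -> variants -> screen.

Runs the full prioritization-and-screening chain on file inputs and writes
the report bundle: Venn summary, prioritized-gene table, DE
hub/bottleneck table, per-gene SNP summary, and the per-category genotype
pattern matrices. Every filter logs before/after counts to stderr; any
stage failure aborts with the stage name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import de as de_mod
from . import fixation, gene_sets, network, variants

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Input paths and thresholds for one pipeline run."""

    # inputs
    trait_table: Path | None = None
    edge_list: Path | None = None
    de_table: Path | None = None
    vcf: Path | None = None
    vcf_second_caller: Path | None = None
    group_map: Path | None = None
    gene_intervals: Path | None = None
    gene_models: Path | None = None
    genome: Path | None = None
    # thresholds
    min_score: float = 0.5
    k_hub: int = 50
    k_bottleneck: int = 50
    degree_percentile_prefilter: float | None = 0.20
    alpha: float = 0.05
    min_abs_lfc: float = 0.0
    min_qual: float = 20.0
    min_called: int = fixation.DEFAULT_MIN_CALLED
    # output
    outdir: Path = Path("results")

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_score <= 1.0:
            raise ValueError("min_score must be in [0, 1]")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.min_abs_lfc < 0 or self.min_qual < 0 or self.min_called < 0:
            raise ValueError("thresholds must be non-negative")


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return decorator


@_stage("gene_sets")
def _run_gene_sets(config: PipelineConfig, outdir: Path) -> dict:
    records = gene_sets.deduplicate(gene_sets.read_trait_table(config.trait_table))
    mfy = gene_sets.trait_gene_set(records, "MFY")
    mfp = gene_sets.trait_gene_set(records, "MFP")
    counts = gene_sets.venn(mfy, mfp)
    exclusive = gene_sets.exclusive_trait_genes(records, {"MFY", "MFP"})
    logger.info(
        "gene_sets: %d records -> MFY %d, MFP %d, common %d, union %d, exclusive %d",
        len(records), counts.size_a, counts.size_b, counts.both, counts.union, len(exclusive),
    )
    pd.DataFrame(
        [
            ("MFY", counts.size_a),
            ("MFP", counts.size_b),
            ("common", counts.both),
            ("union", counts.union),
            ("MFY_MFP_exclusive", len(exclusive)),
        ],
        columns=["set", "n_genes"],
    ).to_csv(outdir / "venn_summary.tsv", sep="\t", index=False)
    return {"records": records, "venn": counts, "union_genes": mfy | mfp, "exclusive": exclusive}


@_stage("network_prioritization")
def _run_network(config: PipelineConfig, outdir: Path) -> dict:
    edges = network.read_edge_list(config.edge_list)
    net = network.build_network(edges, min_score=config.min_score)
    logger.info(
        "network: %d edges read -> %d nodes / %d edges at score >= %g",
        len(edges), net.number_of_nodes(), net.number_of_edges(), config.min_score,
    )
    table = network.centralities(net)
    pg = network.prioritize(
        net,
        k_hub=config.k_hub,
        k_bottleneck=config.k_bottleneck,
        degree_percentile_prefilter=config.degree_percentile_prefilter,
    )
    logger.info(
        "prioritize: %d hubs, %d bottlenecks, union %d, both %d",
        len(pg.hubs), len(pg.bottlenecks), len(pg.union), len(pg.intersection),
    )
    table.as_frame().to_csv(outdir / "centralities.tsv", sep="\t", index=False)
    network.prioritized_table(table, pg).to_csv(
        outdir / "prioritized_genes.tsv", sep="\t", index=False
    )
    return {"network": net, "centralities": table, "prioritized": pg}


@_stage("de_integration")
def _run_de(config: PipelineConfig, prioritized, outdir: Path) -> dict:
    results = de_mod.read_de_table(config.de_table)
    kept = de_mod.filter_de(results, alpha=config.alpha, min_abs_lfc=config.min_abs_lfc)
    logger.info(
        "filter_de: %d of %d rows kept at p < %g, |log2fc| >= %g",
        len(kept), len(results), config.alpha, config.min_abs_lfc,
    )
    table = de_mod.integrate(prioritized, kept)
    logger.info(
        "integrate: %d DE hub/bottleneck genes (%d both, %d up, %d down)",
        table.n_union, table.n_both, table.n_up, table.n_down,
    )
    table.rows.to_csv(outdir / "de_hub_bottleneck.tsv", sep="\t", index=False)
    return {"de_table": table}


@_stage("variant_annotation")
def _run_variants(config: PipelineConfig, outdir: Path) -> dict:
    matrix = variants.read_vcf(config.vcf)
    logger.info("read_vcf: %d sites, %d samples", len(matrix.sites), len(matrix.samples))
    matrix = variants.filter_variants(matrix, min_qual=config.min_qual)
    if config.vcf_second_caller is not None:
        second = variants.filter_variants(
            variants.read_vcf(config.vcf_second_caller), min_qual=config.min_qual
        )
        matrix = variants.intersect_callsets(matrix, second)
    intervals = variants.read_gene_intervals(config.gene_intervals)
    summary = variants.assign_sites_to_genes(matrix.sites, intervals)
    summary.to_csv(outdir / "gene_snp_summary.tsv", sep="\t", index=False)

    biallelic = variants.filter_variants(matrix, min_qual=config.min_qual, biallelic_only=True)
    models = {m.gene_id: m for m in variants.read_gene_models(config.gene_models)}
    genome = variants.read_genome_fasta(config.genome)
    by_gene: dict[int, str] = {}
    for iv in intervals:
        for i, site in enumerate(biallelic.sites):
            if site.chrom == iv.chrom and iv.start <= site.pos <= iv.end:
                by_gene.setdefault(i, iv.gene_id)
    effects, keep = [], []
    for i, site in enumerate(biallelic.sites):
        gene_id = by_gene.get(i)
        if gene_id is None or gene_id not in models:
            continue
        eff = variants.annotate_coding_effect(site, models[gene_id], genome)
        if eff.effect == variants.EFFECT_NONSYNONYMOUS:
            keep.append(i)
            effects.append(eff)
    logger.info(
        "annotation: %d biallelic SNPs -> %d nonsynonymous in modelled genes",
        len(biallelic.sites), len(keep),
    )
    ns_matrix = biallelic.subset_sites(keep)
    pd.DataFrame(
        {
            "chrom": [s.chrom for s in ns_matrix.sites],
            "pos": [s.pos for s in ns_matrix.sites],
            "gene_id": [e.gene_id for e in effects],
            "ref": [s.ref for s in ns_matrix.sites],
            "alt": [s.alts[0] for s in ns_matrix.sites],
            "effect": [e.effect for e in effects],
            "protein_change": [e.render() for e in effects],
        }
    ).to_csv(outdir / "nonsynonymous_snps.tsv", sep="\t", index=False)
    return {"ns_matrix": ns_matrix, "effects": effects, "gene_summary": summary}


@_stage("fixation_screen")
def _run_screen(config: PipelineConfig, ns_matrix, effects, outdir: Path) -> dict:
    groups = fixation.read_group_map(config.group_map)
    site_genes = [e.gene_id for e in effects]
    report = fixation.screen(ns_matrix, groups, min_called=config.min_called, site_genes=site_genes)
    long = report.long_table(ns_matrix, groups)
    long["protein_change"] = [e.render() for e in effects]
    long.to_csv(outdir / "pattern_calls.tsv", sep="\t", index=False)
    for category, calls in report.by_category().items():
        if not calls:
            continue
        wide = report.wide_table(ns_matrix, category)
        wide.to_csv(outdir / f"pattern_{category.lower()}.tsv", sep="\t")
    counts = {c: len(v) for c, v in report.by_category().items()}
    logger.info("screen: %s", counts)
    return {"report": report, "category_counts": counts}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage whose inputs are configured; returns the bundle.

    Stages: gene_sets -> network_prioritization -> de_integration ->
    variant_annotation -> fixation_screen. The DE stage needs the network
    stage; the screen needs the variant stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    if config.trait_table is not None:
        bundle.update(_run_gene_sets(config, outdir))
    if config.edge_list is not None:
        bundle.update(_run_network(config, outdir))
    if config.de_table is not None:
        if "prioritized" not in bundle:
            raise StageError("stage 'de_integration' failed: needs the network stage (edge_list)")
        bundle.update(_run_de(config, bundle["prioritized"], outdir))
    if config.vcf is not None:
        if config.gene_intervals is None or config.gene_models is None or config.genome is None:
            raise StageError(
                "stage 'variant_annotation' failed: vcf input needs gene_intervals, "
                "gene_models and genome"
            )
        bundle.update(_run_variants(config, outdir))
        if config.group_map is not None:
            bundle.update(
                _run_screen(config, bundle["ns_matrix"], bundle["effects"], outdir)
            )
    return bundle
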