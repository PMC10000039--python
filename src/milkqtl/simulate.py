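"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the shape of the real study inputs — a QTL
trait-gene table with a chosen two-trait Venn structure, a sparse
scale-free-ish interaction network with planted hubs, a DE results table
with planted effects, and a two-breed-group WGS cohort (8 high- and 6
low-milk-yield animals by default) whose biallelic coding SNPs are planted
to realize requested fixation categories. Each generator returns its
truth table, so classifier recovery is measurable exactly.

All four generators draw from independent streams derived from one seed;
identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import fixation
from .fixation import (
    FIXED_BOTH_CONCORDANT,
    FIXED_BOTH_DISCORDANT,
    FIXED_HIGH_VARIABLE_LOW,
    FIXED_LOW_VARIABLE_HIGH,
    INSUFFICIENT_DATA,
    VARIABLE_BOTH,
    GroupAssignment,
)
from .gene_sets import TRAIT_VOCABULARY, GeneRecord
from .network import InteractionEdge
from .variants import (
    GeneInterval,
    GeneModel,
    GenotypeCall,
    GenotypeMatrix,
    MISSING_CALL,
    VariantSite,
    write_gene_intervals,
    write_gene_models,
    write_genome_fasta,
    write_vcf,
)

_STREAM = {"universe": 0, "network": 1, "de": 2, "cohort": 3}


@dataclass
class SyntheticConfig:
    """Knobs for all four generators; defaults mirror the study design."""

    seed: int = 0
    # trait-gene universe: 286 fat-yield and 256 fat-percentage genes
    # sharing 125, i.e. a union of 417, inside a larger annotated universe
    n_genes: int = 600
    venn_sizes: tuple[int, int, int] = (161, 125, 131)  # only MFY, both, only MFP
    # network: sparsity of the real interaction graph (403 nodes, 671 edges)
    n_network_nodes: int = 403
    n_network_edges: int = 671
    n_planted_hubs: int = 10
    # DE table: planted |log2FC| centered inside the observed 0.9-7.1 range
    de_effect_mean: float = 2.5
    de_effect_sd: float = 0.8
    de_null_sd: float = 0.5
    # cohort: 8 high-yield and 6 low-yield animals; site categories mirror
    # the published screen (14 fixed-high/variable-low, 9 the reverse, one
    # variable in both groups)
    n_high: int = 8
    n_low: int = 6
    sites_per_category: dict = field(
        default_factory=lambda: {
            FIXED_HIGH_VARIABLE_LOW: 14,
            FIXED_LOW_VARIABLE_HIGH: 9,
            VARIABLE_BOTH: 1,
        }
    )
    missing_rate: float = 0.02
    min_called: int = fixation.DEFAULT_MIN_CALLED
    genome_length: int = 60_000
    genes_per_genome: int = 20

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAM[stream]])


def _gene_id(i: int) -> str:
    return f"ENSBTAG{i:011d}"


# ---------------------------------------------------------------------------
# trait-gene universe


def simulate_universe(config: SyntheticConfig) -> list[GeneRecord]:
    """Gene records realizing the configured MFY/MFP Venn sizes exactly.

    Genes beyond the two-trait union carry other milk-trait codes; genes
    inside it may pick up extra codes at random (so exact-trait-set queries
    stay meaningful).
    """
    only_a, both, only_b = config.venn_sizes
    union = only_a + both + only_b
    if union > config.n_genes:
        raise ValueError(
            f"venn sizes sum to {union} but n_genes is only {config.n_genes}"
        )
    rng = config.rng("universe")
    other_codes = sorted(TRAIT_VOCABULARY - {"MFY", "MFP"})
    records = []
    for i in range(config.n_genes):
        if i < only_a:
            traits = {"MFY"}
        elif i < only_a + both:
            traits = {"MFY", "MFP"}
        elif i < union:
            traits = {"MFP"}
        else:
            traits = set(
                rng.choice(other_codes, size=rng.integers(1, 3), replace=False)
            )
        if i < union and rng.random() < 0.4:
            traits |= set(
                rng.choice(other_codes, size=rng.integers(1, 3), replace=False)
            )
        records.append(GeneRecord(_gene_id(i + 1), traits))
    return records


# ---------------------------------------------------------------------------
# interaction network


def simulate_network(
    config: SyntheticConfig,
) -> tuple[list[InteractionEdge], list[str]]:
    """Preferential-attachment-style graph with degree-dominant planted hubs.

    A random recursive tree grown with degree-proportional attachment is
    densified with random extra edges to the configured edge count; the
    planted hubs are then topped up with neighbours until each strictly
    out-degrees every non-hub node, so top-k-by-degree recovery is a
    construction guarantee.
    """
    n, target_edges = config.n_network_nodes, config.n_network_edges
    if n == 0 or target_edges == 0:
        return [], []
    if target_edges > n * (n - 1) // 2:
        raise ValueError("requested edge count exceeds simple-graph capacity")
    rng = config.rng("network")
    nodes = [_gene_id(i + 1) for i in range(n)]
    adj: dict[str, set[str]] = {v: set() for v in nodes}

    def add_edge(u: str, v: str) -> bool:
        if u == v or v in adj[u]:
            return False
        adj[u].add(v)
        adj[v].add(u)
        return True

    # hub degrees are fixed first, well above the cap enforced on everyone
    # else, so degree dominance holds by construction at the exact edge count
    hubs = sorted(rng.choice(nodes, size=config.n_planted_hubs, replace=False))
    hub_set = set(hubs)
    others = [v for v in nodes if v not in hub_set]
    mean_degree = 2.0 * target_edges / n
    want = {h: int(np.ceil(4.0 * mean_degree)) + 4 + int(rng.integers(0, 3)) for h in hubs}
    cap = min(want.values()) - 1 if want else n  # max total degree of a non-hub
    if sum(want.values()) > target_edges:
        raise ValueError(
            f"n_network_edges={target_edges} too small to plant "
            f"{config.n_planted_hubs} dominant hubs (need >= {sum(want.values())})"
        )
    edges_made = 0
    for hub in hubs:
        # spread hub edges over the least-loaded non-hubs so none nears the cap
        order = sorted(others, key=lambda v: (len(adj[v]), rng.random()))
        for v in order[: want[hub]]:
            if add_edge(hub, v):
                edges_made += 1

    # preferential-attachment growth among the non-hubs with the remaining
    # budget: a recursive tree first, then degree-biased extra edges
    degree_weighted: list[str] = [others[0]] if others else []
    for i in range(1, len(others)):
        if edges_made >= target_edges:
            break
        anchor = degree_weighted[rng.integers(len(degree_weighted))]
        if len(adj[anchor]) < cap and len(adj[others[i]]) < cap:
            if add_edge(others[i], anchor):
                edges_made += 1
        degree_weighted.append(others[i])
        degree_weighted.extend(adj[others[i]] & set(others))
    attempts = 0
    while edges_made < target_edges and attempts < 200 * target_edges:
        attempts += 1
        u = others[rng.integers(len(others))]
        v = degree_weighted[rng.integers(len(degree_weighted))]
        if len(adj[u]) >= cap or len(adj[v]) >= cap:
            continue
        if add_edge(u, v):
            degree_weighted.extend([u, v])
            edges_made += 1
    if edges_made < target_edges:
        raise ValueError("could not place the requested edge count under the hub degree cap")

    edges = []
    for u in nodes:
        for v in adj[u]:
            if u < v:
                score = round(float(rng.uniform(0.5, 1.0)), 3)
                edges.append(InteractionEdge(u, v, score))
    edges.sort(key=lambda e: (e.a, e.b))
    return edges, hubs


# ---------------------------------------------------------------------------
# DE table


def simulate_de(
    config: SyntheticConfig,
    target_genes: list[str],
    background_genes: list[str] | None = None,
) -> pd.DataFrame:
    """DE results with planted effects on ``target_genes``.

    Targets get log2fc ~ Normal(+/-mean, sd) with log-uniform small
    p-values; background genes get null effects and Uniform(0,1) p-values.
    Returns columns gene_id, log2fc, p_value, is_target.
    """
    rng = config.rng("de")
    if background_genes is None:
        background_genes = [
            _gene_id(i + 1)
            for i in range(config.n_genes)
            if _gene_id(i + 1) not in set(target_genes)
        ]
    rows = []
    for g in target_genes:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        lfc = sign * rng.normal(config.de_effect_mean, config.de_effect_sd)
        p = float(10.0 ** rng.uniform(-8.0, -3.0))
        rows.append((g, float(lfc), p, True))
    for g in background_genes:
        lfc = rng.normal(0.0, config.de_null_sd)
        rows.append((g, float(lfc), float(rng.uniform(0.0, 1.0)), False))
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "p_value", "is_target"])


# ---------------------------------------------------------------------------
# WGS cohort


@dataclass
class SimulatedCohort:
    genome: dict[str, str]
    models: list[GeneModel]
    intervals: list[GeneInterval]
    matrix: GenotypeMatrix
    groups: GroupAssignment
    truth: pd.DataFrame  # chrom, pos, gene_id, category, effect, protein_pos

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "gene_models": outdir / "gene_models.tsv",
            "gene_intervals": outdir / "gene_intervals.tsv",
            "vcf": outdir / "cohort.vcf",
            "group_map": outdir / "group_map.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_genome_fasta(self.genome, paths["genome"])
        write_gene_models(self.models, paths["gene_models"])
        write_gene_intervals(self.intervals, paths["gene_intervals"])
        write_vcf(
            self.matrix,
            paths["vcf"],
            contig_lengths={c: len(s) for c, s in self.genome.items()},
        )
        pd.DataFrame(
            {
                "sample_id": list(self.groups.mapping),
                "group": list(self.groups.mapping.values()),
            }
        ).to_csv(paths["group_map"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _place_genes(
    rng: np.random.Generator, config: SyntheticConfig, chrom: str
) -> tuple[list[GeneModel], list[GeneInterval]]:
    """Non-overlapping one- or two-segment CDS models with flanks."""
    models, intervals = [], []
    cursor = 100
    for i in range(config.genes_per_genome):
        n_codons = int(rng.integers(40, 100))
        cds_len = 3 * n_codons
        strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() < 0.5:
            segments = ((cursor, cursor + cds_len - 1),)
        else:
            cut = 3 * int(rng.integers(10, n_codons - 10))
            intron = int(rng.integers(30, 120))
            segments = (
                (cursor, cursor + cut - 1),
                (cursor + cut + intron, cursor + cds_len + intron - 1),
            )
        gene_id = f"SYNGENE{i + 1:04d}"
        models.append(GeneModel(gene_id, chrom, strand, segments))
        start = segments[0][0] - 50
        end = segments[-1][1] + 50
        intervals.append(GeneInterval(gene_id, chrom, max(1, start), end))
        cursor = end + int(rng.integers(100, 400))
    if cursor > config.genome_length:
        raise ValueError(
            f"genome_length {config.genome_length} too short for "
            f"{config.genes_per_genome} genes (need ~{cursor})"
        )
    return models, intervals


def _cds_positions(model: GeneModel) -> list[int]:
    pos = []
    for start, end in model.cds_segments:
        pos.extend(range(start, end + 1))
    return pos


def _planned_effect(
    model: GeneModel, genome_seq: str, pos: int, alt: str
) -> tuple[str, int, str, str]:
    """Generator-side codon bookkeeping: effect of pos ref>alt on the model.

    Independent offset arithmetic from the annotator's genomic mapping:
    works on the spliced CDS the generator itself laid out.
    """
    plus_cds = "".join(genome_seq[s - 1 : e] for s, e in model.cds_segments)
    plus_index = 0
    for start, end in model.cds_segments:
        if start <= pos <= end:
            plus_index += pos - start
            break
        plus_index += end - start + 1
    ref = genome_seq[pos - 1]
    if model.strand == "-":
        cds = str(Seq(plus_cds).reverse_complement())
        idx = len(plus_cds) - 1 - plus_index
        ref = str(Seq(ref).complement())
        alt = str(Seq(alt).complement())
    else:
        cds = plus_cds
        idx = plus_index
    codon_i, within = divmod(idx, 3)
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    alt_codon = codon[:within] + alt + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        effect = "SYNONYMOUS"
    elif alt_aa == "*":
        effect = "STOP_GAINED"
    elif ref_aa == "*":
        effect = "STOP_LOST"
    else:
        effect = "NONSYNONYMOUS"
    return effect, codon_i + 1, ref_aa, alt_aa


def _genotypes_for_category(
    rng: np.random.Generator,
    category: str,
    ref: str,
    alt: str,
    n_high: int,
    n_low: int,
) -> tuple[list[GenotypeCall], list[GenotypeCall], set[int], set[int]]:
    """Per-group calls realizing the category, plus mask-protected indices.

    Protected calls carry the evidence for the category (the heterozygous
    carriers of a variable group), so injecting missingness can never flip
    an informative category into a different informative one.
    """
    rr = GenotypeCall(ref, ref)
    ra = GenotypeCall(ref, alt)
    aa = GenotypeCall(alt, alt)

    def variable(n: int) -> tuple[list[GenotypeCall], set[int]]:
        k = int(rng.integers(1, n))  # 1..n-1 het carriers
        carriers = set(rng.choice(n, size=k, replace=False).tolist())
        return [ra if i in carriers else rr for i in range(n)], carriers

    if category == FIXED_HIGH_VARIABLE_LOW:
        low, carriers = variable(n_low)
        return [rr] * n_high, low, set(), carriers
    if category == FIXED_LOW_VARIABLE_HIGH:
        high, carriers = variable(n_high)
        return high, [rr] * n_low, carriers, set()
    if category == FIXED_BOTH_CONCORDANT:
        return [rr] * n_high, [rr] * n_low, set(), set()
    if category == FIXED_BOTH_DISCORDANT:
        return [rr] * n_high, [aa] * n_low, set(), set()
    if category == VARIABLE_BOTH:
        high, hc = variable(n_high)
        low, lc = variable(n_low)
        return high, low, hc, lc
    if category == INSUFFICIENT_DATA:
        # the whole HIGH group is masked post hoc; see caller
        return [rr] * n_high, [rr] * n_low, set(), set()
    raise ValueError(f"cannot plant sites for category {category!r}")


def simulate_cohort(config: SyntheticConfig) -> SimulatedCohort:
    """Toy genome + gene models + multi-sample VCF with planted patterns.

    Every planted site is a biallelic coding SNP whose alternate allele is
    chosen to be amino-acid changing; per-sample genotypes realize the
    requested fixation category. Missing calls are injected at
    ``missing_rate`` but never below ``min_called`` called animals per
    group and never on the calls that carry a category's evidence.
    """
    if config.n_high < 1 or config.n_low < 1:
        raise ValueError("both groups need at least one sample")
    for cat, count in config.sites_per_category.items():
        if cat not in fixation.CATEGORIES:
            raise ValueError(f"unknown category {cat!r}")
        if count < 0:
            raise ValueError(f"negative site count for {cat}")
        if count > 0 and cat == FIXED_HIGH_VARIABLE_LOW and config.n_low < 2:
            raise ValueError("variable LOW group needs >= 2 samples")
        if count > 0 and cat == FIXED_LOW_VARIABLE_HIGH and config.n_high < 2:
            raise ValueError("variable HIGH group needs >= 2 samples")
    rng = config.rng("cohort")
    chrom = "chr1"
    genome = {chrom: _random_genome(rng, config.genome_length)}
    models, intervals = _place_genes(rng, config, chrom)

    high_samples = [f"HIGH_{i + 1}" for i in range(config.n_high)]
    low_samples = [f"LOW_{i + 1}" for i in range(config.n_low)]
    samples = high_samples + low_samples
    groups = GroupAssignment(
        {**{s: fixation.HIGH for s in high_samples}, **{s: fixation.LOW for s in low_samples}}
    )

    requests = [
        cat
        for cat in sorted(config.sites_per_category)
        for _ in range(config.sites_per_category[cat])
    ]
    rng.shuffle(requests)

    used_positions: set[int] = set()
    planted = []  # (site, high_calls, low_calls, protected_high, protected_low, truth_row)
    gene_cycle = 0
    for category in requests:
        placed = False
        for _ in range(200):
            model = models[gene_cycle % len(models)]
            gene_cycle += 1
            positions = [p for p in _cds_positions(model) if p not in used_positions]
            if not positions:
                continue
            pos = int(positions[rng.integers(len(positions))])
            ref = genome[chrom][pos - 1]
            alts = [b for b in "ACGT" if b != ref]
            rng.shuffle(alts)
            chosen = None
            for alt in alts:
                effect, protein_pos, ref_aa, alt_aa = _planned_effect(
                    model, genome[chrom], pos, alt
                )
                if effect == "NONSYNONYMOUS":
                    chosen = (alt, effect, protein_pos, ref_aa, alt_aa)
                    break
            if chosen is None:
                continue
            alt, effect, protein_pos, ref_aa, alt_aa = chosen
            used_positions.add(pos)
            site = VariantSite(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alts=(alt,),
                qual=round(float(rng.uniform(30.0, 60.0)), 1),
            )
            high, low, prot_h, prot_l = _genotypes_for_category(
                rng, category, ref, alt, config.n_high, config.n_low
            )
            truth_row = {
                "chrom": chrom,
                "pos": pos,
                "gene_id": model.gene_id,
                "category": category,
                "effect": effect,
                "protein_pos": protein_pos,
                "protein_change": f"{protein_pos}({ref_aa}/{alt_aa})",
            }
            planted.append((site, high, low, prot_h, prot_l, truth_row, category))
            placed = True
            break
        if not placed:
            raise ValueError(f"could not place a site for category {category}")

    # missingness injection, category-preserving
    sites, calls, truth_rows = [], [], []
    for site, high, low, prot_h, prot_l, truth_row, category in sorted(
        planted, key=lambda t: t[0].pos
    ):
        def mask(group_calls, protected, informative: bool):
            out = list(group_calls)
            if config.missing_rate <= 0 or not informative:
                if not informative:
                    return [MISSING_CALL] * len(out)
                return out
            maskable = [i for i in range(len(out)) if i not in protected]
            rng.shuffle(maskable)
            floor = config.min_called
            called = len(out)
            for i in maskable:
                if called - 1 < floor:
                    break
                if rng.random() < config.missing_rate:
                    out[i] = MISSING_CALL
                    called -= 1
            return out

        if category == INSUFFICIENT_DATA:
            high_m = [MISSING_CALL] * len(high)
            low_m = mask(low, prot_l, informative=True)
        else:
            high_m = mask(high, prot_h, informative=True)
            low_m = mask(low, prot_l, informative=True)
        sites.append(site)
        calls.append(high_m + low_m)
        truth_rows.append(truth_row)

    matrix = GenotypeMatrix(sites=sites, samples=samples, calls=calls)
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "gene_id", "category", "effect", "protein_pos", "protein_change"],
    )
    return SimulatedCohort(
        genome=genome,
        models=models,
        intervals=intervals,
        matrix=matrix,
        groups=groups,
        truth=truth,
    )
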