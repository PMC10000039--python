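"""Variant parsing, filtering, gene assignment and coding-effect annotation.

Multi-sample VCFs (already called and recalibrated upstream) are reduced to
the set of interest in four steps: keep SNPs above a quality floor, keep
sites common to two callers, assign sites to gene intervals, and classify
each biallelic SNP's codon-level effect against a single transcript model
per gene. Coordinates are 1-based inclusive throughout, the VCF convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam
from Bio.Seq import Seq
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: Marker used for missing genotype cells in table fixtures.
MISSING_CELL = "-"


class VcfError(ValueError):
    """Raised for malformed VCF content."""


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts) and (
            self.ref in _BASES and all(a in _BASES for a in self.alts)
        )

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def key(self) -> tuple[str, int, str, tuple[str, ...]]:
        """Identity for caller intersection: chrom, pos, ref, sorted alts."""
        return (self.chrom, self.pos, self.ref, tuple(sorted(self.alts)))


@dataclass(frozen=True)
class GenotypeCall:
    """An unphased diploid call; both alleles present or both missing."""

    allele1: str | None
    allele2: str | None

    def __post_init__(self) -> None:
        if (self.allele1 is None) != (self.allele2 is None):
            raise VcfError("half-called genotype: both alleles must be present or missing")

    @property
    def is_missing(self) -> bool:
        return self.allele1 is None

    @property
    def is_het(self) -> bool:
        return not self.is_missing and self.allele1 != self.allele2

    def homozygous_allele(self) -> str | None:
        if self.is_missing or self.allele1 != self.allele2:
            return None
        return self.allele1

    def __str__(self) -> str:
        if self.is_missing:
            return "./."
        return f"{self.allele1}/{self.allele2}"


MISSING_CALL = GenotypeCall(None, None)


@dataclass
class GenotypeMatrix:
    """Sites x samples matrix of diploid calls, site-major."""

    sites: list[VariantSite]
    samples: list[str]
    calls: list[list[GenotypeCall]]  # calls[site_index][sample_index]

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.sites):
            raise VcfError("calls row count does not match site count")
        for i, row in enumerate(self.calls):
            if len(row) != len(self.samples):
                raise VcfError(f"site {i}: call count does not match sample count")
        if len(set(self.samples)) != len(self.samples):
            raise VcfError("duplicate sample ids")

    def call(self, site_index: int, sample: str) -> GenotypeCall:
        return self.calls[site_index][self.samples.index(sample)]

    def subset_sites(self, keep: list[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sites=[self.sites[i] for i in keep],
            samples=list(self.samples),
            calls=[self.calls[i] for i in keep],
        )


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: interval start {self.start} > end {self.end}")


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript coding model: ordered CDS segments on one strand."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds_segments: tuple[tuple[int, int], ...]  # 1-based inclusive, genomic order

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        prev_end = 0
        for start, end in self.cds_segments:
            if start > end:
                raise ValueError(f"{self.gene_id}: CDS segment {start}-{end} inverted")
            if start <= prev_end:
                raise ValueError(f"{self.gene_id}: CDS segments overlap or are unordered")
            prev_end = end
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_segments)


EFFECT_NONSYNONYMOUS = "NONSYNONYMOUS"
EFFECT_SYNONYMOUS = "SYNONYMOUS"
EFFECT_STOP_GAINED = "STOP_GAINED"
EFFECT_STOP_LOST = "STOP_LOST"
EFFECT_NONCODING = "NONCODING"


@dataclass(frozen=True)
class CodingEffect:
    gene_id: str
    effect: str
    protein_pos: int | None = None  # 1-based codon index
    ref_aa: str | None = None
    alt_aa: str | None = None

    def render(self) -> str:
        """Protein-change shorthand, e.g. ``392(G/A)``."""
        if self.effect == EFFECT_NONCODING:
            return "."
        return f"{self.protein_pos}({self.ref_aa}/{self.alt_aa})"


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a genotype matrix.

    Diploid GT is required for every sample; ``./.`` becomes a MISSING
    call and phased separators are treated as unphased. Genotype indices
    are resolved against the site's allele list, so multi-allelic calls
    come back as allele strings.
    """
    path = str(path)
    sites: list[VariantSite] = []
    calls: list[list[GenotypeCall]] = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if "GT" not in vcf.header.formats:
            raise VcfError(f"{path}: no GT FORMAT field declared")
        for rec in vcf:
            alts = tuple(rec.alts or ())
            if not alts:
                continue
            alleles = (rec.ref,) + alts
            site = VariantSite(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alts=alts,
                qual=rec.qual,
            )
            row = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or all(g is None for g in gt):
                    row.append(MISSING_CALL)
                    continue
                if len(gt) != 2 or any(g is None for g in gt):
                    raise VcfError(
                        f"{path}: non-diploid GT {gt!r} for sample {s} at {rec.chrom}:{rec.pos}"
                    )
                lo, hi = sorted(gt)  # unphased semantics: allele order irrelevant
                row.append(GenotypeCall(alleles[lo], alleles[hi]))
            sites.append(site)
            calls.append(row)
    return GenotypeMatrix(sites=sites, samples=samples, calls=calls)


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write the matrix as an uncompressed VCF v4.2 with unphased GT."""
    header = pysam.VariantHeader()
    contigs: dict[str, int] = dict(contig_lengths or {})
    for site in matrix.sites:
        needed = site.pos + len(site.ref)
        if contigs.get(site.chrom, 0) < needed:
            contigs[site.chrom] = needed
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in matrix.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site, row in zip(matrix.sites, matrix.calls):
            alleles = (site.ref,) + site.alts
            index = {a: i for i, a in enumerate(alleles)}
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                alleles=alleles,
                qual=site.qual,
            )
            for s, call in zip(matrix.samples, row):
                if call.is_missing:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    try:
                        rec.samples[s]["GT"] = (index[call.allele1], index[call.allele2])
                    except KeyError as exc:
                        raise VcfError(
                            f"sample {s} at {site.chrom}:{site.pos}: allele {exc} "
                            "not in the site's REF/ALT list"
                        ) from None
                rec.samples[s].phased = False
            out.write(rec)


# ---------------------------------------------------------------------------
# Filtering, intersection, gene assignment


def filter_variants(
    matrix: GenotypeMatrix,
    min_qual: float = 20.0,
    biallelic_only: bool = False,
) -> GenotypeMatrix:
    """Keep SNP sites with QUAL strictly above ``min_qual``.

    Sites without a QUAL value pass the quality filter (caller-intersected
    inputs may lack one). ``biallelic_only`` additionally requires exactly
    one alternate allele.
    """
    keep = []
    for i, site in enumerate(matrix.sites):
        if not site.is_snp:
            continue
        if site.qual is not None and not site.qual > min_qual:
            continue
        if biallelic_only and not site.is_biallelic:
            continue
        keep.append(i)
    logger.info(
        "quality/SNP filter: %d of %d sites kept (min_qual=%g, biallelic_only=%s)",
        len(keep), len(matrix.sites), min_qual, biallelic_only,
    )
    return matrix.subset_sites(keep)


def intersect_callsets(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Keep sites of ``a`` whose (chrom, pos, ref, alt set) also occur in ``b``.

    Genotypes are taken from ``a``; this is the caller-concordance step
    (e.g. GATK x freebayes).
    """
    b_keys = {site.key for site in b.sites}
    keep = [i for i, site in enumerate(a.sites) if site.key in b_keys]
    logger.info("caller intersection: %d of %d sites kept", len(keep), len(a.sites))
    return a.subset_sites(keep)


def assign_sites_to_genes(
    sites: list[VariantSite], intervals: list[GeneInterval]
) -> pd.DataFrame:
    """Per-gene SNP summary over 1-based inclusive gene intervals.

    A site belongs to a gene iff the chromosome matches and
    start <= pos <= end; overlapping genes each receive the site. Output
    columns: gene_id, chr, start, end, snp_count, bisnp_count (biallelic
    subset), one row per interval in input order.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        # intervaltree is half-open; +1 makes the genomic end inclusive
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1, iv)
    counts = {iv.gene_id: [0, 0] for iv in intervals}
    for site in sites:
        tree = trees.get(site.chrom)
        if tree is None:
            continue
        for hit in tree[site.pos]:
            c = counts[hit.data.gene_id]
            c[0] += 1
            if site.is_biallelic:
                c[1] += 1
    return pd.DataFrame(
        {
            "gene_id": [iv.gene_id for iv in intervals],
            "chr": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "snp_count": [counts[iv.gene_id][0] for iv in intervals],
            "bisnp_count": [counts[iv.gene_id][1] for iv in intervals],
        }
    )


def sites_in_gene(sites: list[VariantSite], interval: GeneInterval) -> list[VariantSite]:
    return [
        s
        for s in sites
        if s.chrom == interval.chrom and interval.start <= s.pos <= interval.end
    ]


# ---------------------------------------------------------------------------
# Coding-effect annotation


def annotate_coding_effect(
    site: VariantSite,
    model: GeneModel,
    genome: dict[str, str],
) -> CodingEffect:
    """Classify a biallelic SNP's codon-level effect against ``model``.

    The genomic position is mapped into the spliced CDS (reverse-
    complemented for minus-strand models), the containing codon is
    translated for both alleles with the standard nuclear code, and the
    change is classified. Sites outside the CDS are NONCODING. The
    genome's plus-strand base at the site must equal REF.
    """
    if not (site.is_snp and site.is_biallelic):
        raise ValueError(f"{site.chrom}:{site.pos}: coding annotation requires a biallelic SNP")
    if site.chrom != model.chrom:
        return CodingEffect(gene_id=model.gene_id, effect=EFFECT_NONCODING)
    seq = genome[site.chrom]
    genome_base = seq[site.pos - 1].upper()
    if genome_base != site.ref:
        raise ValueError(
            f"{site.chrom}:{site.pos}: REF {site.ref} does not match genome base {genome_base}"
        )

    # 1-based offset of the site within the plus-strand spliced CDS
    plus_offset = None
    consumed = 0
    for start, end in model.cds_segments:
        if start <= site.pos <= end:
            plus_offset = consumed + (site.pos - start) + 1
            break
        consumed += end - start + 1
    if plus_offset is None:
        return CodingEffect(gene_id=model.gene_id, effect=EFFECT_NONCODING)

    plus_cds = "".join(seq[s - 1 : e].upper() for s, e in model.cds_segments)
    ref, alt = site.ref, site.alts[0]
    if model.strand == "+":
        cds, offset = plus_cds, plus_offset
    else:
        cds = str(Seq(plus_cds).reverse_complement())
        offset = model.cds_length - plus_offset + 1
        ref = str(Seq(ref).complement())
        alt = str(Seq(alt).complement())

    codon_index = (offset - 1) // 3  # 0-based codon
    within = (offset - 1) % 3
    codon = cds[codon_index * 3 : codon_index * 3 + 3]
    if codon[within] != ref:
        raise ValueError(
            f"{model.gene_id}: CDS base {codon[within]} at offset {offset} "
            f"does not match strand-adjusted REF {ref}"
        )
    alt_codon = codon[:within] + alt + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())

    if ref_aa == alt_aa:
        effect = EFFECT_SYNONYMOUS
    elif alt_aa == "*":
        effect = EFFECT_STOP_GAINED
    elif ref_aa == "*":
        effect = EFFECT_STOP_LOST
    else:
        effect = EFFECT_NONSYNONYMOUS
    return CodingEffect(
        gene_id=model.gene_id,
        effect=effect,
        protein_pos=codon_index + 1,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )


# ---------------------------------------------------------------------------
# TSV / FASTA plumbing


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) genome FASTA as chrom -> uppercase sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq as _Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(_Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    seqio_write(records, str(path), "fasta")


def read_gene_intervals(path: str | Path) -> list[GeneInterval]:
    """Interval TSV: gene_id, chr, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        GeneInterval(str(r.gene_id), str(r.chr), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def write_gene_intervals(intervals: list[GeneInterval], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [iv.gene_id for iv in intervals],
            "chr": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Gene-model TSV: gene_id, chrom, strand, cds_segments.

    ``cds_segments`` are semicolon-separated ``start-end`` pairs, 1-based
    inclusive, in genomic order.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    models = []
    for r in df.itertuples(index=False):
        segments = tuple(
            (int(part.split("-")[0]), int(part.split("-")[1]))
            for part in str(r.cds_segments).split(";")
            if part.strip()
        )
        models.append(GeneModel(str(r.gene_id), str(r.chrom), str(r.strand), segments))
    return models


def write_gene_models(models: list[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in models],
            "chrom": [m.chrom for m in models],
            "strand": [m.strand for m in models],
            "cds_segments": [
                ";".join(f"{s}-{e}" for s, e in m.cds_segments) for m in models
            ],
        }
    ).to_csv(path, sep="\t", index=False)
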