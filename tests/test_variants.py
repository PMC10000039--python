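"""VCF parsing, SNP filtering, caller intersection, gene assignment and
codon-level effect annotation."""

import pytest
from Bio.Seq import Seq

from milkqtl.variants import (
    EFFECT_NONSYNONYMOUS,
    EFFECT_STOP_GAINED,
    EFFECT_SYNONYMOUS,
    GeneInterval,
    GeneModel,
    GenotypeCall,
    GenotypeMatrix,
    MISSING_CALL,
    VariantSite,
    VcfError,
    annotate_coding_effect,
    assign_sites_to_genes,
    filter_variants,
    intersect_callsets,
    read_vcf,
    write_vcf,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##contig=<ID=chr1,length=1000>\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def _write(tmp_path, body, samples=("S1", "S2")):
    path = tmp_path / "test.vcf"
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(VCF_HEADER + cols + "\n" + body)
    return path


class TestReadVcf:
    def test_gt_index_resolution(self, tmp_path):
        path = _write(tmp_path, "chr1\t10\t.\tC\tG\t50\t.\t.\tGT\t0/1\t1/1\n")
        m = read_vcf(path)
        assert [str(c) for c in m.calls[0]] == ["C/G", "G/G"]
        assert m.sites[0].pos == 10
        assert m.sites[0].qual == pytest.approx(50.0)

    def test_missing_genotype(self, tmp_path):
        path = _write(tmp_path, "chr1\t10\t.\tC\tG\t50\t.\t.\tGT\t./.\t0/0\n")
        m = read_vcf(path)
        assert m.calls[0][0].is_missing
        assert not m.calls[0][1].is_missing

    def test_phased_treated_as_unphased(self, tmp_path):
        path = _write(tmp_path, "chr1\t10\t.\tC\tG\t50\t.\t.\tGT\t0|1\t1|0\n")
        m = read_vcf(path)
        assert str(m.calls[0][0]) == str(m.calls[0][1]) == "C/G"

    def test_multiallelic_resolution(self, tmp_path):
        path = _write(tmp_path, "chr1\t10\t.\tA\tC,T\t50\t.\t.\tGT\t1/2\t0/2\n")
        m = read_vcf(path)
        assert str(m.calls[0][0]) == "C/T"
        assert str(m.calls[0][1]) == "A/T"

    def test_non_diploid_rejected_naming_sample_and_site(self, tmp_path):
        path = _write(tmp_path, "chr1\t10\t.\tC\tG\t50\t.\t.\tGT\t0/1/1\t0/0\n")
        with pytest.raises(VcfError, match=r"S1.*chr1:10"):
            read_vcf(path)

    def test_round_trip_preserves_everything(self, tmp_path):
        sites = [
            VariantSite("chr1", 10, "C", ("G",), qual=41.5),
            VariantSite("chr1", 55, "A", ("C", "T"), qual=30.0),
            VariantSite("chr2", 7, "G", ("A",), qual=None),
        ]
        calls = [
            [GenotypeCall("C", "G"), MISSING_CALL],
            [GenotypeCall("C", "T"), GenotypeCall("A", "A")],
            [GenotypeCall("A", "A"), GenotypeCall("G", "A")],
        ]
        matrix = GenotypeMatrix(sites=sites, samples=["S1", "S2"], calls=calls)
        path = tmp_path / "rt.vcf"
        write_vcf(matrix, path)
        back = read_vcf(path)
        assert back.samples == matrix.samples
        for a, b in zip(back.sites, matrix.sites):
            assert a.key == b.key
            if b.qual is None:
                assert a.qual is None
            else:
                assert a.qual == pytest.approx(b.qual, abs=1e-4)
        assert [[str(c) for c in row] for row in back.calls] == [
            [str(c) for c in row] for row in matrix.calls
        ]

    def test_half_call_rejected(self):
        with pytest.raises(VcfError):
            GenotypeCall("A", None)


def _matrix(sites):
    return GenotypeMatrix(sites=sites, samples=[], calls=[[] for _ in sites])


class TestFilterVariants:
    SITES = [
        VariantSite("chr1", 1, "A", ("C",), qual=30.0),  # biallelic SNP, good
        VariantSite("chr1", 2, "A", ("C", "G"), qual=30.0),  # multi-allelic SNP
        VariantSite("chr1", 3, "AT", ("A",), qual=50.0),  # indel
        VariantSite("chr1", 4, "G", ("T",), qual=15.0),  # low quality
    ]

    def test_filter_semantics(self):
        kept = filter_variants(_matrix(self.SITES), min_qual=20.0)
        assert [s.pos for s in kept.sites] == [1, 2]
        kept_bi = filter_variants(_matrix(self.SITES), min_qual=20.0, biallelic_only=True)
        assert [s.pos for s in kept_bi.sites] == [1]

    def test_quality_strictly_greater(self):
        site = VariantSite("chr1", 1, "A", ("C",), qual=20.0)
        assert filter_variants(_matrix([site]), min_qual=20.0).sites == []

    def test_missing_qual_passes(self):
        site = VariantSite("chr1", 1, "A", ("C",), qual=None)
        assert len(filter_variants(_matrix([site]), min_qual=20.0).sites) == 1

    def test_output_subset_and_matches_predicate_scan(self, rng):
        bases = "ACGT"
        sites = []
        for i in range(300):
            ref = bases[rng.integers(4)] * (1 if rng.random() < 0.8 else 2)
            n_alt = 1 if rng.random() < 0.7 else 2
            alts = tuple(bases[rng.integers(4)] for _ in range(n_alt))
            qual = None if rng.random() < 0.1 else float(rng.uniform(0, 60))
            sites.append(VariantSite("chr1", i + 1, ref, alts, qual))
        kept = filter_variants(_matrix(sites), min_qual=20.0).sites
        oracle = [
            s
            for s in sites
            if s.is_snp and (s.qual is None or s.qual > 20.0)
        ]
        assert kept == oracle
        assert set(s.key for s in kept) <= set(s.key for s in sites)


class TestIntersectCallsets:
    def test_identity(self):
        m = _matrix([VariantSite("chr1", 1, "A", ("C",), 30.0)])
        assert intersect_callsets(m, m).sites == m.sites

    def test_same_position_different_alt_excluded(self):
        a = _matrix([VariantSite("chr1", 1, "A", ("C",), 30.0)])
        b = _matrix([VariantSite("chr1", 1, "A", ("G",), 30.0)])
        assert intersect_callsets(a, b).sites == []

    def test_alt_order_irrelevant(self):
        a = _matrix([VariantSite("chr1", 1, "A", ("C", "G"), 30.0)])
        b = _matrix([VariantSite("chr1", 1, "A", ("G", "C"), 25.0)])
        out = intersect_callsets(a, b)
        assert len(out.sites) == 1
        assert out.sites[0].qual == 30.0  # genotypes and metadata from `a`

    def test_matches_keyed_set_oracle(self, rng):
        def random_sites(n):
            return [
                VariantSite(
                    f"chr{rng.integers(1, 3)}",
                    int(rng.integers(1, 50)),
                    "ACGT"[rng.integers(4)],
                    ("ACGT"[rng.integers(4)],),
                    30.0,
                )
                for _ in range(n)
            ]

        a, b = _matrix(random_sites(80)), _matrix(random_sites(80))
        out = intersect_callsets(a, b)
        b_keys = {s.key for s in b.sites}
        assert out.sites == [s for s in a.sites if s.key in b_keys]


class TestAssignSitesToGenes:
    INTERVALS = [
        GeneInterval("geneA", "chr1", 100, 200),
        GeneInterval("geneB", "chr1", 150, 300),
        GeneInterval("geneC", "chr2", 1, 50),
    ]

    def test_boundaries_inclusive(self):
        sites = [
            VariantSite("chr1", 100, "A", ("C",)),
            VariantSite("chr1", 200, "A", ("C",)),
            VariantSite("chr1", 99, "A", ("C",)),
        ]
        summary = assign_sites_to_genes(sites, self.INTERVALS)
        assert summary.set_index("gene_id").snp_count.to_dict() == {
            "geneA": 2,
            "geneB": 1,
            "geneC": 0,
        }

    def test_other_chromosome_unassigned(self):
        summary = assign_sites_to_genes(
            [VariantSite("chr2", 150, "A", ("C",))], self.INTERVALS
        )
        assert summary.snp_count.sum() == 0

    def test_overlapping_genes_both_count(self):
        summary = assign_sites_to_genes(
            [VariantSite("chr1", 175, "A", ("C",))], self.INTERVALS
        )
        counts = summary.set_index("gene_id").snp_count
        assert counts["geneA"] == 1 and counts["geneB"] == 1

    def test_matches_containment_scan(self, rng):
        intervals = [
            GeneInterval(f"g{i}", f"chr{rng.integers(1, 4)}", int(s), int(s + rng.integers(10, 200)))
            for i, s in enumerate(rng.integers(1, 5000, size=20))
        ]
        sites = [
            VariantSite(
                f"chr{rng.integers(1, 4)}",
                int(rng.integers(1, 5200)),
                "A",
                ("C",) if rng.random() < 0.8 else ("C", "G"),
            )
            for _ in range(1000)
        ]
        summary = assign_sites_to_genes(sites, intervals).set_index("gene_id")
        for iv in intervals:
            inside = [
                s for s in sites if s.chrom == iv.chrom and iv.start <= s.pos <= iv.end
            ]
            assert summary.loc[iv.gene_id, "snp_count"] == len(inside)
            assert summary.loc[iv.gene_id, "bisnp_count"] == sum(
                1 for s in inside if s.is_biallelic
            )
            assert summary.loc[iv.gene_id, "bisnp_count"] <= summary.loc[iv.gene_id, "snp_count"]


class TestAnnotateCodingEffect:
    GENOME = {"chr1": "ATGGCTTAA"}
    MODEL = GeneModel("g", "chr1", "+", ((1, 9),))

    def test_nonsynonymous_by_hand_translation(self):
        # codon 2 GCT (Ala) -> GGT (Gly)
        site = VariantSite("chr1", 5, "C", ("G",))
        eff = annotate_coding_effect(site, self.MODEL, self.GENOME)
        assert eff.effect == EFFECT_NONSYNONYMOUS
        assert (eff.protein_pos, eff.ref_aa, eff.alt_aa) == (2, "A", "G")
        assert eff.render() == "2(A/G)"

    def test_synonymous_by_hand_translation(self):
        # codon 2 GCT -> GCC, both Ala
        site = VariantSite("chr1", 6, "T", ("C",))
        eff = annotate_coding_effect(site, self.MODEL, self.GENOME)
        assert eff.effect == EFFECT_SYNONYMOUS
        assert eff.ref_aa == eff.alt_aa == "A"

    def test_stop_gained_never_nonsynonymous(self):
        # codon 2 GCT -> TGA requires pos4 G>T: GCT -> TCT is Ser; use codon 3
        # TAA is already stop; instead mutate codon 1 ATG -> TAG? pos1 A>T gives TTG (Leu)
        # craft: genome ATGTGGTAA, codon 2 TGG (Trp); pos5 G>A -> TAG stop
        genome = {"chr1": "ATGTGGTAA"}
        site = VariantSite("chr1", 5, "G", ("A",))
        eff = annotate_coding_effect(site, GeneModel("g", "chr1", "+", ((1, 9),)), genome)
        assert eff.effect == EFFECT_STOP_GAINED

    def test_noncoding_outside_cds(self):
        genome = {"chr1": "GGATGGCTTAAGG"}
        model = GeneModel("g", "chr1", "+", ((3, 11),))
        site = VariantSite("chr1", 1, "G", ("A",))
        assert annotate_coding_effect(site, model, genome).effect == "NONCODING"

    def test_reverse_strand_mirror(self):
        # reverse-complement construct of the pos-5 C>G example
        fwd_genome = self.GENOME["chr1"]
        rc = str(Seq(fwd_genome).reverse_complement())
        genome = {"chr1": rc}
        model = GeneModel("g", "chr1", "-", ((1, 9),))
        # original pos 5 maps to rc position 9 - 5 + 1 = 5; alleles complemented
        site = VariantSite("chr1", 5, "G", ("C",))
        eff = annotate_coding_effect(site, model, genome)
        assert eff.effect == EFFECT_NONSYNONYMOUS
        assert (eff.protein_pos, eff.ref_aa, eff.alt_aa) == (2, "A", "G")

    def test_split_cds_with_intron(self):
        # ATG GCT TAA with intron inserted between codon1 and codon2
        genome = {"chr1": "ATG" + "gggg".upper() + "GCTTAA"}
        model = GeneModel("g", "chr1", "+", ((1, 3), (8, 13)))
        site = VariantSite("chr1", 9, "C", ("G",))
        eff = annotate_coding_effect(site, model, genome)
        assert eff.effect == EFFECT_NONSYNONYMOUS
        assert eff.render() == "2(A/G)"

    def test_ref_mismatch_rejected(self):
        site = VariantSite("chr1", 5, "A", ("G",))
        with pytest.raises(ValueError, match="does not match genome"):
            annotate_coding_effect(site, self.MODEL, self.GENOME)

    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            GeneModel("g", "chr1", "+", ((1, 8),))
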