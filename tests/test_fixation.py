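"""The between-group fixation classifier on the published genotype tables
and on random matrices (symmetry and invariance properties)."""

import pytest

from milkqtl import fixation
from milkqtl.fixation import (
    FIXED_BOTH_CONCORDANT,
    FIXED_BOTH_DISCORDANT,
    FIXED_HIGH_VARIABLE_LOW,
    FIXED_LOW_VARIABLE_HIGH,
    HIGH,
    INSUFFICIENT_DATA,
    LOW,
    VARIABLE_BOTH,
    GroupAssignment,
    classify_site,
    screen,
    summarize_group,
)
from milkqtl.variants import GenotypeCall, GenotypeMatrix, MISSING_CALL, VariantSite


def _matrix(genotypes, n_high=3, n_low=3):
    """genotypes: list of 'X/Y' or '-' cells, HIGH samples first."""
    samples = [f"H{i}" for i in range(n_high)] + [f"L{i}" for i in range(n_low)]
    calls = []
    for cell in genotypes:
        if cell == "-":
            calls.append(MISSING_CALL)
        else:
            a, b = cell.split("/")
            calls.append(GenotypeCall(a, b))
    site = VariantSite("chr1", 100, "C", ("G",), qual=30.0)
    matrix = GenotypeMatrix(sites=[site], samples=samples, calls=[calls])
    groups = GroupAssignment(
        {**{f"H{i}": HIGH for i in range(n_high)}, **{f"L{i}": LOW for i in range(n_low)}}
    )
    return matrix, groups


class TestSummarizeGroup:
    def test_missing_counted_but_excluded_from_multiset(self):
        # the FGF2 pattern: 5 called HIGH animals, 3 missing, one het
        m, g = _matrix(
            ["G/G", "G/G", "G/A", "-", "-", "-", "G/G", "G/G"] + ["G/G"] * 6,
            n_high=8,
            n_low=6,
        )
        s = summarize_group(0, m, g, HIGH)
        assert (s.n_called, s.n_missing) == (5, 3)
        assert s.fixed_allele is None  # a het is present
        assert s.genotypes == {"G/G": 4, "A/G": 1}

    def test_all_homozygous_is_fixed(self):
        m, g = _matrix(["C/C"] * 6)
        s = summarize_group(0, m, g, HIGH)
        assert s.fixed_allele == "C"

    def test_uniform_het_is_not_fixed(self):
        m, g = _matrix(["C/G"] * 6)
        assert summarize_group(0, m, g, HIGH).fixed_allele is None

    def test_below_min_called_is_not_fixed(self):
        m, g = _matrix(["C/C", "-", "-"] + ["C/C"] * 3)
        assert summarize_group(0, m, g, HIGH, min_called=2).fixed_allele is None

    def test_matches_brute_force_tally(self, rng):
        cells = []
        for _ in range(12):
            r = rng.random()
            cells.append("-" if r < 0.2 else ("C/C" if r < 0.6 else "C/G"))
        m, g = _matrix(cells, n_high=6, n_low=6)
        s = summarize_group(0, m, g, LOW)
        low_cells = cells[6:]
        assert s.n_missing == low_cells.count("-")
        assert s.n_called == 6 - s.n_missing
        called = [c for c in low_cells if c != "-"]
        assert (s.fixed_allele == "C") == (
            len(called) >= 2 and all(c == "C/C" for c in called)
        )


class TestClassifySite:
    @pytest.mark.parametrize(
        "high,low,expected",
        [
            (["C/C"] * 3, ["C/C", "C/G", "C/G"], FIXED_HIGH_VARIABLE_LOW),
            (["C/C", "C/G", "G/G"], ["G/G"] * 3, FIXED_LOW_VARIABLE_HIGH),
            (["G/G"] * 3, ["G/G"] * 3, FIXED_BOTH_CONCORDANT),
            (["C/C"] * 3, ["G/G"] * 3, FIXED_BOTH_DISCORDANT),
            (["C/C", "C/G", "C/C"], ["C/C", "G/G", "C/G"], VARIABLE_BOTH),
            (["C/C", "-", "-"], ["C/C"] * 3, INSUFFICIENT_DATA),
        ],
    )
    def test_rule_table(self, high, low, expected):
        m, g = _matrix(high + low)
        assert classify_site(0, m, g).category == expected

    def test_table3_ghr_column(self, table3_matrix):
        # HIGH all C/C; Dangi, Gaolao, Pulikulam carry C/G
        matrix, groups, genes, labels = table3_matrix
        idx = labels.index("GHR:31685773")
        call = classify_site(idx, matrix, groups)
        assert call.category == FIXED_HIGH_VARIABLE_LOW
        assert call.high_summary.fixed_allele == "C"
        assert call.low_summary.genotypes["C/G"] == 3

    def test_table4_zbtb16_anomalous_column_is_variable_both(self, table4_matrix):
        # Hallikar is A/A inside the nominally fixed LOW group and one
        # Sahiwal is G/A, so the stated rule yields VARIABLE_BOTH
        matrix, groups, genes, labels = table4_matrix
        idx = labels.index("ZBTB16:59718206")
        call = classify_site(idx, matrix, groups)
        assert call.category == VARIABLE_BOTH
        assert call.low_summary.fixed_allele is None

    def test_variable_allele_agnostic_beyond_declared_alt(self, table3_matrix):
        # LPIN1 85211528: Pulikulam C/T where declared ALT is G — still variable
        matrix, groups, genes, labels = table3_matrix
        idx = labels.index("LPIN1:85211528")
        call = classify_site(idx, matrix, groups)
        assert call.category == FIXED_HIGH_VARIABLE_LOW
        assert "C/T" in call.low_summary.genotypes

    def test_multiallelic_site_rejected(self):
        site = VariantSite("chr1", 1, "A", ("C", "G"), 30.0)
        m = GenotypeMatrix([site], ["H0", "L0"], [[GenotypeCall("A", "A")] * 2])
        g = GroupAssignment({"H0": HIGH, "L0": LOW})
        with pytest.raises(ValueError, match="pre-filter"):
            classify_site(0, m, g, min_called=1)


class TestScreenOnFixtures:
    def test_table3_all_fixed_high_variable_low(self, table3_matrix):
        matrix, groups, genes, labels = table3_matrix
        assert len(matrix.sites) == 14
        assert len(matrix.samples) == 14
        report = screen(matrix, groups, site_genes=genes)
        cats = {c: len(v) for c, v in report.by_category().items() if v}
        assert cats == {FIXED_HIGH_VARIABLE_LOW: 14}
        assert report.genes_by_category()[FIXED_HIGH_VARIABLE_LOW] == {
            "GHR", "TLR4", "LPIN1", "CACNA1C", "ZBTB16", "ITGA1", "ANK1", "NT5E",
        }
        # every HIGH summary is complete and fixed
        for call in report.calls:
            assert call.high_summary.n_missing == 0
            assert call.high_summary.is_fixed

    def test_table4_nine_of_ten_fixed_low(self, table4_matrix):
        matrix, groups, genes, labels = table4_matrix
        report = screen(matrix, groups, site_genes=genes)
        cats = {c: len(v) for c, v in report.by_category().items() if v}
        assert cats == {FIXED_LOW_VARIABLE_HIGH: 9, VARIABLE_BOTH: 1}
        # the single missing-data column is FGF2 with 3 missing HIGH calls
        fgf2 = [c for c, g in zip(report.calls, genes) if g == "FGF2"]
        assert len(fgf2) == 1
        assert fgf2[0].high_summary.n_missing == 3
        others = [c for c, g in zip(report.calls, genes) if g != "FGF2"]
        assert all(c.high_summary.n_missing == 0 for c in others)

    def test_single_invariant_site(self):
        m, g = _matrix(["G/G"] * 6)
        report = screen(m, g)
        assert [c.category for c in report.calls] == [FIXED_BOTH_CONCORDANT]


class TestClassifierProperties:
    def _random_matrix(self, rng, n_sites=30):
        samples = [f"H{i}" for i in range(5)] + [f"L{i}" for i in range(4)]
        sites, calls = [], []
        for i in range(n_sites):
            sites.append(VariantSite("chr1", i + 1, "C", ("G",), 30.0))
            row = []
            for _ in samples:
                r = rng.random()
                if r < 0.1:
                    row.append(MISSING_CALL)
                elif r < 0.5:
                    row.append(GenotypeCall("C", "C"))
                elif r < 0.8:
                    row.append(GenotypeCall("C", "G"))
                else:
                    row.append(GenotypeCall("G", "G"))
            calls.append(row)
        groups = GroupAssignment(
            {**{f"H{i}": HIGH for i in range(5)}, **{f"L{i}": LOW for i in range(4)}}
        )
        return GenotypeMatrix(sites, samples, calls), groups

    def test_label_symmetry_under_group_swap(self, rng):
        matrix, groups = self._random_matrix(rng)
        swap = {
            FIXED_HIGH_VARIABLE_LOW: FIXED_LOW_VARIABLE_HIGH,
            FIXED_LOW_VARIABLE_HIGH: FIXED_HIGH_VARIABLE_LOW,
        }
        for i in range(len(matrix.sites)):
            original = classify_site(i, matrix, groups).category
            swapped = classify_site(i, matrix, groups.swapped()).category
            assert swapped == swap.get(original, original)

    def test_sample_order_invariance(self, rng):
        matrix, groups = self._random_matrix(rng)
        perm = rng.permutation(len(matrix.samples))
        permuted = GenotypeMatrix(
            sites=matrix.sites,
            samples=[matrix.samples[j] for j in perm],
            calls=[[row[j] for j in perm] for row in matrix.calls],
        )
        for i in range(len(matrix.sites)):
            assert (
                classify_site(i, matrix, groups).category
                == classify_site(i, permuted, groups).category
            )

    def test_masking_redundant_call_only_degrades_to_insufficient(self, rng):
        # Masking a call whose genotype stays represented in its group
        # leaves the group's genotype set unchanged, so the category can
        # only survive or fall to INSUFFICIENT_DATA. (Masking a group's
        # *sole* variant carrier legitimately reclassifies the site, so
        # that case is excluded by construction.)
        matrix, groups = self._random_matrix(rng, n_sites=20)
        for i in range(len(matrix.sites)):
            before = classify_site(i, matrix, groups).category
            for j, sample in enumerate(matrix.samples):
                call = matrix.calls[i][j]
                if call.is_missing:
                    continue
                group = groups.mapping[sample]
                peers = [
                    matrix.calls[i][k]
                    for k, s in enumerate(matrix.samples)
                    if k != j and groups.mapping[s] == group
                ]
                if not any(str(p) == str(call) for p in peers):
                    continue  # call is load-bearing, not redundant
                masked_row = list(matrix.calls[i])
                masked_row[j] = MISSING_CALL
                masked = GenotypeMatrix(
                    sites=matrix.sites,
                    samples=matrix.samples,
                    calls=[masked_row if k == i else r for k, r in enumerate(matrix.calls)],
                )
                after = classify_site(i, masked, groups).category
                assert after in (before, INSUFFICIENT_DATA)
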