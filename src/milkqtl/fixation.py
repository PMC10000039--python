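"""Between-group genotype fixation screen.

Each biallelic SNP site in a two-group cohort (high- vs low-milk-yield
breeds) is labelled by its genotype pattern: a group is *fixed* when every
called animal is homozygous for one and the same allele (a uniformly
heterozygous group is not fixed), and *variable* relative to the other
group when at least one called genotype differs from that group's fixed
homozygote. The interesting categories are fixed-in-one / variable-in-the-
other; fixed-in-both (concordant or discordant) and variable-in-both round
out the partition. The rule is purely categorical — no allele-frequency
statistic is computed — and tolerates missing calls down to a per-group
floor of called animals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .variants import GenotypeCall, GenotypeMatrix, VariantSite

HIGH = "HIGH"
LOW = "LOW"

FIXED_HIGH_VARIABLE_LOW = "FIXED_HIGH_VARIABLE_LOW"
FIXED_LOW_VARIABLE_HIGH = "FIXED_LOW_VARIABLE_HIGH"
FIXED_BOTH_CONCORDANT = "FIXED_BOTH_CONCORDANT"
FIXED_BOTH_DISCORDANT = "FIXED_BOTH_DISCORDANT"
VARIABLE_BOTH = "VARIABLE_BOTH"
INSUFFICIENT_DATA = "INSUFFICIENT_DATA"

CATEGORIES = (
    FIXED_HIGH_VARIABLE_LOW,
    FIXED_LOW_VARIABLE_HIGH,
    FIXED_BOTH_CONCORDANT,
    FIXED_BOTH_DISCORDANT,
    VARIABLE_BOTH,
    INSUFFICIENT_DATA,
)

#: Minimum called animals a group needs before its fixation status counts.
DEFAULT_MIN_CALLED = 2


class GroupMapError(ValueError):
    """Raised for inconsistent sample-to-group assignments."""


@dataclass
class GroupAssignment:
    """sample_id -> HIGH/LOW mapping; both groups must be non-empty."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.mapping.values() if g not in (HIGH, LOW)}
        if bad:
            raise GroupMapError(f"unknown group label(s) {sorted(bad)}; use HIGH/LOW")
        groups = set(self.mapping.values())
        if groups != {HIGH, LOW}:
            raise GroupMapError("both HIGH and LOW groups must be non-empty")

    def samples(self, which: str) -> list[str]:
        if which not in (HIGH, LOW):
            raise GroupMapError(f"unknown group {which!r}")
        return [s for s, g in self.mapping.items() if g == which]

    def validate_against(self, matrix: GenotypeMatrix) -> None:
        missing = set(self.mapping) - set(matrix.samples)
        if missing:
            raise GroupMapError(f"group map samples absent from matrix: {sorted(missing)}")
        unassigned = set(matrix.samples) - set(self.mapping)
        if unassigned:
            raise GroupMapError(f"matrix samples without a group: {sorted(unassigned)}")

    def swapped(self) -> "GroupAssignment":
        return GroupAssignment(
            {s: (LOW if g == HIGH else HIGH) for s, g in self.mapping.items()}
        )


@dataclass
class GroupSummary:
    group: str
    n_called: int
    n_missing: int
    genotypes: Counter  # multiset of genotype strings, e.g. "C/G"
    fixed_allele: str | None  # set iff all called animals are X/X for one X

    @property
    def is_fixed(self) -> bool:
        return self.fixed_allele is not None


@dataclass
class PatternCall:
    site: VariantSite
    category: str
    high_summary: GroupSummary
    low_summary: GroupSummary


def read_group_map(path: str | Path) -> GroupAssignment:
    """Group-map TSV: sample_id, group (HIGH/LOW)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return GroupAssignment({str(r.sample_id): str(r.group) for r in df.itertuples(index=False)})


def _genotype_str(call: GenotypeCall) -> str:
    # normalize allele order so C/G and G/C are the same genotype
    a, b = sorted((call.allele1, call.allele2))
    return f"{a}/{b}"


def summarize_group(
    site_index: int,
    matrix: GenotypeMatrix,
    groups: GroupAssignment,
    which: str,
    min_called: int = DEFAULT_MIN_CALLED,
) -> GroupSummary:
    """Tally one group's calls at a site and decide its fixation status.

    Missing calls are counted but excluded from the genotype multiset.
    ``fixed_allele`` is set only when every called animal is homozygous
    for the same allele and at least ``min_called`` animals are called.
    """
    members = groups.samples(which)
    if not members:
        raise GroupMapError(f"group {which!r} is empty")
    row = matrix.calls[site_index]
    index = {s: i for i, s in enumerate(matrix.samples)}
    calls = [row[index[s]] for s in members]
    called = [c for c in calls if not c.is_missing]
    genotypes = Counter(_genotype_str(c) for c in called)
    fixed: str | None = None
    if len(called) >= min_called:
        hom = {c.homozygous_allele() for c in called}
        if len(hom) == 1 and None not in hom:
            fixed = hom.pop()
    return GroupSummary(
        group=which,
        n_called=len(called),
        n_missing=len(calls) - len(called),
        genotypes=genotypes,
        fixed_allele=fixed,
    )


def classify_site(
    site_index: int,
    matrix: GenotypeMatrix,
    groups: GroupAssignment,
    min_called: int = DEFAULT_MIN_CALLED,
) -> PatternCall:
    """Label one site by its between-group fixation pattern.

    Rule: a group with fewer than ``min_called`` called animals makes the
    site INSUFFICIENT_DATA. Otherwise both fixed -> concordant/discordant
    by allele equality; exactly one fixed -> fixed-in-that-group,
    variable-in-the-other (the other group necessarily carries a genotype
    differing from the fixed homozygote); neither fixed -> VARIABLE_BOTH.
    """
    site = matrix.sites[site_index]
    if site.is_snp and not site.is_biallelic:
        raise ValueError(
            f"{site.chrom}:{site.pos}: multi-allelic site; pre-filter with "
            "filter_variants(biallelic_only=True)"
        )
    groups.validate_against(matrix)
    high = summarize_group(site_index, matrix, groups, HIGH, min_called)
    low = summarize_group(site_index, matrix, groups, LOW, min_called)

    if high.n_called < min_called or low.n_called < min_called:
        category = INSUFFICIENT_DATA
    elif high.is_fixed and low.is_fixed:
        category = (
            FIXED_BOTH_CONCORDANT
            if high.fixed_allele == low.fixed_allele
            else FIXED_BOTH_DISCORDANT
        )
    elif high.is_fixed:
        _assert_variable_against(low, high.fixed_allele, site)
        category = FIXED_HIGH_VARIABLE_LOW
    elif low.is_fixed:
        _assert_variable_against(high, low.fixed_allele, site)
        category = FIXED_LOW_VARIABLE_HIGH
    else:
        category = VARIABLE_BOTH
    return PatternCall(site=site, category=category, high_summary=high, low_summary=low)


def _assert_variable_against(summary: GroupSummary, fixed_allele: str, site: VariantSite) -> None:
    # When one group is fixed X/X and the other is not fixed, the other
    # necessarily has >= 1 called genotype != X/X. Checked, not assumed.
    fixed_gt = f"{fixed_allele}/{fixed_allele}"
    differing = sum(n for gt, n in summary.genotypes.items() if gt != fixed_gt)
    assert differing >= 1, (
        f"{site.chrom}:{site.pos}: group {summary.group} not fixed yet shows "
        f"no genotype differing from {fixed_gt}"
    )


@dataclass
class PatternReport:
    """All sites classified, with per-category and per-gene roll-ups."""

    calls: list[PatternCall]
    site_genes: list[str | None]  # parallel to calls; None when unassigned

    def by_category(self) -> dict[str, list[PatternCall]]:
        out: dict[str, list[PatternCall]] = {c: [] for c in CATEGORIES}
        for call in self.calls:
            out[call.category].append(call)
        return out

    def genes_by_category(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {c: set() for c in CATEGORIES}
        for call, gene in zip(self.calls, self.site_genes):
            if gene is not None:
                out[call.category].add(gene)
        return out

    def long_table(self, matrix: GenotypeMatrix, groups: GroupAssignment) -> pd.DataFrame:
        rows = []
        for call, gene in zip(self.calls, self.site_genes):
            site = call.site
            rows.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "gene": gene or "",
                    "ref": site.ref,
                    "alt": ",".join(site.alts),
                    "category": call.category,
                    "high_genotypes": _render_genotypes(call.high_summary),
                    "low_genotypes": _render_genotypes(call.low_summary),
                    "n_missing_high": call.high_summary.n_missing,
                    "n_missing_low": call.low_summary.n_missing,
                }
            )
        return pd.DataFrame(rows)

    def wide_table(
        self, matrix: GenotypeMatrix, category: str, site_labels: list[str] | None = None
    ) -> pd.DataFrame:
        """Sites-as-columns, samples-as-rows matrix for one category."""
        cols = {}
        for i, call in enumerate(self.calls):
            if call.category != category:
                continue
            site = call.site
            label = (
                site_labels[i]
                if site_labels is not None
                else f"{site.chrom}:{site.pos}"
            )
            cols[label] = [str(matrix.calls[i][j]) for j in range(len(matrix.samples))]
        return pd.DataFrame(cols, index=matrix.samples)


def _render_genotypes(summary: GroupSummary) -> str:
    return ";".join(f"{gt}x{n}" for gt, n in sorted(summary.genotypes.items()))


def screen(
    matrix: GenotypeMatrix,
    groups: GroupAssignment,
    min_called: int = DEFAULT_MIN_CALLED,
    site_genes: list[str | None] | None = None,
) -> PatternReport:
    """Classify every site in the matrix.

    ``site_genes`` (optional, parallel to ``matrix.sites``) attaches gene
    ids for the per-gene roll-up.
    """
    calls = [
        classify_site(i, matrix, groups, min_called) for i in range(len(matrix.sites))
    ]
    if site_genes is None:
        site_genes = [None] * len(matrix.sites)
    if len(site_genes) != len(matrix.sites):
        raise ValueError("site_genes must parallel matrix.sites")
    return PatternReport(calls=calls, site_genes=list(site_genes))
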