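"""Set algebra over milk-trait QTL gene annotations.

Gene lists extracted from QTL databases (one row per trait association)
contain the same gene under several traits; the accounting that matters
downstream — how many genes are tied to fat yield, fat percentage, both,
or both *exclusively* — is plain set algebra over deduplicated records.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

#: Trait codes recognised in annotation tables: milk fat yield / percentage,
#: milk protein yield / percentage, milk yield, kappa-casein percentage,
#: test-day milk yield.
TRAIT_VOCABULARY = frozenset({"MFY", "MFP", "MPY", "MPP", "MY", "MKCP", "TDMY"})


class TraitTableError(ValueError):
    """Raised for malformed trait-annotation input."""


@dataclass
class GeneRecord:
    """A gene with its set of milk-trait associations."""

    gene_id: str
    traits: set[str]
    symbol: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise TraitTableError("gene record with empty gene_id")
        if not self.traits:
            raise TraitTableError(f"gene {self.gene_id!r} has no traits")
        unknown = set(self.traits) - TRAIT_VOCABULARY
        if unknown:
            raise TraitTableError(
                f"gene {self.gene_id!r}: unknown trait code(s) {sorted(unknown)}"
            )


@dataclass(frozen=True)
class VennCounts:
    """Two-set Venn cardinalities; ``union`` obeys inclusion-exclusion."""

    only_a: int
    only_b: int
    both: int

    @property
    def union(self) -> int:
        return self.only_a + self.only_b + self.both

    @property
    def size_a(self) -> int:
        return self.only_a + self.both

    @property
    def size_b(self) -> int:
        return self.only_b + self.both


def deduplicate(records: list[GeneRecord]) -> list[GeneRecord]:
    """Collapse records sharing a gene_id, merging their trait sets.

    Order of first occurrence is preserved, so the operation is a stable
    group-by. Applying it twice equals applying it once.
    """
    merged: dict[str, GeneRecord] = {}
    for rec in records:
        if rec.gene_id in merged:
            prev = merged[rec.gene_id]
            prev.traits |= rec.traits
            if prev.symbol is None:
                prev.symbol = rec.symbol
        else:
            merged[rec.gene_id] = GeneRecord(rec.gene_id, set(rec.traits), rec.symbol)
    return list(merged.values())


def venn(a: set[str], b: set[str]) -> VennCounts:
    """Exact two-set Venn counts over gene identifiers."""
    both = a & b
    return VennCounts(only_a=len(a - both), only_b=len(b - both), both=len(both))


def trait_gene_set(records: list[GeneRecord], trait: str) -> set[str]:
    """Genes annotated with ``trait`` (after deduplication semantics)."""
    if trait not in TRAIT_VOCABULARY:
        raise TraitTableError(f"unknown trait code {trait!r}")
    return {r.gene_id for r in records if trait in r.traits}


def exclusive_trait_genes(records: list[GeneRecord], required: set[str]) -> set[str]:
    """Genes whose trait set equals ``required`` exactly — no extra traits.

    This is the "associated with both fat yield and fat percentage traits
    only" accounting: a gene also annotated for, say, milk yield does not
    qualify.
    """
    if not required:
        raise TraitTableError("required trait set must be non-empty")
    unknown = set(required) - TRAIT_VOCABULARY
    if unknown:
        raise TraitTableError(f"unknown trait code(s) in required set: {sorted(unknown)}")
    required = set(required)
    return {r.gene_id for r in records if r.traits == required}


def read_trait_table(path: str | Path) -> list[GeneRecord]:
    """Read a trait-annotation TSV: gene_id, optional symbol, traits.

    ``traits`` is semicolon-separated. Rows with an empty gene_id are
    rejected with the offending row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "gene_id" not in df.columns or "traits" not in df.columns:
        raise TraitTableError(f"{path}: expected columns gene_id, traits")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gene_id = (row.gene_id or "").strip() if isinstance(row.gene_id, str) else ""
        if not gene_id:
            raise TraitTableError(f"{path}: row {i}: empty gene_id")
        traits = {t.strip() for t in str(row.traits).split(";") if t.strip()}
        symbol = getattr(row, "symbol", None)
        if isinstance(symbol, float):  # pandas NaN
            symbol = None
        records.append(GeneRecord(gene_id, traits, symbol))
    return records


def write_trait_table(records: list[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "symbol": [r.symbol or "" for r in records],
            "traits": [";".join(sorted(r.traits)) for r in records],
        }
    ).to_csv(path, sep="\t", index=False)
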