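"""Packaged reference tables for the 14-animal cohort study.

Four machine-readable tables ship with the package: the differentially
expressed hub/bottleneck gene list with fold changes (table1), the
per-gene SNP summary (table2), and the two genotype pattern matrices —
sites fixed in the high-milk-yield group (table3) and sites fixed in the
low-milk-yield group (table4). The genotype tables convert to the same
GenotypeMatrix the VCF reader produces, so the fixation screen runs on
them unchanged.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .fixation import HIGH, LOW, GroupAssignment
from .variants import MISSING_CALL, MISSING_CELL, GenotypeCall, GenotypeMatrix, VariantSite

_FILES = {
    "table1": "table1_de_hub_bottleneck.tsv",
    "table2": "table2_gene_snp_summary.tsv",
    "table3": "table3_fixed_high_variable_low.tsv",
    "table4": "table4_fixed_low_variable_high.tsv",
}

#: The cohort: Sahiwal and Gir are the high-milk-yield group (~8 kg/day),
#: the six other breeds the low-milk-yield group (~2.5 kg/day).
HIGH_SAMPLES = (
    "Sahiwal 1", "Sahiwal 2", "Sahiwal 3", "Sahiwal 4",
    "Gir 1", "Gir 2", "Gir 3", "Gir 4",
)
LOW_SAMPLES = ("Amritmahal", "Dangi", "Gaolao", "Deoni", "Pulikulam", "Hallikar")
COHORT_SAMPLES = HIGH_SAMPLES + LOW_SAMPLES


def cohort_groups() -> GroupAssignment:
    return GroupAssignment(
        {**{s: HIGH for s in HIGH_SAMPLES}, **{s: LOW for s in LOW_SAMPLES}}
    )


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged table by short name (table1 ... table4)."""
    if name not in _FILES:
        raise KeyError(
            f"unknown fixture {name!r}; valid names: {', '.join(sorted(_FILES))}"
        )
    ref = resources.files("milkqtl.data").joinpath(_FILES[name])
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def genotype_table_to_matrix(
    df: pd.DataFrame,
) -> tuple[GenotypeMatrix, GroupAssignment, list[str], list[str]]:
    """Convert a table3/table4-style genotype table to matrix form.

    Returns (matrix, group assignment, per-site gene symbols, per-site
    labels "GENE:pos"). Cells are "X/Y" genotypes or "-" for missing.
    """
    samples = [c for c in df.columns if c in COHORT_SAMPLES]
    sites, calls, genes, labels = [], [], [], []
    for _, row in df.iterrows():
        site = VariantSite(
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref=str(row["ref"]),
            alts=(str(row["alt"]),),
            qual=None,
        )
        row_calls = []
        for s in samples:
            cell = str(row[s]).strip()
            if cell in (MISSING_CELL, "", "nan"):
                row_calls.append(MISSING_CALL)
            else:
                a, b = cell.split("/")
                row_calls.append(GenotypeCall(a, b))
        sites.append(site)
        calls.append(row_calls)
        genes.append(str(row["gene"]))
        labels.append(f"{row['gene']}:{row['pos']}")
    matrix = GenotypeMatrix(sites=sites, samples=samples, calls=calls)
    return matrix, cohort_groups(), genes, labels


def load_genotype_fixture(
    name: str,
) -> tuple[GenotypeMatrix, GroupAssignment, list[str], list[str]]:
    """table3/table4 straight to (matrix, groups, site genes, labels)."""
    if name not in ("table3", "table4"):
        raise KeyError(f"{name!r} is not a genotype fixture (use table3 or table4)")
    return genotype_table_to_matrix(load_fixture(name))
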