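#!/usr/bin/env python
"""Generate the full synthetic input bundle with ground truth.

Writes the trait-gene table, scored edge list, DE results and the
two-breed-group cohort (genome, gene models, multi-sample VCF, group map,
truth table) under results/synthetic/. Later analysis steps consume these
files only; nothing downstream sees the truth except the recovery check.
"""

import sys
from pathlib import Path

import pandas as pd

from milkqtl import gene_sets
from milkqtl.simulate import SyntheticConfig, simulate_cohort, simulate_de, simulate_network, simulate_universe

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SyntheticConfig(seed=SEED)

    records = simulate_universe(config)
    gene_sets.write_trait_table(records, OUT / "trait_genes.tsv")
    print(f"trait-gene table: {len(records)} genes -> {OUT / 'trait_genes.tsv'}")

    edges, hubs = simulate_network(config)
    pd.DataFrame(
        {
            "protein_a": [e.a for e in edges],
            "protein_b": [e.b for e in edges],
            "combined_score": [e.score for e in edges],
        }
    ).to_csv(OUT / "edges.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": hubs}).to_csv(OUT / "planted_hubs.tsv", sep="\t", index=False)
    print(f"edge list: {len(edges)} edges, {len(hubs)} planted hubs")

    de = simulate_de(config, target_genes=hubs)
    de.to_csv(OUT / "de_results.tsv", sep="\t", index=False)
    print(f"DE table: {len(de)} genes, {int(de.is_target.sum())} planted targets")

    cohort = simulate_cohort(config)
    paths = cohort.write(OUT)
    print(
        f"cohort: {len(cohort.matrix.sites)} planted sites x "
        f"{len(cohort.matrix.samples)} samples -> {paths['vcf']}"
    )


if __name__ == "__main__":
    main()
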