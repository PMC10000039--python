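#!/usr/bin/env python
"""DE filtering and intersection with the prioritized genes.

Runs twice: on the simulated bundle (planted hubs as DE targets; checks
recall of the planted effects at p < 0.05), and on the packaged gene
table, where the 17 hub + 18 bottleneck entries with their fold changes
reproduce the 25-gene union with 10 genes in both roles.
"""

from pathlib import Path

import pandas as pd

from milkqtl import fixtures, network
from milkqtl.de import DEResult, filter_de, integrate
from milkqtl.network import PrioritizedGenes

ROOT = Path(__file__).resolve().parent.parent / "results"


def synthetic() -> None:
    de_df = pd.read_csv(ROOT / "synthetic" / "de_results.tsv", sep="\t")
    results = [DEResult(r.gene_id, r.log2fc, r.p_value) for r in de_df.itertuples()]
    kept = filter_de(results, alpha=0.05)
    targets = set(de_df.loc[de_df.is_target, "gene_id"])
    kept_ids = {r.gene_id for r in kept}
    print(
        f"synthetic DE: {len(kept)}/{len(results)} rows at p < 0.05; "
        f"target recall {len(targets & kept_ids)}/{len(targets)}"
    )
    pdf = pd.read_csv(ROOT / "prioritized_genes.tsv", sep="\t")
    pg = PrioritizedGenes(
        hubs=list(pdf.loc[pdf.role.isin(["hub", "both"]), "gene_id"]),
        bottlenecks=list(pdf.loc[pdf.role.isin(["bottleneck", "both"]), "gene_id"]),
    )
    table = integrate(pg, kept)
    table.rows.to_csv(ROOT / "de_hub_bottleneck_synthetic.tsv", sep="\t", index=False)
    print(
        f"synthetic integration: {table.n_union} DE hub/bottleneck genes "
        f"({table.n_both} both, {table.n_up} up, {table.n_down} down)"
    )


def packaged() -> None:
    t1 = fixtures.load_fixture("table1")
    hubs = list(t1.loc[t1.section == "hub", "gene_id"])
    bottlenecks = list(t1.loc[t1.section == "bottleneck", "gene_id"])
    de = [
        DEResult(r.gene_id, float(r.log2fc), float(r.p_value))
        for r in t1.drop_duplicates("gene_id").itertuples()
    ]
    table = integrate(
        PrioritizedGenes(hubs=hubs, bottlenecks=bottlenecks), filter_de(de, alpha=0.05)
    )
    table.rows.to_csv(ROOT / "de_hub_bottleneck_cohort.tsv", sep="\t", index=False)
    print(
        f"packaged gene table: {len(hubs)} hubs + {len(bottlenecks)} bottlenecks -> "
        f"union {table.n_union}, both {table.n_both}, "
        f"{table.n_up} up / {table.n_down} down"
    )


def main() -> None:
    synthetic()
    packaged()
    print(f"-> {ROOT / 'de_hub_bottleneck_synthetic.tsv'}")
    print(f"-> {ROOT / 'de_hub_bottleneck_cohort.tsv'}")


if __name__ == "__main__":
    main()
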