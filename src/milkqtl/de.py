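"""Differential-expression filtering and intersection with prioritized genes.

The DE results table (gene_id, log2 fold change, p-value) comes from an
upstream count-model fit (e.g. DESeq2 on mammary epithelial RNA-seq,
high-fat vs low-fat breed orientation); this module only consumes it.
Filtering uses raw p-values by default, matching tables that report
unadjusted p < 0.05; an optional Benjamini-Hochberg mode is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .network import PrioritizedGenes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2fc: float
    p_value: float


@dataclass
class DEHubBottleneckTable:
    """DE genes restricted to the hub/bottleneck union, with role flags."""

    rows: pd.DataFrame  # gene_id, log2fc, p_value, is_hub, is_bottleneck

    @property
    def n_union(self) -> int:
        return len(self.rows)

    @property
    def n_both(self) -> int:
        return int((self.rows.is_hub & self.rows.is_bottleneck).sum())

    @property
    def n_up(self) -> int:
        return int((self.rows.log2fc > 0).sum())

    @property
    def n_down(self) -> int:
        return int((self.rows.log2fc < 0).sum())


def read_de_table(path: str | Path) -> list[DEResult]:
    """Read a DE results TSV with columns gene_id, log2fc, p_value."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene_id", "log2fc", "p_value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene_id, log2fc, p_value")
    return [
        DEResult(str(r.gene_id), float(r.log2fc), float(r.p_value))
        for r in df.itertuples(index=False)
    ]


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """BH step-up adjusted p-values (monotone q-values), order preserved."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        q = p_values[idx] * m / rank
        running_min = min(running_min, q)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


def filter_de(
    results: list[DEResult],
    alpha: float = 0.05,
    min_abs_lfc: float = 0.0,
    adjust: bool = False,
) -> list[DEResult]:
    """Keep rows with p < alpha (strict) and |log2fc| >= min_abs_lfc.

    Rows with a p-value outside [0, 1] are rejected with a warning. With
    ``adjust=True`` the threshold is applied to Benjamini-Hochberg adjusted
    p-values instead (off by default; tables of raw p-values are the norm
    here).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if min_abs_lfc < 0:
        raise ValueError("min_abs_lfc must be >= 0")
    valid = []
    for r in results:
        if not 0.0 <= r.p_value <= 1.0:
            logger.warning("gene %s: p-value %r outside [0, 1]; row dropped", r.gene_id, r.p_value)
            continue
        valid.append(r)
    pvals = [r.p_value for r in valid]
    if adjust:
        pvals = benjamini_hochberg(pvals)
    return [
        r
        for r, p in zip(valid, pvals)
        if p < alpha and abs(r.log2fc) >= min_abs_lfc
    ]


def integrate(prioritized: PrioritizedGenes, de: list[DEResult]) -> DEHubBottleneckTable:
    """Intersect DE genes with the hub/bottleneck union.

    One row per DE gene found in the union, flagged by membership; summary
    counts (union, both, up, down) derive from the rows. A log2fc of
    exactly zero counts as neither up nor down.
    """
    hubs, bottlenecks = set(prioritized.hubs), set(prioritized.bottlenecks)
    union = hubs | bottlenecks
    seen: dict[str, DEResult] = {}
    for r in de:
        if r.gene_id in union and r.gene_id not in seen:
            seen[r.gene_id] = r
    rows = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in seen.values()],
            "log2fc": [r.log2fc for r in seen.values()],
            "p_value": [r.p_value for r in seen.values()],
            "is_hub": [g in hubs for g in seen],
            "is_bottleneck": [g in bottlenecks for g in seen],
        }
    )
    if rows.empty:
        rows = pd.DataFrame(
            columns=["gene_id", "log2fc", "p_value", "is_hub", "is_bottleneck"]
        ).astype({"log2fc": float, "p_value": float, "is_hub": bool, "is_bottleneck": bool})
    return DEHubBottleneckTable(rows=rows)
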