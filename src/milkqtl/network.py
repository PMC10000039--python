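"""Interaction-network construction and hub/bottleneck prioritization.

The network is a simple undirected graph over gene identifiers built from a
scored edge list (STRING-style combined scores). Scores are used only to
threshold edges; shortest paths are unweighted. Hubs are the top-k genes by
degree; bottlenecks the top-k by betweenness centrality — the connectors
between network clusters.

Betweenness convention (fixed, since tools differ): unnormalized node
betweenness on the unweighted graph, endpoints excluded, each unordered
pair of endpoints counted once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


class EdgeListError(ValueError):
    """Raised for malformed interaction edge input."""


@dataclass(frozen=True)
class InteractionEdge:
    a: str
    b: str
    score: float


@dataclass
class CentralityTable:
    """Per-node degree and betweenness."""

    degree: dict[str, int]
    betweenness: dict[str, float]

    def as_frame(self) -> pd.DataFrame:
        nodes = sorted(self.degree)
        return pd.DataFrame(
            {
                "gene_id": nodes,
                "degree": [self.degree[n] for n in nodes],
                "betweenness": [self.betweenness[n] for n in nodes],
            }
        )


@dataclass
class PrioritizedGenes:
    """Ordered hub and bottleneck lists with their union/intersection."""

    hubs: list[str]
    bottlenecks: list[str]

    @property
    def union(self) -> set[str]:
        return set(self.hubs) | set(self.bottlenecks)

    @property
    def intersection(self) -> set[str]:
        return set(self.hubs) & set(self.bottlenecks)


def _normalize_score(raw: float, line: int | None = None) -> float:
    """STRING distributes combined scores as 0-1000 integers; accept both."""
    score = float(raw)
    if score > 1.0:
        if score <= 1000.0:
            logger.info(
                "edge%s: score %g interpreted as millesimal, divided by 1000",
                f" at line {line}" if line else "",
                score,
            )
            score /= 1000.0
        else:
            raise EdgeListError(f"edge score {raw!r} outside [0, 1] and [0, 1000]")
    if score < 0.0:
        raise EdgeListError(f"negative edge score {raw!r}")
    return score


def read_edge_list(path: str | Path) -> list[InteractionEdge]:
    """Read a scored edge-list TSV: protein_a, protein_b, combined_score.

    Integer scores in (1, 1000] are auto-detected as millesimal and scaled.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"protein_a", "protein_b", "combined_score"}
    if not required <= set(df.columns):
        raise EdgeListError(f"{path}: expected columns {sorted(required)}")
    edges = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        a, b = str(row.protein_a).strip(), str(row.protein_b).strip()
        if not a or not b:
            raise EdgeListError(f"{path}: line {i}: empty endpoint")
        try:
            score = _normalize_score(float(row.combined_score), line=i)
        except (TypeError, ValueError) as exc:
            raise EdgeListError(f"{path}: line {i}: bad score {row.combined_score!r}") from exc
        edges.append(InteractionEdge(a, b, score))
    return edges


def build_network(edges: list[InteractionEdge], min_score: float = 0.5) -> nx.Graph:
    """Build the simple undirected graph of edges at or above ``min_score``.

    Self-loops are dropped; duplicate pairs collapse keeping the maximum
    score; endpoints of dropped edges do not enter the node set.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError(f"min_score must be in [0, 1], got {min_score}")
    g = nx.Graph()
    for e in edges:
        score = _normalize_score(e.score)
        if e.a == e.b or score < min_score:
            continue
        if g.has_edge(e.a, e.b):
            g[e.a][e.b]["score"] = max(g[e.a][e.b]["score"], score)
        else:
            g.add_edge(e.a, e.b, score=score)
    return g


def centralities(net: nx.Graph) -> CentralityTable:
    """Degree (incident edge count) and unnormalized betweenness per node."""
    return CentralityTable(
        degree=dict(net.degree()),
        betweenness=nx.betweenness_centrality(net, normalized=False),
    )


def select_top(table: CentralityTable, metric: str, k: int) -> list[str]:
    """Top-k genes by ``metric``, ties broken by gene_id ascending."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if metric == "degree":
        values = table.degree
    elif metric == "betweenness":
        values = table.betweenness
    else:
        raise ValueError(f"unknown metric {metric!r}; use 'degree' or 'betweenness'")
    ranked = sorted(values, key=lambda n: (-values[n], n))
    return ranked[: min(k, len(ranked))]


def prioritize(
    net: nx.Graph,
    k_hub: int = 50,
    k_bottleneck: int = 50,
    degree_percentile_prefilter: float | None = None,
) -> PrioritizedGenes:
    """Select hub (top degree) and bottleneck (top betweenness) genes.

    When ``degree_percentile_prefilter`` is given (a fraction f in (0, 1]),
    bottleneck candidates are restricted to nodes at or above the (1 - f)
    degree quantile — e.g. f=0.2 ranks betweenness only among the top 20%
    of the degree distribution. With f=1.0 or None the ranking is
    unrestricted.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot prioritize an empty network")
    if k_hub < 1 or k_bottleneck < 1:
        raise ValueError("k_hub and k_bottleneck must be >= 1")
    table = centralities(net)
    hubs = select_top(table, "degree", k_hub)

    bt_table = table
    if degree_percentile_prefilter is not None:
        f = degree_percentile_prefilter
        if not 0.0 < f <= 1.0:
            raise ValueError(f"degree_percentile_prefilter must be in (0, 1], got {f}")
        if f < 1.0:
            import numpy as np

            cutoff = float(np.quantile(sorted(table.degree.values()), 1.0 - f))
            keep = {n for n, d in table.degree.items() if d >= cutoff}
            bt_table = CentralityTable(
                degree={n: table.degree[n] for n in keep},
                betweenness={n: table.betweenness[n] for n in keep},
            )
    bottlenecks = select_top(bt_table, "betweenness", k_bottleneck)
    return PrioritizedGenes(hubs=hubs, bottlenecks=bottlenecks)


def prioritized_table(table: CentralityTable, pg: PrioritizedGenes) -> pd.DataFrame:
    """Long-form report of prioritized genes with rank, metric and flags."""
    rows = []
    hub_rank = {g: i + 1 for i, g in enumerate(pg.hubs)}
    bt_rank = {g: i + 1 for i, g in enumerate(pg.bottlenecks)}
    for g in sorted(pg.union):
        rows.append(
            {
                "gene_id": g,
                "degree": table.degree.get(g, 0),
                "betweenness": table.betweenness.get(g, 0.0),
                "hub_rank": hub_rank.get(g, ""),
                "bottleneck_rank": bt_rank.get(g, ""),
                "role": (
                    "both"
                    if g in pg.intersection
                    else ("hub" if g in hub_rank else "bottleneck")
                ),
            }
        )
    return pd.DataFrame(rows)
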