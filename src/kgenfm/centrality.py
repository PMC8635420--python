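"""Network statistics for KG inspection: degree and betweenness centrality.

Betweenness of a node n is C_b(n) = sum over unordered pairs {s, t} (both
different from n) of sigma_st(n) / sigma_st, where sigma_st counts shortest
paths between s and t and sigma_st(n) those passing through n.  Nodes with
high betweenness in biomedical KGs are typically "identifier" hubs (database
accession nodes linked to every member of a type); they dominate shortest
paths, inject noise into embeddings, and are candidates for
:func:`kgenfm.kg.remove_nodes`.

Conventions: the KG is projected to an undirected simple graph (parallel
edges from multiple relations collapse); normalized betweenness divides the
raw value by (N-1)(N-2)/2, giving values in [0, 1]; disconnected pairs
contribute 0 and normalization still uses the total node count N.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .kg import KnowledgeGraph


@dataclass
class CentralityResult:
    """Per-entity centrality table, ranked by betweenness (ties by id)."""

    table: pd.DataFrame  # columns: entity, type, degree, raw, normalized, rank

    def top(self, k: int) -> pd.DataFrame:
        return self.table.head(k)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def to_undirected_graph(kg: KnowledgeGraph) -> nx.Graph:
    """Undirected simple-graph projection of the KG (self-loops dropped)."""
    g = nx.Graph()
    g.add_nodes_from(kg.entities())
    g.add_edges_from((h, t) for h, _, t in kg.triples if h != t)
    return g


def betweenness_centrality(kg: KnowledgeGraph, normalized: bool = True) -> CentralityResult:
    """Betweenness (Brandes), degree, and a 1-based rank per entity."""
    g = to_undirected_graph(kg)
    n = g.number_of_nodes()
    raw = nx.betweenness_centrality(g, normalized=False)
    if n >= 3:
        scale = 2.0 / ((n - 1) * (n - 2))
    else:
        scale = 0.0  # no interior pairs exist; betweenness is identically 0
    rows = sorted(raw, key=lambda e: (-raw[e], e))
    df = pd.DataFrame(
        {
            "entity": rows,
            "type": [kg.entity_types.get(e, "other") for e in rows],
            "degree": [g.degree(e) for e in rows],
            "raw": [raw[e] for e in rows],
            "normalized": [raw[e] * scale for e in rows],
        }
    )
    df["rank"] = range(1, len(df) + 1)
    if not normalized:
        df = df.drop(columns=["normalized"])
    return CentralityResult(table=df)


def centrality_report(kg: KnowledgeGraph, top_k: int) -> pd.DataFrame:
    """Top-k entities by betweenness with type labels and degrees.

    Suitable for spotting hub/identifier nodes to feed ``remove_nodes``;
    ``top_k`` larger than the node count returns all rows.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    return betweenness_centrality(kg, normalized=True).top(top_k)
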