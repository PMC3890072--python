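"""Metabolite-network construction and focal-neighborhood extraction.

Significant partial correlations become signed, weighted edges of an
undirected graph; the reported network is the induced subgraph on every
metabolite within shortest-path distance k (default 3) of a focal
metabolite, urate in the motivating analysis.  "Induced" matters: edges
between two metabolites at equal distance from the focus are kept, which is
how tight clusters (e.g. steroid conjugates) appear fully wired even though
only one member touches the focal node directly.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .pcor import FdrDecision, PcorResult


def build_graph(pcor: PcorResult, decision: FdrDecision,
                node_attrs: dict[str, dict] | None = None) -> nx.Graph:
    """One node per metabolite; one edge per FDR-significant pair, weighted
    by its partial correlation with a '+'/'-' sign attribute."""
    if decision.significant_mask.shape != pcor.r.shape:
        raise ValueError("mask and partial-correlation dimensions differ")
    g = nx.Graph()
    for mid in pcor.metabolite_ids:
        g.add_node(mid, **(node_attrs or {}).get(mid, {}))
    ids = pcor.metabolite_ids
    for i, j in zip(*np.nonzero(np.triu(decision.significant_mask, 1))):
        w = float(pcor.r[i, j])
        g.add_edge(ids[i], ids[j], pcor=w, pval=float(pcor.pvals[i, j]),
                   sign="+" if w > 0 else "-")
    return g


def k_neighborhood(g: nx.Graph, focal: str, k: int = 3) -> nx.Graph:
    """Induced subgraph on all nodes within shortest-path distance k of
    ``focal`` (focal itself at distance 0)."""
    if focal not in g:
        raise KeyError(f"focal metabolite {focal!r} not in graph")
    if k < 0:
        raise ValueError(f"k must be nonnegative, got {k}")
    dist = nx.single_source_shortest_path_length(g, focal, cutoff=k)
    return g.subgraph(dist.keys()).copy()


def edge_table(g: nx.Graph, pcor: PcorResult) -> pd.DataFrame:
    """Long-format edge listing (metabolite_1, metabolite_2, pcor, pval),
    lexicographically ordered for reproducible output."""
    index = {mid: i for i, mid in enumerate(pcor.metabolite_ids)}
    rows = []
    for u, v in g.edges:
        if u not in index or v not in index:
            raise KeyError(f"edge ({u}, {v}) not present in partial-correlation result")
        a, b = sorted((u, v))
        i, j = index[a], index[b]
        rows.append((a, b, float(pcor.r[i, j]), float(pcor.pvals[i, j])))
    rows.sort(key=lambda t: (t[0], t[1]))
    return pd.DataFrame(rows, columns=["metabolite_1", "metabolite_2",
                                       "pcor", "pval"])


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def write_edge_table(g: nx.Graph, pcor: PcorResult, path) -> None:
    edge_table(g, pcor).to_csv(path, sep="\t", index=False)
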