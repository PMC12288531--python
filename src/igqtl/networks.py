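"""Gene co-regulation networks from shared guQTL variants.

Nodes are genes with at least one significant guQTL class; an edge joins
two genes sharing at least one significant variant (member variants, not
just class representatives), weighted by the Jaccard index of their
variant sets.  Structure is summarised as connected components and all
maximal cliques of size >= 2 (exact enumeration; networkx's
Bron-Kerbosch with pivoting).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

MAX_NODES = 10_000


def guqtl_sets(results: pd.DataFrame) -> dict[str, set[str]]:
    """Per-gene set of all member variants of significant classes.

    Genes with no significant class are excluded (they are not network
    nodes)."""
    sig = results[results["significant"]]
    out: dict[str, set[str]] = {}
    for gene, sub in sig.groupby("gene"):
        members: set[str] = set()
        for ids in sub["member_ids"]:
            members.update(ids.split(",") if isinstance(ids, str) else ids)
        out[str(gene)] = members
    return out


def jaccard_edges(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Edge list over gene pairs with at least one shared variant;
    Jaccard = |A and B| / |A or B|."""
    genes = sorted(sets)
    rows = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1:]:
            shared = len(sets[ga] & sets[gb])
            if shared == 0:
                continue
            union = len(sets[ga] | sets[gb])
            rows.append({"gene_a": ga, "gene_b": gb, "shared": shared,
                         "jaccard": shared / union})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "shared", "jaccard"])


def build_graph(sets: dict[str, set[str]]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(sorted(sets))
    edges = jaccard_edges(sets)
    for _, e in edges.iterrows():
        g.add_edge(e["gene_a"], e["gene_b"], shared=int(e["shared"]),
                   jaccard=float(e["jaccard"]))
    return g


@dataclass
class NetworkStructure:
    components: list[list[str]]
    cliques: list[list[str]]


def find_structure(graph: nx.Graph) -> NetworkStructure:
    """Connected components and maximal cliques (size >= 2).

    Output ordering is deterministic: size descending, then
    lexicographic membership.  Isolated nodes appear as singleton
    components but never as cliques.
    """
    if graph.number_of_nodes() > MAX_NODES:
        raise ValueError(f"graph exceeds {MAX_NODES} nodes; out of intended scale")
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c))
    cliques = [sorted(c) for c in nx.find_cliques(graph) if len(c) >= 2]
    cliques.sort(key=lambda c: (-len(c), c))
    return NetworkStructure(components=components, cliques=cliques)


def layout_positions(graph: nx.Graph, seed: int = 0) -> dict[str, tuple[float, float]]:
    """Fruchterman-Reingold layout export hook (presentation only)."""
    pos = nx.spring_layout(graph, seed=seed)
    return {n: (float(x), float(y)) for n, (x, y) in pos.items()}
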