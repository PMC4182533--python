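"""Disease sub-network extraction and decomposition.

The disease-associated sub-network keeps every interactome edge with at least
one endpoint in the prioritised gene list, so first neighbours of prioritised
genes are included (indirect interactions among disease proteins pass through
them). Nodes are flagged by role: ``prioritised`` or ``neighbour``.
"""

from __future__ import annotations

import networkx as nx

from .types import GeneSet, ValidationError

__all__ = [
    "extract_disease_network",
    "connected_components",
    "giant_component",
    "density",
    "density_ratio",
]


def extract_disease_network(proteome: nx.Graph, prioritised: GeneSet) -> nx.Graph:
    """Sub-network of all interactions touching the prioritised set.

    The node set is exactly the endpoints of the retained edges; every edge
    has >= 1 prioritised endpoint. Node attribute ``role`` distinguishes
    prioritised genes from their first neighbours.
    """
    hits = prioritised.members & set(proteome.nodes())
    if not hits:
        raise ValidationError("no prioritised gene is present in the network")
    sub = nx.Graph()
    for u, v in proteome.edges():
        if u in hits or v in hits:
            sub.add_edge(u, v)
    for n in sub.nodes():
        sub.nodes[n]["role"] = "prioritised" if n in hits else "neighbour"
    return sub


def connected_components(net: nx.Graph) -> list[set[str]]:
    """Components sorted by size descending, ties by smallest member."""
    comps = [set(c) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def giant_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component (ties broken deterministically)."""
    comps = connected_components(net)
    if not comps:
        return nx.Graph()
    return net.subgraph(comps[0]).copy()


def density(net: nx.Graph) -> float:
    """2E / N(N-1); zero for graphs with fewer than two nodes."""
    n = net.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * net.number_of_edges() / (n * (n - 1))


def density_ratio(sub: nx.Graph, whole: nx.Graph) -> float:
    """How many times denser the sub-network is than the full network."""
    d_whole = density(whole)
    if d_whole == 0:
        raise ValidationError("reference network has zero density")
    return density(sub) / d_whole
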