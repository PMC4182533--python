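"""Shared fixtures and independent oracle helpers.

The oracles here are deliberately naive re-derivations (brute force,
enumeration, union-find) used to cross-check the package's optimised paths.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.stats import rankdata

from crohnet import SyntheticScenario


@pytest.fixture
def default_scenario() -> SyntheticScenario:
    return SyntheticScenario(seed=0)


@pytest.fixture
def path_abc() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes()})


def auroc(scores, labels) -> float:
    """Rank-based AUROC (Mann-Whitney)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    r = rankdata(scores)
    n1 = labels.sum()
    n0 = (~labels).sum()
    return float((r[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------- oracles --


def oracle_canonical_id(edges_01: set[tuple[int, int]], k: int) -> int:
    """Independent canonicalisation: min over permutations of the bit matrix."""
    best = None
    for perm in itertools.permutations(range(k)):
        value = 0
        for i in range(k):
            for j in range(k):
                a, b = perm[i], perm[j]
                bit = 1 if (min(a, b), max(a, b)) in edges_01 and a != b else 0
                value = (value << 1) | bit
        if best is None or value < best:
            best = value
    return best


def oracle_census(net: nx.Graph, k: int) -> dict[int, int]:
    """All-C(n,k)-combinations census of connected induced k-subgraphs."""
    counts: dict[int, int] = {}
    nodes = sorted(net.nodes())
    for combo in itertools.combinations(nodes, k):
        sub = net.subgraph(combo)
        if nx.is_connected(sub):
            idx = {n: i for i, n in enumerate(combo)}
            edges = {
                (min(idx[u], idx[v]), max(idx[u], idx[v])) for u, v in sub.edges()
            }
            cid = oracle_canonical_id(edges, k)
            counts[cid] = counts.get(cid, 0) + 1
    return counts


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def oracle_components(net: nx.Graph) -> list[set[str]]:
    uf = UnionFind(net.nodes())
    for u, v in net.edges():
        uf.union(u, v)
    groups: dict[str, set[str]] = {}
    for n in net.nodes():
        groups.setdefault(uf.find(n), set()).add(n)
    return sorted(groups.values(), key=lambda c: (-len(c), min(c)))
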