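"""Network motif census with a degree-preserving null model.

Connected induced subgraphs of 3 or 4 nodes are enumerated exhaustively (ESU
enumeration: every connected induced k-subgraph is visited exactly once) and
keyed by their canonical subgraph ID: the undirected subgraph is written as a
symmetric k x k adjacency matrix and the ID is the minimum, over all k! node
permutations, of the row-major bit string read as a binary integer. Under
this convention the 3-path is id78, the triangle id238 and the 4-clique
id31710.

Over-representation is judged against an ensemble of degree-preserving
randomisations of the input graph produced by double-edge switching: classes
with z >= threshold are motifs, z <= -threshold anti-motifs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Mapping

import networkx as nx
import numpy as np

from .types import GeneSet, ValidationError

__all__ = [
    "MotifCensus",
    "canonical_id",
    "enumerate_subgraphs",
    "switch_randomize",
    "motif_zscores",
    "motif_participation",
]

_SUPPORTED_K = (3, 4)


@dataclass(frozen=True)
class MotifClassStats:
    real_count: int
    null_mean: float
    null_sd: float
    z_score: float
    call: str  # motif | anti-motif | neutral


@dataclass(frozen=True)
class MotifCensus:
    k: int
    classes: Mapping[int, MotifClassStats]
    n_random: int
    z_threshold: float
    swaps_per_edge: int
    seed: int | None

    def motif_ids(self) -> list[int]:
        return sorted(i for i, s in self.classes.items() if s.call == "motif")

    def anti_motif_ids(self) -> list[int]:
        return sorted(i for i, s in self.classes.items() if s.call == "anti-motif")


def _matrix_value(k: int, adj: list[list[int]]) -> int:
    value = 0
    for i in range(k):
        for j in range(k):
            value = (value << 1) | adj[i][j]
    return value


def canonical_id(adjacency: np.ndarray | list[list[int]]) -> int:
    """Canonical decimal ID of a small undirected subgraph.

    The adjacency matrix must be symmetric with a zero diagonal. The ID is
    minimised over all node permutations, so it is invariant to relabelling.
    """
    A = np.asarray(adjacency, dtype=int)
    k = A.shape[0]
    if A.shape != (k, k) or np.any(A != A.T) or np.any(np.diag(A) != 0):
        raise ValidationError("adjacency must be symmetric with zero diagonal")
    best = None
    for perm in itertools.permutations(range(k)):
        adj = [[int(A[perm[i], perm[j]]) for j in range(k)] for i in range(k)]
        v = _matrix_value(k, adj)
        if best is None or v < best:
            best = v
    return best


@lru_cache(maxsize=None)
def _id_table(k: int) -> tuple[tuple[tuple[int, int], ...], dict[int, int]]:
    """Map every k-node edge bitmask to its canonical ID (connected masks only)."""
    pairs = tuple(itertools.combinations(range(k), 2))
    table: dict[int, int] = {}
    for mask in range(1 << len(pairs)):
        A = np.zeros((k, k), dtype=int)
        g = nx.Graph()
        g.add_nodes_from(range(k))
        for bit, (i, j) in enumerate(pairs):
            if mask >> bit & 1:
                A[i, j] = A[j, i] = 1
                g.add_edge(i, j)
        if nx.is_connected(g):
            table[mask] = canonical_id(A)
    return pairs, table


def _esu(net: nx.Graph, k: int, visit: Callable[[list[str]], None]) -> None:
    """ESU enumeration of connected induced k-subgraphs, each exactly once."""
    nodes = sorted(net.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    adj = {n: set(net.neighbors(n)) - {n} for n in nodes}

    def extend(sub: list[str], extension: set[str], v_idx: int, sub_neigh: set[str]) -> None:
        if len(sub) == k:
            visit(sub)
            return
        ext = set(extension)
        while ext:
            w = ext.pop()
            new_neigh = sub_neigh | adj[w] | {w}
            exclusive = {
                u for u in adj[w] if index[u] > v_idx and u not in sub_neigh and u not in sub
            }
            extend(sub + [w], ext | exclusive, v_idx, new_neigh)

    for v in nodes:
        start_ext = {u for u in adj[v] if index[u] > index[v]}
        extend([v], start_ext, index[v], adj[v] | {v})


def _instance_id(net: nx.Graph, sub: list[str], pairs, table) -> int:
    mask = 0
    for bit, (i, j) in enumerate(pairs):
        if net.has_edge(sub[i], sub[j]):
            mask |= 1 << bit
    return table[mask]


def enumerate_subgraphs(net: nx.Graph, k: int) -> dict[int, int]:
    """Census of connected induced k-subgraphs keyed by canonical ID."""
    if k not in _SUPPORTED_K:
        raise ValidationError(f"subgraph size must be one of {_SUPPORTED_K}")
    pairs, table = _id_table(k)
    counts: dict[int, int] = {}

    def visit(sub: list[str]) -> None:
        cid = _instance_id(net, sub, pairs, table)
        counts[cid] = counts.get(cid, 0) + 1

    _esu(net, k, visit)
    return counts


def switch_randomize(net: nx.Graph, swaps_per_edge: int = 10, seed: int | None = None) -> nx.Graph:
    """Degree-preserving randomisation by accepted double-edge swaps.

    Performs swaps_per_edge * E accepted swaps (a-b, c-d -> a-d, c-b),
    rejecting any swap that would create a self-loop or duplicate edge. An
    attempt cap of 100x the target guards graphs with no valid swap (a
    triangle is returned unchanged).
    """
    edges = [tuple(sorted(e)) for e in net.edges()]
    out = nx.Graph()
    out.add_nodes_from(net.nodes())
    out.add_edges_from(edges)
    n_edges = len(edges)
    if n_edges < 2:
        return out
    rng = np.random.default_rng(seed)
    target = swaps_per_edge * n_edges
    edge_set = set(edges)
    accepted = 0
    attempts = 0
    max_attempts = max(1000, 100 * target)
    while accepted < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(n_edges), rng.integers(n_edges)
        if i == j:
            continue
        a, b = edges[int(i)]
        c, d = edges[int(j)]
        if rng.random() < 0.5:
            c, d = d, c
        # propose a-d and c-b
        if a == d or c == b:
            continue
        e1, e2 = tuple(sorted((a, d))), tuple(sorted((c, b)))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard((min(a, b), max(a, b)))
        edge_set.discard((min(c, d), max(c, d)))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[int(i)], edges[int(j)] = e1, e2
        accepted += 1
    out.remove_edges_from(list(out.edges()))
    out.add_edges_from(edges)
    return out


def motif_zscores(
    net: nx.Graph,
    k: int,
    n_random: int = 100,
    z_threshold: float = 2.0,
    swaps_per_edge: int = 10,
    seed: int | None = None,
) -> MotifCensus:
    """Compare the real census against degree-preserving randomisations.

    z = (real - null mean) / null sd per canonical ID; classes whose null sd
    is zero and whose real count equals the null mean are neutral.
    """
    real = enumerate_subgraphs(net, k)
    rng = np.random.default_rng(seed)
    null_counts: dict[int, list[int]] = {}
    ids = set(real)
    draws = []
    for _ in range(n_random):
        g = switch_randomize(net, swaps_per_edge, seed=int(rng.integers(2**31)))
        c = enumerate_subgraphs(g, k)
        draws.append(c)
        ids |= set(c)
    for cid in ids:
        null_counts[cid] = [c.get(cid, 0) for c in draws]
    classes: dict[int, MotifClassStats] = {}
    for cid in sorted(ids):
        vals = np.array(null_counts[cid], dtype=float)
        mu = float(vals.mean()) if len(vals) else 0.0
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        r = real.get(cid, 0)
        if sd > 0:
            z = (r - mu) / sd
        elif r == mu:
            z = 0.0
        else:
            z = float("inf") if r > mu else float("-inf")
        if z >= z_threshold:
            call = "motif"
        elif z <= -z_threshold:
            call = "anti-motif"
        else:
            call = "neutral"
        classes[cid] = MotifClassStats(
            real_count=r, null_mean=mu, null_sd=sd, z_score=float(z), call=call
        )
    return MotifCensus(
        k=k,
        classes=classes,
        n_random=n_random,
        z_threshold=z_threshold,
        swaps_per_edge=swaps_per_edge,
        seed=seed,
    )


def motif_participation(
    net: nx.Graph,
    census: MotifCensus,
    genes: GeneSet | None = None,
    include_all_classes: bool = False,
) -> dict[str, int]:
    """Count, per gene, the subgraph instances of motif classes containing it.

    By default only classes called ``motif`` in the census are counted; with
    ``include_all_classes`` every subgraph class participates. The result is
    restricted to ``genes`` when given, and is sorted by descending count
    with lexicographic tie-break.
    """
    if include_all_classes:
        wanted = set(census.classes)
    else:
        wanted = set(census.motif_ids())
    pairs, table = _id_table(census.k)
    counts: dict[str, int] = {n: 0 for n in net.nodes()}

    def visit(sub: list[str]) -> None:
        if _instance_id(net, sub, pairs, table) in wanted:
            for n in sub:
                counts[n] += 1

    _esu(net, census.k, visit)
    if genes is not None:
        counts = {g: counts.get(g, 0) for g in genes.members}
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
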