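"""Global topological characterisation and the random-graph comparison.

Covers the degree-resolved clustering profile C(k) (a signature of
hierarchical modularity), the topological coefficient (neighbourhood-sharing
signature), and a comparison of whole-graph metrics against an ensemble of
Erdős–Rényi graphs with the same number of nodes and edges, summarised as
z-scores with two-sided normal p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
from scipy import stats

from .disease_network import density, giant_component
from .types import ValidationError

__all__ = [
    "TopologyReport",
    "clustering_by_degree",
    "topological_coefficient",
    "graph_metrics",
    "er_ensemble_compare",
]


@dataclass(frozen=True)
class TopologyReport:
    degree: Mapping[str, int]
    clustering: Mapping[str, float]
    topological_coeff: Mapping[str, float]
    metrics: Mapping[str, float]
    null_mean: Mapping[str, float] = field(default_factory=dict)
    null_sd: Mapping[str, float] = field(default_factory=dict)
    z_scores: Mapping[str, float] = field(default_factory=dict)
    p_values: Mapping[str, float] = field(default_factory=dict)
    n_random: int = 0
    seed: int | None = None


def clustering_by_degree(net: nx.Graph) -> dict[int, float]:
    """Mean clustering coefficient per degree k, over nodes with k >= 2."""
    clustering = nx.clustering(net)
    by_k: dict[int, list[float]] = {}
    for n, c in clustering.items():
        k = net.degree(n)
        if k >= 2:
            by_k.setdefault(k, []).append(c)
    return {k: float(np.mean(v)) for k, v in sorted(by_k.items())}


def topological_coefficient(net: nx.Graph, node: str) -> float | None:
    """TC(n) = mean over partners m sharing >=1 neighbour of J(n, m) / k(n).

    J(n, m) counts neighbours shared by n and m, plus one if n and m are
    adjacent. Undefined (None) for nodes with fewer than two neighbours.
    """
    neigh = set(net.neighbors(node)) - {node}
    k = len(neigh)
    if k < 2:
        return None
    shared: dict[str, int] = {}
    for u in neigh:
        for m in net.neighbors(u):
            if m != node:
                shared[m] = shared.get(m, 0) + 1
    for m in list(shared):
        if m in neigh:
            shared[m] += 1
    if not shared:
        return None
    return float(np.mean([j / k for j in shared.values()]))


def graph_metrics(net: nx.Graph) -> dict[str, float]:
    """Whole-graph summary; path-based metrics are computed on the giant component."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValidationError("empty graph")
    degrees = [d for _, d in net.degree()]
    giant = giant_component(net)
    metrics = {
        "n_nodes": float(n),
        "n_edges": float(net.number_of_edges()),
        "mean_degree": float(np.mean(degrees)),
        "mean_clustering": float(nx.average_clustering(net)),
        "density": density(net),
        "n_components": float(nx.number_connected_components(net)),
    }
    if giant.number_of_nodes() >= 2:
        metrics["mean_shortest_path"] = float(nx.average_shortest_path_length(giant))
        metrics["diameter"] = float(nx.diameter(giant))
    else:
        metrics["mean_shortest_path"] = float("nan")
        metrics["diameter"] = float("nan")
    return metrics


_COMPARED = ["mean_clustering", "mean_shortest_path", "diameter", "n_components"]


def er_ensemble_compare(net: nx.Graph, n_random: int = 100, seed: int = 0) -> TopologyReport:
    """Compare graph metrics against same-N, same-E Erdős–Rényi graphs.

    For each metric x the report carries z = (x - mu) / sigma over the
    ensemble and a two-sided normal p-value; a degenerate ensemble
    (sigma = 0) yields NaN z. Mean degree and density are identical by
    construction and not compared.
    """
    rng = np.random.default_rng(seed)
    real = graph_metrics(net)
    n, e = net.number_of_nodes(), net.number_of_edges()
    draws: dict[str, list[float]] = {k: [] for k in _COMPARED}
    for _ in range(n_random):
        g = nx.gnm_random_graph(n, e, seed=int(rng.integers(2**31)))
        m = graph_metrics(nx.relabel_nodes(g, {i: str(i) for i in g.nodes()}))
        for k in _COMPARED:
            draws[k].append(m[k])
    null_mean, null_sd, zs, ps = {}, {}, {}, {}
    for k in _COMPARED:
        vals = np.array(draws[k], dtype=float)
        vals = vals[~np.isnan(vals)]
        mu = float(vals.mean()) if len(vals) else float("nan")
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        null_mean[k], null_sd[k] = mu, sd
        if sd and sd > 0 and not np.isnan(real[k]):
            z = (real[k] - mu) / sd
            zs[k] = z
            ps[k] = float(2.0 * stats.norm.sf(abs(z)))
        else:
            zs[k] = float("nan")
            ps[k] = float("nan")
    return TopologyReport(
        degree=dict(net.degree()),
        clustering=nx.clustering(net),
        topological_coeff={
            v: tc for v in net.nodes() if (tc := topological_coefficient(net, v)) is not None
        },
        metrics=real,
        null_mean=null_mean,
        null_sd=null_sd,
        z_scores=zs,
        p_values=ps,
        n_random=n_random,
        seed=seed,
    )
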