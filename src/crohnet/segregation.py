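"""Topological segregation of functional classes.

For a protein i in functional class j, the shell fraction S_i(d) is the
proportion of proteins at shortest-path distance d from i that also belong to
class j. Averaging over the class members with a non-empty shell gives
<S_j(d)>; if the class were placed at random this would equal the class's
global frequency n_j / N at every distance. The scalar segregation index

    S_j = mean over d of  <S_j(d)> / (n_j / N)

therefore equals 1 for randomly placed classes and exceeds 1 for classes
that form topologically cohesive neighbourhoods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np

from .types import AnnotationMap, GeneSet, ValidationError

__all__ = [
    "SegregationProfile",
    "distance_shells",
    "shell_fraction",
    "segregation_index",
    "list_segregation",
    "annotation_segregation",
]


@dataclass(frozen=True)
class SegregationProfile:
    class_name: str
    shell_average: Mapping[int, float]   # d -> <S(d)>
    shell_ratio: Mapping[int, float]     # d -> <S(d)> / (n_j / N)
    population: int                      # n_j: class members in the network
    network_size: int                    # N
    index: float                         # scalar segregation index
    d_max: int


def distance_shells(net: nx.Graph, node: str) -> dict[int, set[str]]:
    """Breadth-first shells from a node; d=0 (the node itself) is omitted.

    The shells partition the node's connected component minus the node.
    """
    lengths = nx.single_source_shortest_path_length(net, node)
    shells: dict[int, set[str]] = {}
    for other, d in lengths.items():
        if d > 0:
            shells.setdefault(d, set()).add(other)
    return shells


def shell_fraction(net: nx.Graph, node: str, class_members: set[str], d: int) -> float:
    """Fraction of the distance-d shell of ``node`` belonging to the class.

    The focal node never counts toward either side of the ratio; the shell at
    d must be non-empty.
    """
    shells = distance_shells(net, node)
    if d not in shells or not shells[d]:
        raise ValidationError(f"shell at distance {d} from {node!r} is empty")
    shell = shells[d] - {node}
    return len(shell & class_members) / len(shell)


def segregation_index(
    net: nx.Graph,
    class_members: set[str],
    class_name: str = "class",
    d_max: int | None = None,
    min_shell_coverage: float = 0.5,
    ratio_of_averages: bool = False,
) -> SegregationProfile:
    """Per-distance shell profile and the scalar segregation index of a class.

    <S(d)> averages the shell fraction over class members whose shell at d is
    non-empty. Unless given, d_max is the largest distance at which at least
    ``min_shell_coverage`` of class members still have a non-empty shell. The
    default index averages the per-distance ratios over d in [1, d_max]; with
    ``ratio_of_averages`` the per-distance averages are pooled first and the
    ratio taken once.
    """
    members = sorted(class_members & set(net.nodes()))
    n_j, n = len(members), net.number_of_nodes()
    if n_j < 2:
        raise ValidationError("class must have at least 2 members in the network")
    shells = {m: distance_shells(net, m) for m in members}
    all_d = sorted({d for s in shells.values() for d in s})
    if not all_d:
        raise ValidationError("class members are all isolated")
    if d_max is None:
        covered = [
            d for d in all_d if sum(1 for m in members if d in shells[m]) >= min_shell_coverage * n_j
        ]
        d_max = max(covered) if covered else min(all_d)
    baseline = n_j / n
    shell_average: dict[int, float] = {}
    shell_ratio: dict[int, float] = {}
    cls = set(members)
    for d in [d for d in all_d if d <= d_max]:
        fractions = []
        for m in members:
            shell = shells[m].get(d)
            if shell:
                shell = shell - {m}
                fractions.append(len(shell & cls) / len(shell))
        if fractions:
            shell_average[d] = float(np.mean(fractions))
            shell_ratio[d] = shell_average[d] / baseline
    if ratio_of_averages:
        index = float(np.mean(list(shell_average.values()))) / baseline
    else:
        index = float(np.mean(list(shell_ratio.values())))
    return SegregationProfile(
        class_name=class_name,
        shell_average=shell_average,
        shell_ratio=shell_ratio,
        population=n_j,
        network_size=n,
        index=index,
        d_max=d_max,
    )


def list_segregation(net: nx.Graph, genes: GeneSet, **kwargs) -> SegregationProfile:
    """Segregation of a gene list (e.g. the prioritised set) as one class."""
    return segregation_index(net, set(genes.members), class_name=genes.label, **kwargs)


def annotation_segregation(
    net: nx.Graph,
    annotations: AnnotationMap,
    min_size: int = 5,
    **kwargs,
) -> list[SegregationProfile]:
    """Segregation profiles for every class with >= min_size members in the network.

    Sorted from most to least segregated.
    """
    profiles = []
    nodes = set(net.nodes())
    for name, members in annotations.items():
        if len(members & nodes) >= max(min_size, 2):
            profiles.append(segregation_index(net, set(members), class_name=name, **kwargs))
    profiles.sort(key=lambda p: (-p.index, p.class_name))
    return profiles
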