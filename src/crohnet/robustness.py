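"""Failure-attack tolerance: node-removal trajectories.

Nodes are deleted in batches under a strategy — uniformly random (failure),
by descending original degree (hub attack), by ascending degree, or in the
order of a supplied gene set — and after each batch the surviving interaction
count and the cumulative number of secondary extinctions are recorded. A
secondary extinction is a node that was never deliberately removed but lost
all of its interaction partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .types import GeneSet, ValidationError

__all__ = ["RemovalStep", "RemovalTrajectory", "removal_trajectory", "mean_trajectory"]

STRATEGIES = ("random", "degree_desc", "degree_asc", "gene_set")


@dataclass(frozen=True)
class RemovalStep:
    fraction_removed: float
    surviving_edges: int
    secondary_extinctions: int  # cumulative


@dataclass(frozen=True)
class RemovalTrajectory:
    strategy: str
    steps: tuple[RemovalStep, ...]
    seed: int | None

    def surviving_edges_at(self, fraction: float) -> int:
        """Surviving edge count at the first step with fraction >= the query."""
        for s in self.steps:
            if s.fraction_removed >= fraction - 1e-12:
                return s.surviving_edges
        return self.steps[-1].surviving_edges


def _removal_order(
    net: nx.Graph,
    strategy: str,
    seed: int | None,
    gene_set: GeneSet | None,
    recalculate: bool,
) -> list[str] | None:
    nodes = sorted(net.nodes())
    if strategy == "random":
        rng = np.random.default_rng(seed)
        order = list(rng.permutation(len(nodes)))
        return [nodes[int(i)] for i in order]
    if strategy == "degree_desc":
        return None if recalculate else sorted(nodes, key=lambda n: (-net.degree(n), n))
    if strategy == "degree_asc":
        return sorted(nodes, key=lambda n: (net.degree(n), n))
    if strategy == "gene_set":
        if gene_set is None:
            raise ValidationError("gene_set strategy requires a gene set")
        return sorted(gene_set.members & set(nodes))
    raise ValidationError(f"unknown strategy {strategy!r}")


def removal_trajectory(
    net: nx.Graph,
    strategy: str,
    step_fraction: float = 0.05,
    seed: int | None = None,
    gene_set: GeneSet | None = None,
    recalculate: bool = False,
) -> RemovalTrajectory:
    """Remove nodes in batches and record the damage after each batch.

    Batches hold ceil(step_fraction * N) nodes (the trailing batch may be
    smaller). Degree orderings use the ORIGINAL degrees; pass
    ``recalculate=True`` for an adaptive hub attack that re-sorts after every
    batch. For the gene_set strategy only the listed nodes are removed and
    fractions are relative to the full node count.
    """
    if not 0.0 < step_fraction <= 1.0:
        raise ValidationError("step_fraction must be in (0, 1]")
    n_total = net.number_of_nodes()
    if n_total == 0:
        raise ValidationError("empty graph")
    work = net.copy()
    batch = int(np.ceil(step_fraction * n_total))
    order = _removal_order(net, strategy, seed, gene_set, recalculate)
    removed: set[str] = set()
    extinct: set[str] = set()
    steps: list[RemovalStep] = []
    position = 0
    n_to_remove = len(order) if order is not None else n_total
    while position < n_to_remove:
        if order is not None:
            chunk = order[position : position + batch]
        else:  # adaptive hub attack: re-rank surviving nodes by current degree
            chunk = sorted(work.nodes(), key=lambda n: (-work.degree(n), n))[:batch]
        position += len(chunk)
        work.remove_nodes_from(chunk)
        removed.update(chunk)
        for node in work.nodes():
            if work.degree(node) == 0 and node not in extinct:
                extinct.add(node)
        steps.append(
            RemovalStep(
                fraction_removed=len(removed) / n_total,
                surviving_edges=work.number_of_edges(),
                secondary_extinctions=len(extinct),
            )
        )
    return RemovalTrajectory(strategy=strategy, steps=tuple(steps), seed=seed)


def mean_trajectory(trajectories: list[RemovalTrajectory]) -> list[tuple[float, float, float]]:
    """Average surviving edges and extinctions across same-shape trajectories."""
    lengths = {len(t.steps) for t in trajectories}
    if len(lengths) != 1:
        raise ValidationError("trajectories must have identical step counts")
    out = []
    for i in range(lengths.pop()):
        fr = trajectories[0].steps[i].fraction_removed
        edges = float(np.mean([t.steps[i].surviving_edges for t in trajectories]))
        ext = float(np.mean([t.steps[i].secondary_extinctions for t in trajectories]))
        out.append((fr, edges, ext))
    return out
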