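"""Random-walk-with-restart gene prioritisation and the consensus rule.

A walker is released from a set of training genes (known disease genes) and
diffuses along the interactome:

    p(t+1) = (1 - r) W p(t) + r e

where W is the column-normalised adjacency matrix, e the restart vector
(uniform over training genes present in the network) and r the restart
probability. Nodes proximal to the training set accumulate stationary
probability and are prioritised. The final gene list is the consensus of the
walk-based selection with an externally supplied relatedness ranking, united
with the training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .types import GeneSet, RankedList, ValidationError

__all__ = [
    "ProbabilityVector",
    "PrioritisationResult",
    "rwr",
    "rwr_exact",
    "select_by_steady_state",
    "select_external",
    "consensus",
]


@dataclass(frozen=True)
class ProbabilityVector:
    """Stationary visiting probabilities of the restarted walk."""

    probabilities: Mapping[str, float]
    restart: float
    iterations: int
    converged: bool

    def __getitem__(self, gene: str) -> float:
        return self.probabilities[gene]

    def top(self, k: int) -> list[str]:
        """The k most-visited genes, ties broken lexicographically."""
        order = sorted(self.probabilities, key=lambda g: (-self.probabilities[g], g))
        return order[:k]


@dataclass(frozen=True)
class PrioritisationResult:
    rwr_selected: GeneSet
    external_selected: GeneSet
    training: GeneSet
    consensus: GeneSet
    combiner: str = "intersection"


def _walk_matrix(net: nx.Graph) -> tuple[sp.csr_matrix, list[str]]:
    """Column-normalised adjacency; zero columns for isolated nodes."""
    nodes = sorted(net.nodes())
    A = nx.to_scipy_sparse_array(net, nodelist=nodes, format="csc", dtype=float)
    deg = np.asarray(A.sum(axis=0)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    W = A @ sp.diags(inv)
    return sp.csr_matrix(W), nodes


def _restart_vector(nodes: list[str], training: GeneSet) -> np.ndarray:
    seeds = sorted(training.members & set(nodes))
    if not seeds:
        raise ValidationError("no training gene is present in the network")
    e = np.zeros(len(nodes))
    idx = {g: i for i, g in enumerate(nodes)}
    for g in seeds:
        e[idx[g]] = 1.0 / len(seeds)
    return e


def rwr(
    net: nx.Graph,
    training: GeneSet,
    r: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> ProbabilityVector:
    """Iterate the restarted walk to its stationary distribution.

    Stops when the L1 difference between successive probability vectors drops
    below ``tol`` (converged) or after ``max_iter`` iterations. With r = 1 the
    result is the restart vector itself. Probability mass is conserved at
    every iteration on graphs without isolated nodes; walker mass never
    reaches components that contain no training gene.
    """
    if not 0.0 < r <= 1.0:
        raise ValidationError("restart probability must be in (0, 1]")
    W, nodes = _walk_matrix(net)
    e = _restart_vector(nodes, training)
    p = e.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        p_next = (1.0 - r) * (W @ p) + r * e
        if np.abs(p_next - p).sum() < tol:
            p = p_next
            converged = True
            break
        p = p_next
    return ProbabilityVector(
        probabilities={g: float(p[i]) for i, g in enumerate(nodes)},
        restart=r,
        iterations=iterations,
        converged=converged,
    )


def rwr_exact(net: nx.Graph, training: GeneSet, r: float = 0.5) -> ProbabilityVector:
    """Direct linear solve of the stationary equation (I - (1-r)W) p = r e."""
    if not 0.0 < r <= 1.0:
        raise ValidationError("restart probability must be in (0, 1]")
    W, nodes = _walk_matrix(net)
    e = _restart_vector(nodes, training)
    A = sp.eye(len(nodes), format="csc") - (1.0 - r) * W
    p = spla.spsolve(sp.csc_matrix(A), r * e)
    return ProbabilityVector(
        probabilities={g: float(p[i]) for i, g in enumerate(nodes)},
        restart=r,
        iterations=0,
        converged=True,
    )


def select_by_steady_state(
    p: ProbabilityVector,
    candidates: GeneSet,
    rule: str = "top_k",
    value: float = 212,
) -> GeneSet:
    """Select candidate genes from the stationary distribution.

    ``top_k`` takes the ``value`` highest-probability candidates (ties broken
    lexicographically); ``prob_threshold`` takes candidates with probability
    strictly above ``value``. Candidates absent from the network are ignored.
    """
    pool = sorted(candidates.members & set(p.probabilities))
    pool.sort(key=lambda g: (-p.probabilities[g], g))
    if rule == "top_k":
        k = int(value)
        if k > len(pool):
            warnings.warn(
                f"top_k={k} exceeds candidate pool size {len(pool)}; returning all",
                stacklevel=2,
            )
            k = len(pool)
        chosen = pool[:k]
    elif rule == "prob_threshold":
        chosen = [g for g in pool if p.probabilities[g] > value]
    else:
        raise ValidationError(f"unknown selection rule {rule!r}")
    return GeneSet("rwr_selected", chosen)


def select_external(ranked: RankedList, p_threshold: float = 0.1) -> GeneSet:
    """Genes from the external relatedness ranking with p strictly below threshold."""
    return GeneSet("external_selected", ranked.below_p(p_threshold))


def consensus(
    rwr_selected: GeneSet,
    external_selected: GeneSet,
    training: GeneSet,
    combiner: str = "intersection",
) -> PrioritisationResult:
    """Combine the two prioritisations with the training set.

    The default combiner intersects the walk-based and external selections —
    genes nominated by both lines of evidence — and unites the result with
    the training genes. A ``union`` combiner is available.
    """
    if combiner == "intersection":
        combined = rwr_selected.members & external_selected.members
    elif combiner == "union":
        combined = rwr_selected.members | external_selected.members
    else:
        raise ValidationError(f"unknown combiner {combiner!r}")
    return PrioritisationResult(
        rwr_selected=rwr_selected,
        external_selected=external_selected,
        training=training,
        consensus=GeneSet("consensus", combined | training.members),
        combiner=combiner,
    )
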