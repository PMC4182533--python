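"""Synthetic interactome scenarios with planted disease structure.

Every stage of the analysis pipeline consumes one of five external artifacts:
an interactome, training/candidate gene sets, a relatedness ranking, a
differential-expression table and functional annotations. The generator here
fabricates all five with the statistical structure the analysis assumes:

* a scale-free interactome grown by preferential attachment with a
  triad-formation step, so hub-attack fragility and degree-dependent
  clustering — both diagnostic signatures in real protein networks — are
  present in the synthetic input;
* a planted disease module: a randomly chosen node subset densified until its
  internal density reaches a target, emulating the empirical tendency of
  disease proteins to interact among themselves;
* training genes drawn from the module and candidates mixing the remaining
  module genes with off-module decoys;
* a noisy relatedness ranking correlated with module membership (a stand-in
  for a text-mining prioritiser's output);
* a DE table enriched in the module, and functional classes grown by label
  spreading with tunable topological cohesion.

All randomness flows through ``scenario.seed``; identical scenarios produce
identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .types import AnnotationMap, DETable, GeneSet, RankedList, ValidationError

__all__ = [
    "SyntheticScenario",
    "generate_interactome",
    "plant_module",
    "make_training_and_candidates",
    "simulate_relatedness_ranking",
    "simulate_de_table",
    "assign_classes",
    "generate_scenario_artifacts",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study.

    Defaults describe the reference scenario used throughout the test suite:
    a 500-node interactome grown with m=2 attachments per node, a 30-gene
    disease module densified to internal density 0.3, 10 training genes,
    and moderately informative external evidence.
    """

    seed: int = 0
    n_nodes: int = 500
    m: int = 2                      # edges added per new node (preferential attachment)
    triad_probability: float = 0.5  # chance a subsequent link closes a triangle
    module_size: int = 30
    module_density: float = 0.3
    n_training: int = 10
    n_decoys: int = 30              # off-module decoys mixed into the candidate set
    n_classes: int = 8
    class_cohesion: float = 0.9
    de_sensitivity: float = 0.8
    de_background: float = 0.05
    ranking_noise: float = 0.2

    def __post_init__(self):
        if self.module_size > self.n_nodes:
            raise ValidationError("module_size exceeds n_nodes")
        if self.n_training > self.module_size:
            raise ValidationError("n_training exceeds module_size")
        if not 0.0 <= self.module_density <= 1.0:
            raise ValidationError("module_density outside [0, 1]")
        for name in ("de_sensitivity", "de_background", "class_cohesion", "triad_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} outside [0, 1]")
        if self.ranking_noise < 0:
            raise ValidationError("ranking_noise must be >= 0")

    def with_seed(self, seed: int) -> "SyntheticScenario":
        return replace(self, seed=seed)


def _node_name(i: int) -> str:
    return f"g{i:05d}"


def generate_interactome(scenario: SyntheticScenario) -> nx.Graph:
    """Grow a scale-free graph by preferential attachment with triad formation.

    The seed graph is a clique on m+1 nodes; each subsequent node attaches to
    m distinct existing nodes. The first target is drawn with probability
    proportional to degree; each further target is, with probability
    ``triad_probability``, a uniformly chosen neighbour of the previous target
    (closing a triangle), otherwise another degree-proportional draw. The
    result is simple and connected with exactly C(m+1, 2) + m(n - m - 1)
    edges.
    """
    n, m = scenario.n_nodes, scenario.m
    if n < m + 1:
        raise ValidationError(f"n_nodes={n} must be >= m+1={m + 1}")
    rng = np.random.default_rng(scenario.seed)
    net = nx.Graph()
    names = [_node_name(i) for i in range(n)]
    # clique seed keeps the graph connected and gives every node degree >= m
    for i in range(m + 1):
        for j in range(i + 1, m + 1):
            net.add_edge(names[i], names[j])
    # repeated-node list: each entry is one unit of degree
    repeated: list[str] = [names[i] for i in range(m + 1) for _ in range(m)]
    for i in range(m + 1, n):
        new = names[i]
        targets: list[str] = []
        prev: str | None = None
        while len(targets) < m:
            candidate = None
            if prev is not None and rng.random() < scenario.triad_probability:
                neigh = [x for x in net.neighbors(prev) if x != new and x not in targets]
                if neigh:
                    candidate = neigh[int(rng.integers(len(neigh)))]
            if candidate is None:
                candidate = repeated[int(rng.integers(len(repeated)))]
                if candidate in targets:
                    continue
            targets.append(candidate)
            prev = candidate
        for t in targets:
            net.add_edge(new, t)
            repeated.append(t)
        repeated.extend([new] * m)
    return net


def plant_module(
    net: nx.Graph, scenario: SyntheticScenario
) -> tuple[nx.Graph, GeneSet]:
    """Densify a random node subset into a disease module.

    Edges are added uniformly at random among the chosen nodes until their
    internal density reaches ``module_density``. Returns the augmented graph
    (a copy) and the module member set.
    """
    if scenario.module_size < 2:
        raise ValidationError("module_size must be >= 2 to define a density")
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    nodes = sorted(net.nodes())
    members = sorted(rng.choice(len(nodes), size=scenario.module_size, replace=False))
    module = [nodes[i] for i in members]
    net = net.copy()
    k = len(module)
    possible = [(module[i], module[j]) for i in range(k) for j in range(i + 1, k)]
    target = int(np.ceil(scenario.module_density * len(possible)))
    missing = [e for e in possible if not net.has_edge(*e)]
    have = len(possible) - len(missing)
    if have < target:
        picks = rng.choice(len(missing), size=target - have, replace=False)
        for idx in sorted(int(i) for i in picks):
            net.add_edge(*missing[idx])
    return net, GeneSet("module", module)


def make_training_and_candidates(
    net: nx.Graph, module: GeneSet, scenario: SyntheticScenario
) -> tuple[GeneSet, GeneSet]:
    """Split the module into training genes and candidates plus decoys.

    Training genes model literature-verified disease genes (walk seeds);
    candidates are the remaining module genes diluted with ``n_decoys``
    off-module decoys, emulating a GWAS-nominated candidate list. The two
    sets are disjoint.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 2]))
    members = sorted(module.members)
    perm = rng.permutation(len(members))
    training = [members[i] for i in perm[: scenario.n_training]]
    unseen = [members[i] for i in perm[scenario.n_training:]]
    off_module = sorted(set(net.nodes()) - module.members)
    n_decoys = min(scenario.n_decoys, len(off_module))
    decoy_idx = rng.choice(len(off_module), size=n_decoys, replace=False)
    decoys = [off_module[int(i)] for i in decoy_idx]
    return GeneSet("training", training), GeneSet("candidates", unseen + decoys)


def simulate_relatedness_ranking(
    net: nx.Graph, module: GeneSet, scenario: SyntheticScenario
) -> RankedList:
    """Noisy gene ranking correlated with module membership.

    Score = 1[gene in module] + Gaussian noise with sd ``ranking_noise``;
    p-values are the rank transform p = rank / N over descending scores, so
    module genes receive low p on average. Stands in for an externally
    produced relatedness ranking.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 3]))
    nodes = sorted(net.nodes())
    scores = np.array([1.0 if g in module.members else 0.0 for g in nodes])
    scores = scores + rng.normal(0.0, scenario.ranking_noise, size=len(nodes))
    order = sorted(range(len(nodes)), key=lambda i: (-scores[i], nodes[i]))
    n = len(nodes)
    entries = [(nodes[i], float(scores[i]), (rank + 1) / n) for rank, i in enumerate(order)]
    return RankedList(entries)


def simulate_de_table(
    net: nx.Graph, module: GeneSet, scenario: SyntheticScenario
) -> DETable:
    """Differential-expression calls enriched in the module.

    A gene is declared DE (adjusted p drawn uniform on [0, 0.05)) with
    probability ``de_sensitivity`` inside the module and ``de_background``
    outside; non-DE genes draw p uniform on [0.05, 1].
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 4]))
    rows = {}
    for g in sorted(net.nodes()):
        rate = scenario.de_sensitivity if g in module.members else scenario.de_background
        if rng.random() < rate:
            rows[g] = float(rng.uniform(0.0, 0.05))
        else:
            rows[g] = float(rng.uniform(0.05, 1.0))
    return DETable(rows)


def assign_classes(net: nx.Graph, scenario: SyntheticScenario) -> AnnotationMap:
    """Partition nodes into functional classes with tunable cohesion.

    One seed node per class is chosen; labels spread outward in breadth-first
    order. When a node is first reached from a labelled neighbour it adopts
    that label with probability ``class_cohesion``, otherwise (and for nodes
    never reached) a uniformly random label. Cohesion 0 therefore yields a
    uniformly random labelling; cohesion near 1 yields topologically
    segregated classes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 5]))
    nodes = sorted(net.nodes())
    k = scenario.n_classes
    if k < 1 or k > len(nodes):
        raise ValidationError("n_classes must be in [1, n_nodes]")
    names = [f"class{c:02d}" for c in range(k)]
    label: dict[str, int] = {}
    seed_idx = rng.choice(len(nodes), size=k, replace=False)
    frontier: list[str] = []
    for c, i in enumerate(seed_idx):
        label[nodes[int(i)]] = c
        frontier.append(nodes[int(i)])
    # multi-source BFS label spreading
    while frontier:
        nxt: list[str] = []
        for u in frontier:
            for v in sorted(net.neighbors(u)):
                if v in label:
                    continue
                if rng.random() < scenario.class_cohesion:
                    label[v] = label[u]
                else:
                    label[v] = int(rng.integers(k))
                nxt.append(v)
        frontier = nxt
    for g in nodes:
        if g not in label:
            label[g] = int(rng.integers(k))
    classes: dict[str, set[str]] = {name: set() for name in names}
    for g, c in label.items():
        classes[names[c]].add(g)
    return AnnotationMap({n: m for n, m in classes.items() if m})


def generate_scenario_artifacts(scenario: SyntheticScenario) -> dict:
    """Run the whole generator: interactome, module, gene sets, ranking, DE, classes."""
    base = generate_interactome(scenario)
    net, module = plant_module(base, scenario)
    training, candidates = make_training_and_candidates(net, module, scenario)
    ranking = simulate_relatedness_ranking(net, module, scenario)
    de = simulate_de_table(net, module, scenario)
    annotations = assign_classes(net, scenario)
    return {
        "network": net,
        "module": module,
        "training": training,
        "candidates": candidates,
        "ranking": ranking,
        "de_table": de,
        "annotations": annotations,
    }
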