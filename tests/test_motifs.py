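"""Motif census, canonical IDs, switching null and participation counts."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import oracle_census, random_graph
from crohnet import (
    GeneSet,
    ValidationError,
    canonical_id,
    enumerate_subgraphs,
    motif_participation,
    motif_zscores,
    switch_randomize,
)


def test_canonical_id_anchor_values():
    """Decimal IDs of the decodable anchor subgraphs: path/triangle/clique."""
    assert canonical_id([[0, 1, 0], [1, 0, 1], [0, 1, 0]]) == 78
    assert canonical_id([[0, 1, 1], [1, 0, 1], [1, 1, 0]]) == 238
    k4 = [[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]]
    assert canonical_id(k4) == 31710
    # 4-star (one node linked to the other three)
    star = [[0, 1, 1, 1], [1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0]]
    assert canonical_id(star) == 4382


def test_canonical_id_permutation_invariant():
    rng = np.random.default_rng(0)
    base = np.array([[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]])
    ref = canonical_id(base)
    for _ in range(10):
        perm = rng.permutation(4)
        assert canonical_id(base[np.ix_(perm, perm)]) == ref


def test_canonical_id_rejects_invalid_matrices():
    with pytest.raises(ValidationError):
        canonical_id([[0, 1], [0, 0]])  # asymmetric
    with pytest.raises(ValidationError):
        canonical_id([[1, 0], [0, 0]])  # self-loop


def test_census_closed_cases():
    tri = nx.relabel_nodes(nx.complete_graph(3), str)
    assert enumerate_subgraphs(tri, 3) == {238: 1}
    c4 = nx.relabel_nodes(nx.cycle_graph(4), str)
    census = enumerate_subgraphs(c4, 4)
    assert sum(census.values()) == 1  # exactly one connected 4-subgraph: the cycle itself
    (cid,) = census
    assert cid == canonical_id(nx.to_numpy_array(nx.cycle_graph(4), dtype=int))
    with pytest.raises(ValidationError):
        enumerate_subgraphs(tri, 5)


@pytest.mark.parametrize("k", [3, 4])
def test_census_equals_combinations_oracle(k):
    """ESU census matches brute-force over all node combinations (30 graphs)."""
    for seed in range(30):
        n = 15 + seed % 11  # 15..25 nodes
        net = random_graph(n, 0.18, seed=seed)
        assert enumerate_subgraphs(net, k) == oracle_census(net, k)


def test_census_keys_invariant_to_relabelling():
    net = random_graph(18, 0.2, seed=2)
    relabelled = nx.relabel_nodes(net, {n: f"zz{n}" for n in net.nodes()})
    assert enumerate_subgraphs(net, 4) == enumerate_subgraphs(relabelled, 4)


def test_switch_randomize_preserves_degree_sequence():
    for seed in range(10):
        net = random_graph(40, 0.1, seed=seed)
        shuffled = switch_randomize(net, swaps_per_edge=10, seed=seed)
        assert dict(shuffled.degree()) == dict(net.degree())
        assert shuffled.number_of_edges() == net.number_of_edges()
        assert nx.number_of_selfloops(shuffled) == 0


def test_switch_randomize_triangle_unchanged():
    tri = nx.relabel_nodes(nx.complete_graph(3), str)
    out = switch_randomize(tri, swaps_per_edge=10, seed=0)
    assert set(map(frozenset, out.edges())) == set(map(frozenset, tri.edges()))


def test_switch_randomize_shuffles_edges_with_high_probability():
    changed = 0
    for seed in range(5):
        net = random_graph(100, 0.04, seed=seed)
        out = switch_randomize(net, swaps_per_edge=10, seed=seed)
        if set(map(frozenset, out.edges())) != set(map(frozenset, net.edges())):
            changed += 1
    assert changed == 5


def test_zscores_self_null_and_planted_triangles():
    # a graph compared against its own degree-preserving null: no extreme z
    g = random_graph(60, 0.07, seed=5)
    census = motif_zscores(g, 3, n_random=30, seed=1)
    for cid, s in census.classes.items():
        assert abs(s.z_score) < 3, cid
    # planting 50 triangles into an ER graph makes the triangle a motif
    rng = np.random.default_rng(2)
    h = random_graph(100, 0.03, seed=2)
    nodes = sorted(h.nodes())
    for _ in range(50):
        a, b, c = (nodes[int(i)] for i in rng.choice(len(nodes), size=3, replace=False))
        h.add_edges_from([(a, b), (b, c), (a, c)])
    census = motif_zscores(h, 3, n_random=30, seed=3)
    assert census.classes[238].z_score >= 2
    assert 238 in census.motif_ids()


def test_zscores_deterministic_under_seed():
    net = random_graph(40, 0.1, seed=8)
    a = motif_zscores(net, 3, n_random=10, seed=4)
    b = motif_zscores(net, 3, n_random=10, seed=4)
    assert a.classes == b.classes


def test_participation_double_counting_identity():
    """Summed participation over all nodes = k x number of counted instances."""
    net = random_graph(25, 0.18, seed=6)
    census = motif_zscores(net, 3, n_random=10, seed=0)
    part = motif_participation(net, census, include_all_classes=True)
    total_instances = sum(enumerate_subgraphs(net, 3).values())
    assert sum(part.values()) == 3 * total_instances


def test_participation_hub_of_planted_stars_ranks_first():
    # hub wired to many leaves: the 3-path class contains the hub most often
    net = nx.Graph()
    net.add_edges_from([("hub", f"leaf{i}") for i in range(8)])
    net.add_edges_from([("a", "b"), ("b", "c")])
    census = motif_zscores(net, 3, n_random=5, seed=0)
    part = motif_participation(net, census, include_all_classes=True)
    assert next(iter(part)) == "hub"
    # gene absent from every instance scores zero
    net.add_edge("x", "y")
    census = motif_zscores(net, 3, n_random=5, seed=0)
    part = motif_participation(net, census, genes=GeneSet("q", ["x"]), include_all_classes=True)
    assert part == {"x": 0}
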