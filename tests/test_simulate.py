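"""Synthetic scenario generator: interactome, module, evidence layers."""

import networkx as nx
import numpy as np
import pytest

from conftest import auroc
from crohnet import (
    SyntheticScenario,
    ValidationError,
    assign_classes,
    generate_interactome,
    make_training_and_candidates,
    plant_module,
    segregation_index,
    simulate_de_table,
    simulate_relatedness_ranking,
)


def test_interactome_edge_count_follows_attachment_rule():
    """Clique seed of m+1 nodes plus m links per later node: C(m+1,2)+m(n-m-1)."""
    for n, m in [(100, 2), (50, 3), (20, 1)]:
        net = generate_interactome(SyntheticScenario(seed=1, n_nodes=n, m=m, module_size=5, n_training=2))
        expected = m * (m + 1) // 2 + m * (n - m - 1)
        assert net.number_of_edges() == expected
        assert net.number_of_nodes() == n
        assert nx.is_connected(net)
        assert nx.number_of_selfloops(net) == 0


def test_interactome_deterministic_under_seed():
    sc = SyntheticScenario(seed=7, n_nodes=200, m=2)
    a, b = generate_interactome(sc), generate_interactome(sc)
    assert set(a.edges()) == set(b.edges())
    c = generate_interactome(sc.with_seed(8))
    assert set(a.edges()) != set(c.edges())


def test_interactome_degree_distribution_heavy_tail():
    """Preferential attachment yields hubs: max degree >> mean degree."""
    for seed in range(10):
        net = generate_interactome(
            SyntheticScenario(seed=seed, n_nodes=5000, m=3, module_size=5, n_training=2)
        )
        degrees = np.array([d for _, d in net.degree()])
        assert degrees.max() > 10 * degrees.mean()


def test_interactome_infeasible_parameters():
    with pytest.raises(ValidationError):
        generate_interactome(SyntheticScenario(seed=0, n_nodes=2, m=2, module_size=2, n_training=1))


def test_plant_module_reaches_density():
    sc = SyntheticScenario(seed=3, n_nodes=500, module_size=30, module_density=0.3)
    net, module = plant_module(generate_interactome(sc), sc)
    members = sorted(module.members)
    internal = sum(
        1
        for i, u in enumerate(members)
        for v in members[i + 1 :]
        if net.has_edge(u, v)
    )
    assert internal >= int(np.ceil(0.3 * 30 * 29 / 2))


def test_plant_module_full_density_is_clique():
    sc = SyntheticScenario(seed=0, n_nodes=100, module_size=10, module_density=1.0, n_training=5)
    net, module = plant_module(generate_interactome(sc), sc)
    sub = net.subgraph(module.members)
    assert sub.number_of_edges() == 45


def test_plant_module_no_edges_added_when_target_met():
    sc = SyntheticScenario(seed=0, n_nodes=100, module_size=10, module_density=0.0, n_training=5)
    base = generate_interactome(sc)
    net, _ = plant_module(base, sc)
    assert net.number_of_edges() == base.number_of_edges()


def test_global_density_stays_close_to_background():
    """A small planted module barely perturbs the global density."""
    sc = SyntheticScenario(seed=5)
    base = generate_interactome(sc)
    net, _ = plant_module(base, sc)
    d0 = 2 * base.number_of_edges() / (500 * 499)
    d1 = 2 * net.number_of_edges() / (500 * 499)
    assert d1 <= 1.5 * d0


def test_training_candidates_disjoint_and_counted():
    sc = SyntheticScenario(seed=2)
    net, module = plant_module(generate_interactome(sc), sc)
    training, candidates = make_training_and_candidates(net, module, sc)
    assert not (training.members & candidates.members)
    assert training.members <= module.members
    assert len(training) == sc.n_training
    n_unseen = len(module.members - training.members)
    assert abs(len(candidates) - (n_unseen + sc.n_decoys)) <= 1


def test_ranking_noise_free_separates_module():
    sc = SyntheticScenario(seed=4, ranking_noise=0.0)
    net, module = plant_module(generate_interactome(sc), sc)
    ranking = simulate_relatedness_ranking(net, module, sc)
    ids = ranking.identifiers()
    assert set(ids[: len(module)]) == module.members
    # rank-transform p-values are uniform on {1/N, ..., 1}
    ps = sorted(p for _, _, p in ranking.entries)
    n = len(ps)
    assert ps == pytest.approx([(i + 1) / n for i in range(n)])


def test_ranking_auroc_under_noise():
    """Scores at sd 0.2 still separate module from background (AUROC >= 0.9)."""
    scores = []
    for seed in range(10):
        sc = SyntheticScenario(seed=seed, ranking_noise=0.2)
        net, module = plant_module(generate_interactome(sc), sc)
        ranking = simulate_relatedness_ranking(net, module, sc)
        labels = [g in module.members for g, _, _ in ranking.entries]
        scores.append(auroc([s for _, s, _ in ranking.entries], labels))
    assert np.median(scores) >= 0.9


def test_de_table_extremes_and_rates():
    sc = SyntheticScenario(seed=6, de_sensitivity=1.0, de_background=0.0)
    net, module = plant_module(generate_interactome(sc), sc)
    table = simulate_de_table(net, module, sc)
    assert table.significant(0.05) == set(module.members)
    assert all(0.0 <= p <= 1.0 for p in table.rows.values())

    sc2 = SyntheticScenario(seed=6, de_sensitivity=0.8, de_background=0.05)
    table2 = simulate_de_table(net, module, sc2)
    n_mod, n_bg = 30, 470
    expected = 0.8 * n_mod + 0.05 * n_bg
    sd = np.sqrt(0.8 * 0.2 * n_mod + 0.05 * 0.95 * n_bg)
    assert abs(len(table2.significant(0.05)) - expected) <= 3 * sd


def test_assign_classes_partition_and_cohesion_limits():
    sc = SyntheticScenario(seed=8, class_cohesion=0.0)
    net = generate_interactome(sc)
    ann = assign_classes(net, sc)
    total = sum(len(m) for _, m in ann.items())
    assert total == net.number_of_nodes()  # exclusive labels partition N
    union = set()
    for _, m in ann.items():
        assert not (union & m)
        union |= m

    # cohesion 0.9 gives topologically segregated classes
    for seed in range(10):
        sc = SyntheticScenario(seed=seed, class_cohesion=0.9)
        net = generate_interactome(sc)
        ann = assign_classes(net, sc)
        for name, members in ann.items():
            if len(members) >= 10:
                assert segregation_index(net, set(members), name).index > 1


def test_scenario_validation():
    with pytest.raises(ValidationError):
        SyntheticScenario(module_size=600)
    with pytest.raises(ValidationError):
        SyntheticScenario(n_training=40, module_size=30)
    with pytest.raises(ValidationError):
        SyntheticScenario(ranking_noise=-1)
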