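"""Exact enrichment tests against exhaustive-enumeration oracles."""

import itertools
from math import comb

import networkx as nx
import numpy as np
import pytest

from conftest import random_graph
from crohnet import (
    AnnotationMap,
    DETable,
    GeneSet,
    SyntheticScenario,
    ValidationError,
    category_overrep,
    de_enrichment,
    fisher_exact_2x2,
    generate_scenario_artifacts,
    hub_neighbour_test,
    hub_overrep,
    hypergeom_overrep,
    identify_hubs,
)


# ---------------------------------------------------------------- oracles --


def hypergeom_upper_tail(pop, succ, n, observed):
    """P(X >= observed) by direct combinatorial summation."""
    total = comb(pop, n)
    return sum(
        comb(succ, k) * comb(pop - succ, n - k)
        for k in range(observed, min(n, succ) + 1)
    ) / total


def fisher_two_sided(a, b, c, d):
    """Sum of probabilities of tables (fixed marginals) no more likely than observed."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            comb(row1, x) * comb(n - row1, col1 - x) / comb(n, col1)
        )

    p_obs = prob(a)
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def binom_upper_tail(n, p, observed):
    return sum(comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(observed, n + 1))


# ------------------------------------------------------------------ tests --


def test_identify_hubs_rules():
    regular = nx.relabel_nodes(nx.cycle_graph(6), str)
    assert identify_hubs(regular).members == frozenset()
    star = nx.relabel_nodes(nx.star_graph(9), str)  # mean degree 1.8
    assert identify_hubs(star).members == {"0"}
    for seed in range(5):
        net = random_graph(30, 0.1, seed=seed)
        mean_deg = np.mean([d for _, d in net.degree()])
        expected = {n for n, d in net.degree() if d > mean_deg}
        assert identify_hubs(net).members == expected


def test_hypergeom_worked_value_and_oracle():
    """pop=10, successes=4, sample=5, observed=4 -> 6/252."""
    res = hypergeom_overrep(10, 4, 5, 4)
    assert res.p_value == pytest.approx(6 / 252)
    rng = np.random.default_rng(1)
    for _ in range(50):
        pop = int(rng.integers(5, 21))
        succ = int(rng.integers(1, pop + 1))
        n = int(rng.integers(1, pop + 1))
        obs = int(rng.integers(0, min(n, succ) + 1))
        res = hypergeom_overrep(pop, succ, n, obs)
        assert res.p_value == pytest.approx(hypergeom_upper_tail(pop, succ, n, obs))
    assert hypergeom_overrep(10, 4, 5, 0).p_value == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        hypergeom_overrep(10, 4, 5, 5)


def test_fisher_worked_values_and_oracle():
    assert fisher_exact_2x2([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)
    assert fisher_exact_2x2([[5, 0], [0, 5]]).p_value == pytest.approx(2 / 252)
    rng = np.random.default_rng(2)
    for _ in range(60):
        cells = rng.multinomial(int(rng.integers(4, 41)), [0.25] * 4)
        a, b, c, d = (int(x) for x in cells)
        res = fisher_exact_2x2([[a, b], [c, d]])
        assert res.p_value == pytest.approx(fisher_two_sided(a, b, c, d), rel=1e-9)
    one_sided = fisher_exact_2x2([[5, 0], [0, 5]], alternative="greater")
    assert one_sided.p_value == pytest.approx(1 / 252)


def test_binomial_worked_value_and_bonferroni():
    """n=10, class fraction 0.1, observed 5 -> upper-tail p ~ 1.47e-3, times m tests."""
    universe = [f"g{i}" for i in range(100)]
    ann = AnnotationMap(
        {"target": universe[:10], "filler1": universe[10:60], "filler2": universe[40:100]}
    )
    ref = GeneSet("ref", universe)
    study = GeneSet("s", universe[:5] + ["g98", "g99", "g60", "g61", "g62"])
    results = {r.name: r for r in category_overrep(study, ann, ref, min_size=5)}
    target = results["target"]
    assert target.counts["observed"] == 5 and target.counts["study_size"] == 10
    expected = binom_upper_tail(10, 0.1, 5)  # = 1.6349e-3 by direct summation
    assert target.p_value == pytest.approx(expected, rel=1e-9)
    assert target.adjusted_p == pytest.approx(min(1.0, 3 * expected))
    assert target.counts["n_tested"] == 3


def test_category_covering_reference_is_not_enriched():
    universe = [f"g{i}" for i in range(50)]
    ann = AnnotationMap({"everything": universe})
    res = category_overrep(GeneSet("s", universe[:10]), ann, GeneSet("ref", universe))
    assert res[0].p_value == pytest.approx(1.0)


def test_category_type_one_error_near_nominal():
    """Uniform draws from the reference reject at ~ the nominal 5% rate."""
    rng = np.random.default_rng(7)
    universe = [f"g{i}" for i in range(1000)]
    perm = list(rng.permutation(universe))
    ann = AnnotationMap({f"c{j}": perm[j * 200 : (j + 1) * 200] for j in range(5)})
    ref = GeneSet("ref", universe)
    rates = []
    for _ in range(100):
        genes = GeneSet("s", rng.choice(universe, size=200, replace=False))
        res = category_overrep(genes, ann, ref, min_size=5)
        rates.append(np.mean([r.p_value < 0.05 for r in res]))
    assert 0.02 <= np.mean(rates) <= 0.08


def test_de_enrichment_table_and_power():
    # extreme table: prioritised subset exactly the DE set
    universe = GeneSet("u", [f"g{i}" for i in range(40)])
    de = DETable({f"g{i}": 0.01 if i < 10 else 0.5 for i in range(40)})
    pri = GeneSet("p", [f"g{i}" for i in range(10)])
    res = de_enrichment(pri, de, universe)
    assert res.counts["prioritised_de"] == 10
    assert res.counts["other_not_de"] == 30
    assert res.p_value == pytest.approx(fisher_two_sided(10, 0, 0, 30), rel=1e-9)
    # synthetic scenario: module enriched in DE calls in >= 9/10 seeds
    hits = 0
    for seed in range(10):
        art = generate_scenario_artifacts(SyntheticScenario(seed=seed))
        res = de_enrichment(
            art["module"], art["de_table"], GeneSet("u", art["network"].nodes())
        )
        if res.p_value < 0.05:
            hits += 1
    assert hits >= 9


def test_hub_overrep_counts_against_proteome():
    art = generate_scenario_artifacts(SyntheticScenario(seed=1))
    net = art["network"]
    hubs = identify_hubs(net)
    res = hub_overrep(art["module"], net)
    assert res.counts["pop_size"] == net.number_of_nodes()
    assert res.counts["pop_successes"] == len(hubs)
    assert res.counts["sample_successes"] == len(art["module"].members & hubs.members)


def test_hub_neighbour_test_fixture():
    # focal node wired to every hub of a star-of-stars proteome: tiny p
    net = nx.Graph()
    for h in ("h1", "h2", "h3"):
        for i in range(6):
            net.add_edge(h, f"{h}_leaf{i}")
    net.add_edges_from([("focal", "h1"), ("focal", "h2"), ("focal", "h3")])
    hubs = identify_hubs(net)
    assert hubs.members == {"h1", "h2", "h3", "focal"}  # mean degree < 3
    res = hub_neighbour_test(net, "focal")
    a = res.counts["neighbour_hubs"]
    assert a == 3
    oracle = fisher_two_sided(
        res.counts["neighbour_hubs"],
        res.counts["neighbour_non_hubs"],
        res.counts["other_hubs"],
        res.counts["other_non_hubs"],
    )
    assert res.p_value == pytest.approx(oracle, rel=1e-9)
    assert res.p_value < 0.05
    # marginal: hub column = |hubs| minus the focal node itself
    assert res.counts["neighbour_hubs"] + res.counts["other_hubs"] == len(hubs) - 1
    with pytest.raises(ValidationError):
        hub_neighbour_test(net, "missing")
    net.add_node("lonely")
    with pytest.raises(ValidationError):
        hub_neighbour_test(net, "lonely")


def test_adjusted_p_never_below_raw():
    res = hypergeom_overrep(20, 5, 10, 3)
    assert res.adjusted_p >= res.p_value
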