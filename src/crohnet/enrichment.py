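"""Enrichment statistics: hubs, DE genes and functional categories.

Hubs are nodes whose degree strictly exceeds the network's mean degree.
Hub over-representation in a gene list uses the upper-tail hypergeometric
test; enrichment of differentially expressed genes in the prioritised list
uses Fisher's exact test on the 2x2 partition of the measured universe; and
functional-category over-representation against a reference list uses the
upper-tail binomial test with Bonferroni correction across tested classes.
Every result carries its full contingency counts for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
from scipy import stats

from .types import AnnotationMap, DETable, GeneSet, ValidationError

__all__ = [
    "EnrichmentResult",
    "identify_hubs",
    "hypergeom_overrep",
    "fisher_exact_2x2",
    "de_enrichment",
    "hub_overrep",
    "hub_neighbour_test",
    "category_overrep",
]


@dataclass(frozen=True)
class EnrichmentResult:
    test: str
    counts: Mapping[str, int]
    p_value: float
    adjusted_p: float
    adjustment: str = "none"
    direction: str = "over"
    name: str = ""
    extra: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value outside [0, 1]")
        if self.adjusted_p < self.p_value - 1e-12:
            raise ValidationError("adjusted p smaller than raw p")


def identify_hubs(net: nx.Graph) -> GeneSet:
    """Nodes with degree strictly greater than the network's mean degree."""
    if net.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    degrees = dict(net.degree())
    mean_deg = float(np.mean(list(degrees.values())))
    return GeneSet("hubs", [n for n, d in degrees.items() if d > mean_deg])


def hypergeom_overrep(
    pop_size: int, pop_successes: int, sample_size: int, sample_successes: int
) -> EnrichmentResult:
    """Upper-tail hypergeometric p: P(X >= observed) for a draw without replacement."""
    if not (
        0 <= pop_successes <= pop_size
        and 0 <= sample_size <= pop_size
        and 0 <= sample_successes <= min(sample_size, pop_successes)
    ):
        raise ValidationError("inconsistent hypergeometric counts")
    p = float(stats.hypergeom.sf(sample_successes - 1, pop_size, pop_successes, sample_size))
    p = min(1.0, p)
    return EnrichmentResult(
        test="hypergeometric",
        counts={
            "pop_size": pop_size,
            "pop_successes": pop_successes,
            "sample_size": sample_size,
            "sample_successes": sample_successes,
        },
        p_value=p,
        adjusted_p=p,
    )


def fisher_exact_2x2(table, alternative: str = "two-sided") -> EnrichmentResult:
    """Fisher's exact test on a 2x2 table.

    Two-sided p sums the probabilities of all tables with the observed
    marginals that are no more probable than the observed one; one-sided
    alternatives ('greater', 'less') are available for directional claims.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("table must be 2x2 with non-negative counts")
    res = stats.fisher_exact(t, alternative=alternative)
    p = float(min(1.0, res.pvalue))
    a, b, c, d = int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])
    expected = (a + b) * (a + c) / max(1, a + b + c + d)
    return EnrichmentResult(
        test=f"fisher_{alternative}",
        counts={"a": a, "b": b, "c": c, "d": d},
        p_value=p,
        adjusted_p=p,
        direction="over" if a >= expected else "under",
        extra={"odds_ratio": float(res.statistic)},
    )


def de_enrichment(
    prioritised: GeneSet,
    de: DETable,
    universe: GeneSet,
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Fisher test of DE-gene enrichment among prioritised genes.

    The universe (measured genes) is partitioned by prioritised membership
    and by DE call (adjusted p < alpha); the resulting 2x2 table goes through
    :func:`fisher_exact_2x2`.
    """
    uni = set(universe.members)
    if not uni:
        raise ValidationError("empty universe")
    de_set = de.significant(alpha) & uni
    pri = prioritised.members & uni
    a = len(pri & de_set)
    b = len(pri - de_set)
    c = len(de_set - pri)
    d = len(uni - pri - de_set)
    result = fisher_exact_2x2([[a, b], [c, d]], alternative=alternative)
    return EnrichmentResult(
        test="de_enrichment_fisher",
        counts={
            "prioritised_de": a,
            "prioritised_not_de": b,
            "other_de": c,
            "other_not_de": d,
        },
        p_value=result.p_value,
        adjusted_p=result.p_value,
        direction=result.direction,
        extra=result.extra,
    )


def hub_overrep(genes: GeneSet, proteome: nx.Graph) -> EnrichmentResult:
    """Hypergeometric over-representation of proteome hubs in a gene list.

    Degrees (and hence hub status) are measured on the full proteome; the
    sample is the gene list restricted to proteome nodes.
    """
    hubs = identify_hubs(proteome).members
    nodes = set(proteome.nodes())
    sample = genes.members & nodes
    return hypergeom_overrep(
        pop_size=len(nodes),
        pop_successes=len(hubs),
        sample_size=len(sample),
        sample_successes=len(sample & hubs),
    )


def hub_neighbour_test(
    net: nx.Graph,
    protein: str,
    hubs: GeneSet | None = None,
    proteome: nx.Graph | None = None,
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Fisher test: are a protein's first neighbours enriched in proteome hubs?

    The 2x2 table crosses neighbour/non-neighbour with hub/non-hub over the
    proteome nodes, the focal protein excluded. Hub status defaults to the
    strictly-above-mean-degree rule on the proteome.
    """
    proteome = proteome if proteome is not None else net
    if protein not in net:
        raise ValidationError(f"{protein!r} not in the network")
    neighbours = set(net.neighbors(protein)) - {protein}
    if not neighbours:
        raise ValidationError(f"{protein!r} has no neighbours")
    hub_set = (hubs or identify_hubs(proteome)).members - {protein}
    others = set(proteome.nodes()) - {protein}
    neighbours &= others
    a = len(neighbours & hub_set)
    b = len(neighbours - hub_set)
    c = len(hub_set - neighbours)
    d = len(others - neighbours - hub_set)
    res = fisher_exact_2x2([[a, b], [c, d]], alternative=alternative)
    return EnrichmentResult(
        test="hub_neighbour_fisher",
        counts={
            "neighbour_hubs": a,
            "neighbour_non_hubs": b,
            "other_hubs": c,
            "other_non_hubs": d,
        },
        p_value=res.p_value,
        adjusted_p=res.p_value,
        direction=res.direction,
        extra=res.extra,
    )


def category_overrep(
    genes: GeneSet,
    annotations: AnnotationMap,
    reference: GeneSet,
    min_size: int = 5,
    significance: float = 0.05,
) -> list[EnrichmentResult]:
    """Binomial over-representation of annotation classes with Bonferroni correction.

    Per class with at least ``min_size`` annotated genes in the reference:
    upper-tail binomial p with success probability the class's share of the
    reference and n the number of study genes in the annotated universe.
    Genes outside the reference are dropped with a warning-free filter
    (callers see the counts). Bonferroni multiplies by the number of classes
    tested.
    """
    ref = set(reference.members)
    if not ref:
        raise ValidationError("empty reference list")
    annotated_universe = annotations.genes() & ref
    study = genes.members & annotated_universe
    tested: list[tuple[str, int, int]] = []
    for name in sorted(annotations.classes):
        members = annotations[name] & ref
        if len(members) >= min_size:
            tested.append((name, len(members), len(study & members)))
    m = len(tested)
    n = len(study)
    results = []
    for name, class_size, observed in tested:
        frac = class_size / len(ref)
        p = float(stats.binom.sf(observed - 1, n, frac)) if n > 0 else 1.0
        p = min(1.0, p)
        adj = min(1.0, m * p)
        results.append(
            EnrichmentResult(
                test="binomial_category",
                counts={
                    "class_size": class_size,
                    "observed": observed,
                    "study_size": n,
                    "reference_size": len(ref),
                    "n_tested": m,
                },
                p_value=p,
                adjusted_p=adj,
                adjustment="bonferroni",
                direction="over" if observed >= n * frac else "under",
                name=name,
                extra={"class_fraction": frac, "significant": float(adj < significance)},
            )
        )
    results.sort(key=lambda r: (r.adjusted_p, r.name))
    return results
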