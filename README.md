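# crohnet

Network-based prioritisation and topological analysis of disease
susceptibility genes.

Genome-wide association studies nominate hundreds of candidate genes for
complex diseases such as Crohn's, but give little guidance on which of them
act together. `crohnet` implements the graph-theoretic workflow that turns a
candidate list into a characterised disease network: genes proximal to known
disease genes on the protein–protein interaction network are prioritised by
diffusion, the interactions around them form a disease sub-network, and that
sub-network is interrogated for the structural signatures expected of a real
disease module — elevated density, hub enrichment, motif content, fragility
to hub removal and topological segregation of functional classes.

## The methods

**Prioritisation** is a random walk with restart on the interactome,

    p(t+1) = (1 − r) W p(t) + r e,

with `W` the column-normalised adjacency matrix, `e` uniform over the
training genes (known disease genes) and restart probability `r` (default
0.5). Iteration stops when the L1 change falls below `tol` (default 1e−10);
a direct linear solve of `(I − (1−r)W) p = r e` is provided as an oracle.
The top-ranked candidates are intersected with an externally supplied
relatedness ranking (genes at p < 0.1) and united with the training set to
form the consensus list.

**The disease sub-network** keeps every interaction with at least one
endpoint in the consensus list, so first neighbours are included. It is then
characterised by:

- *topology*: degree-resolved clustering C(k), topological coefficients, and
  whole-graph metrics compared with same-size Erdős–Rényi graphs (z-scores);
- *robustness*: node-removal trajectories (random failure, hub attack,
  low-degree-first, or a supplied gene set) recording surviving interactions
  and secondary extinctions (nodes isolated without being removed);
- *motifs*: an exhaustive census of connected 3- and 4-node induced
  subgraphs keyed by canonical IDs (3-path = id78, triangle = id238, 4-clique
  = id31710), scored against a degree-preserving edge-switching null;
- *segregation*: for a gene class j, the distance-averaged ratio of the
  within-class fraction of each member's distance-d shell to the class's
  global frequency n_j/N — equal to 1 for randomly placed classes;
- *enrichment*: hypergeometric hub over-representation, Fisher tests for
  differential-expression enrichment and hub-rich neighbourhoods, and the
  binomial category over-representation test with Bonferroni correction.

A synthetic-data generator produces scale-free interactomes (preferential
attachment with triad formation) with a planted, densified disease module
and matching evidence layers (training/candidate sets, a noisy relatedness
ranking, a DE table, functional classes with tunable cohesion), so the whole
pipeline runs and is tested without any external downloads.

## Worked example

```python
from crohnet import (SyntheticScenario, generate_scenario_artifacts, rwr,
                     select_by_steady_state, select_external, consensus)

art = generate_scenario_artifacts(SyntheticScenario(seed=0))
vector = rwr(art["network"], art["training"], r=0.5)
walk = select_by_steady_state(vector, art["candidates"], "top_k", 30)
external = select_external(art["ranking"], 0.1)
result = consensus(walk, external, art["training"])
unseen = art["module"].members - art["training"].members
print(len(result.consensus), len(result.consensus.members & unseen), len(unseen))
```

prints `31 20 20`: from 10 training genes the walk plus external evidence
produce a 31-gene consensus list that recovers all 20 unseen members of the
planted 30-gene disease module. The scripts in `examples/` walk through each
capability (simulation, prioritisation, sub-network extraction, motifs,
segregation, robustness/enrichment, full pipeline) and print the numbers
they compute; `examples/03_disease_subnetwork.py` for instance reports a
density ratio of 2.40 for the module's sub-network against the interactome.

The full pipeline is also exposed as a thin CLI:

```
crohnet run --out results/            # simulate → prioritise → … → report
crohnet simulate --seed 1 --out data/ # just the synthetic artifacts
crohnet prioritise --network data/network.tsv --training data/training.txt \
    --candidates data/candidates.txt --external-ranking data/ranking.tsv \
    --rule top_k:30 --out prioritised.txt
```

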