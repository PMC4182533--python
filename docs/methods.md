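# Methods

## Scope and model

The package analyses an undirected, simple interaction graph over opaque
gene identifiers. Self-interactions are dropped on input by default (they
distort degree, clustering and motif statistics); a flag retains them, in
which case they count toward degree but are excluded from clustering and
motif computations. Evidence layers are plain-text artifacts: one-ID-per-line
gene sets, `id/score/p` rankings, GMT annotation files and `id/adjusted-p`
DE tables. No identifier mapping is performed.

## Random walk with restart

The walk iterates `p(t+1) = (1−r) W p(t) + r e` with `W = A D⁻¹`
(column-normalised adjacency: a walker at a node steps to a uniformly chosen
neighbour) and `e` uniform over the training genes present in the network.
Parameters, with defaults and rationale:

- `r = 0.5` — restart probability; balances local neighbourhood against
  global diffusion and is the conventional midpoint when no value is
  dictated by the data. Exposed everywhere.
- `tol = 1e−10` (L1), `max_iter = 10 000` — the spectral radius of
  `(1−r)W` is at most `1−r`, so convergence is geometric and these bounds
  are loose; the `converged` flag records whether the tolerance was met.
- Isolated nodes receive a zero column in `W`; they can only hold mass via
  restart, so with non-isolated training genes probability mass is conserved
  exactly (asserted per iteration in tests).

`rwr_exact` solves `(I − (1−r)W) p = r e` directly and serves as the
independent oracle for the iterative solver.

Candidate selection supports `top_k` (default) and `prob_threshold` rules,
because diffusion tools differ in how they cut the stationary ranking; ties
break lexicographically so selections are deterministic. The consensus
combiner defaults to intersection-with-the-external-selection united with
the training set — the weakest combination consistent with requiring both
lines of evidence — with a `union` mode available and the choice logged in
provenance.

## Disease sub-network

The sub-network keeps every interactome edge with at least one endpoint in
the prioritised list; nodes are flagged `prioritised` or `neighbour`.
Density is `2E/(N(N−1))`; the density ratio divides sub-network density by
interactome density. Components are ordered by size with lexicographic
tie-break, making the giant component deterministic.

## Topology

`C(k)` averages clustering over nodes of degree `k ≥ 2` (degree-<2 nodes
have undefined clustering). The topological coefficient of node n is the
mean over partners m sharing at least one neighbour with n of `J(n,m)/k(n)`,
where `J` counts shared neighbours plus one if n and m are adjacent;
nodes with fewer than two neighbours are omitted. The random-graph
comparison uses `G(N, M)` (fixed edge count) so the ensemble matches the
observed graph in both nodes and edges; mean shortest path and diameter are
computed on the giant component, which is recorded in the report. Default
ensemble size is 100 (configurable); z-scores use the sample standard
deviation and two-sided normal p-values, with σ = 0 reported as undefined.

## Robustness

Nodes are removed in batches of `⌈step_fraction·N⌉` under four strategies.
Degree orderings are static (original degrees, lexicographic tie-break) —
the deterministic baseline — with an adaptive recalculated-degree attack
behind a flag. A secondary extinction is a surviving node whose degree has
fallen to zero; the count is cumulative. Random removal is seeded, and a
mean-curve helper averages trajectories across seeds.

## Motif census

Connected induced subgraphs of size 3 and 4 are enumerated exhaustively with
the ESU scheme (each subgraph visited exactly once); per instance, the edge
bitmask is mapped through a precomputed table to the canonical ID — the
minimum over all node permutations of the row-major bit string of the
symmetric adjacency matrix. This reproduces the decimal convention in which
the 3-path is 78, the triangle 238, the 4-star 4382 and the 4-clique 31710.
The null model performs `swaps_per_edge·E` accepted double-edge swaps
(defaults 10 swaps per edge, 100 replicates), rejecting self-loops and
duplicates; an attempt cap of 100× the target terminates gracefully on
graphs with no valid swap (a triangle returns unchanged). Classes with
`z ≥ 2` are motifs, `z ≤ −2` anti-motifs; a zero-variance class matching its
null mean is neutral. Participation counts, per gene, the instances of
motif-called classes containing it (a flag widens this to all classes, since
conventions differ); summed over all nodes it equals `k` times the instance
count, a double-counting identity asserted in tests.

## Segregation

For class j and member i, `S_i(d)` is the fraction of the distance-d shell
of i (focal node excluded) belonging to j; `⟨S_j(d)⟩` averages over members
with non-empty shells at d, and the index averages `⟨S_j(d)⟩/(n_j/N)` over
`d ∈ [1, d_max]`. Because the baseline `n_j/N` does not depend on d, the
alternative ratio-of-averages aggregation is algebraically identical; both
are exposed for auditability and the per-distance profile is always emitted.
`d_max` defaults to the largest distance at which at least 50% of class
members still have a non-empty shell, which keeps sparsely reachable
distances from dominating the average; it is configurable. Classes need at
least `min_size` members in the network (default 5) to be evaluated. Under
uniformly random labels the expected shell ratio is 1 at every distance, the
calibration asserted by a 100-permutation Monte-Carlo test.

## Enrichment

Hubs are nodes with degree strictly above the mean degree; for questions
about a sub-network's genes, degree is measured on the full interactome
(the comparison pool is the proteome hub set). Hub over-representation is
the upper-tail hypergeometric probability; DE enrichment builds the 2×2
partition of the measured universe by prioritised membership and DE call
(adjusted p < 0.05 by default) and applies Fisher's exact test (two-sided =
sum of no-more-probable tables; one-sided available); the hub-neighbour test
crosses neighbour status with hub status over the proteome with the focal
node excluded. Category over-representation uses the upper-tail binomial
with success probability the class's share of the reference list and n the
study genes in the annotated universe, Bonferroni-corrected over tested
classes (those with ≥ `min_size` reference members). scipy.stats supplies
the distributions; the test suite checks every exact test against
independent exhaustive-enumeration oracles. Because study genes are drawn
without replacement while the binomial assumes independence, the category
test is mildly conservative — its measured type-I rate sits just below the
nominal 5% in the calibration test.

## Synthetic scenarios

The generator grows the interactome by preferential attachment from an
(m+1)-clique seed; each new node makes `m` links, the first by a
degree-proportional draw and subsequent ones, with probability
`triad_probability` (default 0.5), to a random neighbour of the previous
target, closing a triangle. This yields exactly `C(m+1,2) + m(n−m−1)` edges,
a connected simple graph, heavy-tailed degrees and degree-dependent
clustering — the features (hub fragility, hierarchical C(k)) the analysis
is designed to detect, which a uniform random graph would not provide. The
disease module is a random node subset densified with uniform internal edges
until its density reaches `module_density`; defaults (n = 500, m = 2,
module 30 at density 0.3, 10 training genes, 30 decoy candidates) give a
module whose sub-network is roughly three times denser than background, a
realistic contrast for a disease module. The relatedness ranking scores
`1[module] + N(0, 0.2)` with rank-transform p-values (the pipeline consumes
only thresholded ranks, so model-based p-values would add nothing); the DE
table draws significant p-values (uniform on [0, 0.05)) with probability 0.8
inside the module and 0.05 outside; functional classes spread labels
outward from seed nodes by breadth-first adoption with probability
`class_cohesion`, falling back to random labels, so cohesion 0 is exactly
the uniform-label null and cohesion 0.9 produces strongly segregated
classes. All draws flow from a single scenario seed (per-artifact streams
derived via seed sequences), so scenarios are fully reproducible.

What the generator does not emulate: assay noise and false-positive edges in
curated interactomes, degree-correlated annotation bias, linkage
disequilibrium between candidate loci, and expression-matrix structure
behind the DE table. Passing tests therefore demonstrate that the methods
recover planted structure of the assumed kind at realistic sizes, not that
any particular biological claim holds on real data.

## Pipeline

Stages run in fixed dependency order; each writes deterministic,
lexicographically sorted tables plus a JSON provenance record (parameters,
seeds, row counts). Stage seeds derive from the global seed and the stage
name, so a rerun is byte-identical. Incremental mode skips stages whose
outputs exist and regenerates the rest — with deterministic seeds the
regenerated artifacts equal the deleted ones. Setting `scenario: null` in
the config disables simulation and runs the analysis over externally
supplied artifacts in the output directory; a missing upstream artifact
raises a dependency error naming the stage. Default problem sizes in the
pipeline configuration (500-node scenario, 50-replicate ER ensemble,
20-replicate k = 3 motif null) are chosen so a complete run finishes in
seconds on one CPU while every statistic retains enough replicates to be
meaningful; all counts are configurable upward.

## Known limitations

- Motif enumeration is exhaustive and pure Python: practical to a few
  thousand 4-subgraph-dense nodes, not proteome scale; sizes ≥ 5 and
  directed graphs are out of scope.
- The ER comparison reports normal-approximation p-values from ensemble
  z-scores; for small ensembles these are indicative, not exact.
- The binomial category test inherits PANTHER-style assumptions (sampling
  with replacement); see the conservativeness note above.
- No identifier mapping, no network downloads, and no plotting are
  provided; tables are written for external tools to draw.
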