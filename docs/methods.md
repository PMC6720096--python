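# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
study systems do and do not establish.

## Disease-network construction

The construction is a guilt-by-association expansion.  The background
network is a simple undirected graph over protein IDs; edge identity is the
sorted ID pair, so duplicate rows in either order merge and self-loops are
dropped (counted in the log).  IDs are taken verbatim apart from
whitespace stripping — no identifier-mapping service is consulted, because
any mapping rule would be an unstated modelling decision; seeds absent from
the background are reported as `missing_seeds` rather than silently added
or invented.

The *basic* network is the induced subgraph on the seeds, keeping
non-interacting seeds as isolates: the isolate count is itself informative
(it measures how incompletely the seed list samples the disease module).
The *expanded* network is the **full induced subgraph** on seeds plus
direct neighbors — including neighbor–neighbor edges, not just the
seed–neighbor star — because every downstream statistic (clustering,
modularity, motif counts) is meaningless on a star union.  Expansion stops
at distance 1; deeper expansion dilutes disease specificity.

## Hub detection

Degree ranking uses lexicographic tie-breaking.  Ties are common at low
degree and the hub set is defined as a ranking *prefix*, so determinism
here is a correctness requirement, not a convenience.

The relative-connectivity curve r(k) is computed incrementally with a
union–find over the ranking order (O((N+E)·α)); tests cross-check it
against independent per-k recomputation.  The stabilisation cutoff is the
smallest k with |r(k′) − r_full| ≤ tol·r_full for **all** k′ ≥ k.  The
suffix quantifier matters: r(k) fluctuates while isolated hubs join the
giant prefix component, and a one-point criterion would cut at a transient
crossing.  The default tol = 0.05 is a reproducible replacement for
reading a stabilisation point off a plotted curve; cutoff_k is monotone
non-increasing in tol by construction.

## Null models

A null network is an induced background subgraph on nodes drawn without
replacement to match the template's *background*-degree multiset.  When an
exact-degree pool is exhausted the sampler falls back to the nearest
available degree (ties toward the smaller degree), logs the event and
records a per-sample fallback count — high-degree pools are thin and an
exact match is not always possible.  A size-matched mode (uniform node
draw) is also available, since "random networks with the same number of
nodes" and "with the same degree distribution" are different nulls and
both are legitimate calibrations; degree-matched is the default.

The observed statistic is located in the ensemble by its empirical
percentile (fraction of null values strictly below; with all nulls equal
to the observed value the percentile is 0 by the strict convention).  A
one-sample Kolmogorov–Smirnov p-value of the null sample against the point
mass at the observed value is also emitted for continuity with a common
reporting style, but the percentile is the recommended summary: the KS
test is designed for distribution–distribution comparison, not for
locating a single observation.

## Z-scores, path length, small-worldness

The binomial-proportion Z-score is evaluated exactly as printed in its
definition; records with b = 0 or b = d (degenerate reference proportion)
are flagged `defined=False` and excluded from summary statistics, never
zeroed.  The characteristic path length L is the mean pairwise distance
over the **largest connected component** (unweighted BFS via
`scipy.sparse.csgraph`); disconnected graphs otherwise have infinite mean
distance, and null draws are frequently disconnected.  Transitivity is the
global triangle-based coefficient 3·triangles/triples — not mean local
clustering — which is also the variant the S^Δ small-world index is
defined on; S^Δ = (C/C_rand)/(L/L_rand) with ensemble means in the
denominators.

## Communities and backbone

Community detection is greedy modularity agglomeration (CNM).  The input
graph is canonicalised (sorted nodes/edges) first, making the partition a
pure function of the graph; a deterministic partition was preferred over
stochastic optimisers with marginally higher Q because the backbone and
all recovery tests depend on reproducible labels.  Edgeless graphs get
singleton communities with Q = 0 by convention.  Reported Q is verified in
tests against a direct evaluation of the modularity sum (tolerance 1e-10)
and against igraph.

The backbone takes, per community, the members whose full-network degree
reaches the community's 90th percentile (minimum one node; an explicit
top-k rule is available), plus any global hubs in the community.  The rule
is configurable because "the hub proteins of each sub-network" admits
several operationalisations; the report always carries the per-community
hub lists, the induced backbone network and its direct coverage of the
remaining proteins, so the choice is auditable.

## miRNA layer

Regulation records are identified by the (miRNA, target) pair; sources are
carried as tags and merged on intersection.  Motif counting treats
length-2 paths as unordered (u–w–v ≡ v–w–u, u ≠ v); a triangle contributes
three distinct paths, and whether the endpoints u, v are themselves
adjacent does not affect B/C classification — the middle node's targeting
state alone separates full from indirect mediation, making B and C
mutually exclusive per (miRNA, path).  Counts use per-middle binomial
tallies of targeted neighbors; tests pin them to an explicit cubic triple
enumeration on 200 random instances.

Coverage works on the regulated-protein universe (the protein side of the
bipartite object) by default, switchable to the full network; the
denominator is always reported, since coverage claims are meaningless
without one.  Core selection is greedy set cover with lexicographic
tie-breaking: exact minimum cover is NP-hard, greedy carries the classical
(ln n + 1) guarantee, and tests verify both validity and that bound
against the exhaustive optimum on small instances.  In the simplified
core-regulator network each backbone protein is annotated
directly-regulated, indirectly-regulated (an untargeted pattern-C middle
of a core miRNA) or unregulated.

## Synthetic study systems

The generator emulates the structure the analysis assumes, not any real
dataset's exact counts:

* **Background**: preferential attachment from a single edge, `attach_m=2`
  stubs per node — the simplest growth rule with a power-law degree tail.
  An n-node instance has 1 + 2(n−2) edges; the log-log CCDF slope of a
  2,000-node instance falls in the plausible scale-free range (tested).
* **Module**: a random node subset densified with uniform internal edges
  to internal density 0.25 — dense enough that module membership is
  topologically detectable, sparse enough not to be a clique.
* **Hubs**: 5 nodes chosen after growth (identity independent of
  attachment luck), stripped of mutual edges and boosted with 150 stubs to
  uniform non-hub nodes.  The boost puts planted hubs clearly above the
  natural degree tail (max natural degree ≈ 90 at n = 2,000), in
  proportion to the gap real PPI hubs show; suppressed hub–hub links are
  what the connectivity-curve method exploits.
* **Seeds**: 60 seeds, 40% drawn off-module — emulating seed lists in
  which a large minority of disease proteins have no known mutual
  interaction and appear as isolates in the basic network.
* **Regulation tables**: per-miRNA target counts Poisson(8) truncated at
  1; five core miRNAs draw at 10× that mean.  Targets grow along network
  neighborhoods with probability 0.5 per step (targets of one miRNA tend
  to interact), else uniformly.  Table B keeps each table-A record with
  probability q = 2J/(1+J) and replaces dropped ones with fresh random
  pairs, giving expected Jaccard J = 0.8 between the two tables
  (Monte-Carlo verified).

All outputs are pure functions of `rng_seed` (per-stage seed sequences).
What passing recovery tests show is that the methods recover *this kind*
of planted structure: modules made detectable by density, hubs by degree
and link suppression, core regulators by target-set size.  Real PPI data
add ascertainment bias (study-frequency correlates with degree), false
positive/negative interactions and incomplete seed lists, none of which
the generator models; recovery rates here are upper bounds on what
comparable real data would give.

## Problem sizes and numerical choices

Default analyses use the 2,000-node background with a 1,000-draw null
ensemble; validation suites use 250–600-node backgrounds and 100-seed
Monte-Carlo repetitions, sizes at which every stochastic direction check
is stable while exhaustive oracles (cubic motif scans, subset-enumeration
set cover, 2-partition modularity) remain feasible.  Floating-point
reports are serialized with shortest-round-trip reprs, so parsing a report
back reproduces each value bit for bit.  Degenerate inputs follow one
rule: statistics that are mathematically undefined (transitivity without a
length-2 path, z with a degenerate reference proportion, slope of an
all-isolate degree distribution) return NaN with a logged warning, while
contract violations (empty seed list, template larger than background,
malformed input rows) raise.

## Known limitations

* Identifier harmonisation across interaction databases is out of scope;
  inputs are assumed to share one ID namespace.
* The expanded network is exactly the distance-≤1 induction; no weighting
  by evidence quality or interaction count.
* Greedy modularity is a deterministic baseline; it can split or merge
  communities that Louvain/Leiden-style optimisers would not.
* Set-cover core sets are greedy approximations; optimality holds only up
  to the (ln n + 1) factor.
* The KS p-value against a point mass is reported for continuity but is
  statistically unorthodox; use the empirical percentile.
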