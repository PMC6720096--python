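# netregmir

Network analysis of disease-associated proteins and the miRNAs that
regulate them.  Given a background protein–protein interaction (PPI)
network, a list of disease-associated seed proteins and validated
miRNA→target tables, the package answers three questions a systems
biologist asks of a disease module: *which proteins form the
disease-specific network*, *which of them hold it together*, and *which
miRNAs control it*.

It is a library first (importable API plus `examples/`), with a thin
`netregmir` command line over the same functions.

## What it computes

**Three-step construction.** From the background network `G` and seed set
`S`: the *basic* network is the induced subgraph `G[S]` (isolated seeds
retained); the *expanded* network is `G[S ∪ N(S)]`, the induced subgraph on
seeds plus their direct neighbors — the disease-specific network used
downstream.

**Hub detection by relative subgraph connectivity.** Nodes are ranked by
decreasing degree; for each prefix of size *k* the relative connectivity
r(k) = (largest-component size of the induced prefix subgraph) / *k* is
tracked.  Because hub–hub links are suppressed in biological networks,
hub-only prefixes are poorly connected; the hub set is the shortest prefix
after which |r(k′) − r_full| ≤ tol·r_full for all k′ ≥ k (default tol = 0.05).

**Null-calibrated statistics.** Degree-matched null networks are induced
background subgraphs on nodes drawn, without replacement, to match the
template's background-degree multiset.  Against an ensemble of such nulls
the package reports the global clustering coefficient C (triangle-based
transitivity) with its empirical percentile, the small-world coefficient

    S^Δ = (C / C_rand) / (L / L_rand),      S^Δ > 1 ⇒ small world,

with L the characteristic path length of the largest component, and the
per-node binomial-proportion Z-score

    z = (a/c − b/d) / sqrt[(b/d)(1 − b/d)/d],

where a, b are a node's link counts and c, d the total link counts in the
focal and reference networks (z > 0: the node keeps proportionally more
links inside the focal network).

**Communities and backbone.** Deterministic greedy modularity
agglomeration partitions the expanded network; per-community hubs (top
degree percentile, plus global hubs) form the backbone, and its direct
reach over the remaining proteins is reported.

**miRNA regulation motifs.** After intersecting two validated-target
tables and projecting onto the disease network, each miRNA's targets T are
scanned for three motifs: **A** — both endpoints of a PPI edge in T;
**B** — all three proteins of a length-2 path u–w–v in T; **C** — u, v ∈ T
but the middle w ∉ T (w is indirectly mediated).  Key/core regulators are
chosen by greedy set cover of the regulated proteins, direct-only versus
all three patterns.

A synthetic generator (`netregmir.synthetic`) produces scale-free
backgrounds with a planted dense module, planted suppressed-link hubs,
mixed seed lists and paired noisy regulation tables — with ground truth, so
every claim above is testable as a recovery problem.

## Worked example

```bash
python examples/02_hub_detection.py
```

```
r(k) at k=1,5,10,24: 1.000, 0.200, 0.500, 0.958
cutoff_k = 24  (r stabilises within 5% of r_full = 1.000)
planted hubs recovered in prefix: 5 of 5
```

The five planted hubs are mutually non-adjacent, so the top-5 prefix is
fully disconnected (r(5) = 0.2); connectivity recovers as connector
proteins join, stabilises by k = 24, and all five planted hubs sit inside
the selected prefix.

```bash
python examples/04_mirna_regulation_patterns.py
```

```
tables: 1350 ∩ 1350 -> 1214 validated records
bipartite: 90 miRNAs regulate 132 proteins via 234 links
motifs: A (co-regulated pairs) = 85, B (fully mediated triples) = 99, C (indirectly mediated triples) = 433
co-regulated edge fraction = 0.088
90% coverage: 36 miRNAs direct-only vs 28 with all three patterns
```

Indirect mediation (pattern C) expands each regulator's reach, so fewer
miRNAs suffice for the same coverage; the planted broad regulators
dominate the greedy ranking.

The other examples cover construction (`01`), null models and
small-worldness (`03`) and the full pipeline with its simplified
core-regulator network (`05`).  The same stages are available from the
shell: `netregmir simulate|build|hubs|stats|zscore|communities|backbone|
mirna|run` (see `netregmir --help`).

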