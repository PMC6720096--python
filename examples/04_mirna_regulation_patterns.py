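"""miRNA regulation motifs and core-regulator selection.

Intersects two validated miRNA→target tables, projects the result onto the
expanded disease network, enumerates the three regulation motifs (pair
co-regulation, full and indirect triple mediation) and selects key/core
miRNAs by greedy protein coverage.
"""

from netregmir.build import build_triple
from netregmir.mirna import (build_bipartite, coregulated_edge_fraction,
                             count_patterns, intersect_regulations,
                             rank_key_mirnas, select_core)
from netregmir.synthetic import SyntheticConfig, generate

study = generate(SyntheticConfig(rng_seed=1))
triple = build_triple(study.background, study.seeds)
expanded = triple.expanded

inter = intersect_regulations(study.table_a, study.table_b)
print(f"tables: {len(study.table_a)} ∩ {len(study.table_b)} -> "
      f"{len(inter)} validated records")

bip = build_bipartite(inter, expanded)
counts = count_patterns(bip, expanded)
totals = counts.totals()
print(f"bipartite: {len(bip.mirnas)} miRNAs regulate {len(bip.proteins)} "
      f"proteins via {len(bip.links)} links")
print(f"motifs: A (co-regulated pairs) = {totals['A']}, "
      f"B (fully mediated triples) = {totals['B']}, "
      f"C (indirectly mediated triples) = {totals['C']}")
print(f"co-regulated edge fraction = "
      f"{coregulated_edge_fraction(counts, expanded):.3f}")

core = select_core(bip, expanded, threshold=0.9)
print(f"90% coverage: {len(core['direct'].core_set)} miRNAs direct-only vs "
      f"{len(core['direct+indirect'].core_set)} with all three patterns")
key, cov = rank_key_mirnas(bip, expanded, 5)
print(f"top-5 greedy regulators {key} cover {cov:.0%} directly; "
      f"planted core miRNAs: {sorted(study.truth.core_mirnas)}")

# Indirect mediation expands each miRNA's reach, so far fewer regulators
# suffice for the same coverage; the planted broad regulators dominate the
# greedy ranking.
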