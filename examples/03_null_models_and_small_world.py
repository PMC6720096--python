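"""Null-model calibration: clustering, Z-scores and small-worldness.

Compares the expanded disease network's global clustering coefficient with
a degree-matched null ensemble drawn from the background, computes per-node
binomial-proportion Z-scores (focal vs background link share), and the
small-world coefficient S^Δ = (C/C_rand)/(L/L_rand).
"""

import numpy as np

from netregmir.build import build_triple
from netregmir.synthetic import SyntheticConfig, generate
from netregmir.topology import (compare_to_null, sample_degree_matched_null,
                                small_worldness, transitivity,
                                z_scores_for_network)

study = generate(SyntheticConfig(rng_seed=1))
triple = build_triple(study.background, study.seeds)
expanded = triple.expanded

nulls = sample_degree_matched_null(study.background, expanded,
                                   n_samples=200, rng_seed=1)
c_obs = transitivity(expanded)
c_null = [transitivity(g) for g in nulls]
pct, ks_p = compare_to_null(c_obs, c_null)
print(f"C(expanded) = {c_obs:.4f}, null mean = {np.mean(c_null):.4f}, "
      f"empirical percentile = {pct:.3f}")

sw = small_worldness(expanded, nulls)
print(f"S^delta = {sw.s_delta:.3f}  "
      f"(C/C_rand = {sw.C / sw.C_rand:.3f}, L/L_rand = {sw.L / sw.L_rand:.3f})")

z = [r.z for r in z_scores_for_network(expanded, study.background) if r.defined]
print(f"Z-scores: mean = {np.mean(z):.2f}, "
      f"{100 * np.mean([v > 0 for v in z]):.0f}% positive")

# A percentile near 0 or 1 would mark the disease network's clustering as
# extreme relative to degree-matched background draws; strongly positive
# Z-scores say its proteins keep most of their interactions inside the
# disease network — the signature of a relatively self-contained module.
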