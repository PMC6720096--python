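"""Hub detection by relative subgraph connectivity.

Ranks all proteins by degree, tracks the relative connectivity r(k) of the
induced subgraph on each top-k prefix, and cuts where the curve stabilises
at the whole-network value.  Because links between hubs are suppressed,
hub-only prefixes are poorly connected and r(k) dips before recovering —
that dip is the hub signature.
"""

from netregmir.synthetic import SyntheticConfig, generate_background
from netregmir.topology import (connectivity_curve, identify_hubs,
                                rank_by_degree)

net, truth = generate_background(SyntheticConfig(rng_seed=1))
curve = connectivity_curve(net, rank_by_degree(net))
report = identify_hubs(curve, tol=0.05)

print(f"r(k) at k=1,5,10,{report.cutoff_k}: "
      + ", ".join(f"{curve.r[k - 1]:.3f}" for k in (1, 5, 10, report.cutoff_k)))
print(f"cutoff_k = {report.cutoff_k}  (r stabilises within 5% of "
      f"r_full = {curve.r_full:.3f})")
recovered = truth.planted_hubs & set(report.hubs)
print(f"planted hubs recovered in prefix: {len(recovered)} of "
      f"{len(truth.planted_hubs)}")

# The five planted hubs are mutually non-adjacent, so the top-5 prefix is
# fully disconnected (r(5) = 0.2); r only reaches the whole-network value
# once enough connector proteins join, and every planted hub sits inside
# the resulting prefix.
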