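"""Crossover-point mapping end to end.

Simulates the randomized-library experiment (library + cointegrate junction
amplicons, sequencing error, a slice of abnormal reads), profiles the three
amplicon classes, infers the crossover boundary from the segregation of
non-WT bases, and prints the per-position stringency table.
"""

import numpy as np

import xovermap as xm

site = xm.default_site()
config = {
    "boundary": "unknown",   # use the site's annotated top-strand crossover
    "depth": 10_000,
    "error_rate": 0.001,
    "abnormal_fraction": 0.05,
    "seed": 31,
}
result = xm.run_e2e(config)
b_true = xm.ts_boundary_ordinal(site)

print(f"true boundary (between the two L-box-border adenines): {b_true}")
print(f"inferred boundary: {result.call.boundary_hat} "
      f"(log-likelihood gap to runner-up: {result.call.confidence:.1f})")

print("\nnon-WT retention per window position:")
left = result.profiles.left.nonwt_rates()
right = result.profiles.right.nonwt_rates()
print("  position:", "  ".join(f"{j:5d}" for j in range(1, 11)))
print("  left    :", "  ".join(f"{r:.3f}" for r in left))
print("  right   :", "  ".join(f"{r:.3f}" for r in right))
# Positions up to the boundary keep their randomized bases in the left
# junction; the remainder segregate into the right junction.  The ~0.075
# vs ~0.001 contrast is the signature the changepoint model reads.

print("\nlog-likelihood curve over candidate boundaries 0..10:")
curve = result.call.loglik_curve - result.call.loglik_curve.max()
for b, ll in enumerate(curve):
    marker = " <- call" if b == result.call.boundary_hat else ""
    print(f"  b={b:2d}: {ll:10.1f}{marker}")

print("\nper-position stringency (skew from the neutral 7.5% retention):")
cols = ["position", "wt_base", "observed", "skew", "q_value"]
print(result.stringency.table[cols].to_string(index=False,
                                              float_format="%.4f"))
print("skew near 0: the position tolerates any base; strongly negative "
      "skew would mark a base the integrase requires.")
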