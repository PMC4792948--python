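"""Count-based assay estimators.

Frequencies with Wilson intervals from colony counts, the
transformation-efficiency-adjusted activity of the non-replicative circle
assay, and fold changes between induction conditions.
"""

import xovermap as xm
from xovermap.assay_stats import AssayCounts, adjusted_activity, fold_change

print("L-box recombinant frequencies from clone counts:")
for k, n in ((1, 607), (3, 642)):
    est = xm.frequency(AssayCounts(k, n))
    print(f"  {k}/{n}: {est.percent()}  "
          f"(95% CI {100 * est.ci_low:.3f}% - {100 * est.ci_high:.2f}%)")
# Rare events: the Wilson interval stays informative even at 1 recombinant.

act = adjusted_activity(AssayCounts(117), AssayCounts(100_000), te_ratio=1.0)
print(f"\ncircle-assay activity, 117 pir- vs 100,000 pir+ clones "
      f"(TE ratio 1): {act:.3g}")

fc = fold_change(AssayCounts(44, 10_000), AssayCounts(1, 10_000))
print(f"\ninduction fold change, 44/10,000 vs 1/10,000: "
      f"{fc.ratio:.0f}-fold (95% CI {fc.ci_low:.0f} - {fc.ci_high:.0f})")
print("the wide interval reflects the single repressed-condition event.")
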