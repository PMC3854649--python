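"""Recovering a planted high-fold-change/non-significant pathway.

Simulates a 1000-gene two-class experiment in which pathway P001's
members share a 2.0 log2-unit class shift buried in high within-group
variance: large fold changes, but the gene-level t-test misses nearly
all of them at alpha = 0.01.  The weighted hypergeometric test ranks the
pathway first; classical ORA cannot distinguish it from background.
"""

import numpy as np

import wsea

spec = wsea.SimulationSpec(
    planted=(wsea.PlantedEffect("P001", "high-FC-nonsignificant", magnitude=2.0),),
    seed=20260918,
)
matrix, design, collection = wsea.simulate_dataset(spec)
stats = wsea.prepare_gene_stats(matrix, design, alpha=0.01)

members = sorted(collection["P001"].members)
print(f"planted pathway P001: {len(members)} genes")
print(
    f"mean |log2 FC| of members: "
    f"{np.abs(np.log2(stats.loc[members, 'fold_change'])).mean():.2f}"
)
print(f"members significant at 0.01: {int(stats.loc[members, 'is_significant'].sum())}")
print(f"significant genes on the whole array: {int(stats['is_significant'].sum())}")
print()

for method in ("hypergeometric", "weighted_hypergeometric", "weighted_chi2"):
    res = wsea.enrich(collection, stats, method, a=1.0, alpha=0.01)
    row = res[res["set_id"] == "P001"].iloc[0]
    print(f"{method:25s} P001 rank={int(row['rank']):2d}  p={row.p_value:.3g}")

print()
print(
    "Reading: the planted pathway contributes essentially no significant\n"
    "genes, so count-based ORA ranks it like noise; the weighted tests,\n"
    "which sum |log2 FC| over members, place it first."
)
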