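"""Core constraint-based analyses on a toy network: FBA, pFBA, FVA, scan, deletions.

The toy has two redundant conversion routes from the native carbon source to
the biomass precursor, so it shows degeneracy (FVA), parsimony (pFBA), and
synthetic lethality (group deletion) in a network small enough to read.
"""

import numpy as np

from undermet import (
    fba, flux_scan, fva, group_deletion, make_toy_model, pfba,
    single_gene_deletions,
)

model = make_toy_model(n_branches=2, seed=1)

wt = fba(model)
print(f"FBA optimum: {wt.objective_value:.3f} h^-1 (uptake bound 10, yield-limited)")

par = pfba(model)
print(f"pFBA: same objective {par.objective_value:.3f}, total |flux| "
      f"{par.sum_abs_flux():.1f} (one route carries everything)")

print("\nFVA at 99% optimality (redundant arms can each carry 0..full flux):")
for iv in fva(model, ["CNV_1a", "CNV_2a", "BIOMASS"], fraction=0.99):
    print(f"  {iv.reaction_id:8s} [{iv.min_flux:6.2f}, {iv.max_flux:6.2f}]")

print("\nflux scan of one arm (biomass optimum vs pinned arm flux):")
for v, opt in flux_scan(model, "CNV_1a", list(np.linspace(0, 12, 7))).points:
    print(f"  v={v:5.1f} -> {'infeasible' if opt is None else f'{opt:.2f}'}")

genes = ["g_b1a", "g_b2a", "g_tpt"]
print("\nsingle-gene deletions (redundant-arm genes are dispensable):")
for gene, opt in single_gene_deletions(model, genes).items():
    print(f"  d{gene}: {opt:.2f}")
both = group_deletion(model, {"g_b1a", "g_b2a"})
print(f"deleting both arm genes at once: {both.objective_value:.2f} "
      "(synthetic lethal pair)")
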