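"""Univariate mixed-model GWAS baseline on a two-class contrast.

Builds the centred kinship matrix, runs per-SNP Wald tests for every
class pair and shows that the planted causal SNPs dominate the p-value
ranking.
"""

import numpy as np

from boostsel.association import pairwise_gwas
from boostsel.simulate import SimulationConfig, simulate_dataset

matrix, phenos, truth = simulate_dataset(SimulationConfig(
    n_samples=200, n_sites=800, seed=5,
))
gwas = pairwise_gwas(matrix, phenos, p_threshold=1e-8)

site_index = {sid: j for j, sid in enumerate(matrix.site_ids)}
causal_blocks = {j // 5 for j in truth.causal_indices}  # default 5-site LD blocks


def describe(site_id):
    j = site_index[site_id]
    if j in truth.causal_indices:
        return "causal"
    return "LD proxy of causal" if j // 5 in causal_blocks else "non-causal"


for (a, b), results in gwas.per_pair.items():
    tested = [r for r in results if not r.skipped]
    best = min(tested, key=lambda r: r.p_value)
    print(f"{a} vs {b}: best p = {best.p_value:.2e} at {best.site_id} "
          f"({describe(best.site_id)})")
print(f"{len(gwas.significant_union)} sites significant at p < 1e-8 "
      f"across {len(gwas.per_pair)} contrasts")
signal = [s for s in gwas.significant_union
          if describe(s) in ("causal", "LD proxy of causal")]
print(f"{len(signal)} of them are causal SNPs or proxies in their LD blocks")
# The LMM corrects each contrast for relatedness; planted effects (or
# their tightly linked proxies) should top the ranking while the fixed
# 1e-8 threshold stays strict.
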