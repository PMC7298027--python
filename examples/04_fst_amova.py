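"""Population differentiation: pairwise F_ST and hierarchical AMOVA.

Simulates four populations drifted at F = 0.10 nested in two groups; the
Weir-Cockerham estimator recovers the simulated parameter and the AMOVA
partitions variance across the four hierarchy levels with permutation
p-values.
"""

import numpy as np
import pandas as pd

from equipop import differentiation as diff
from equipop import genodata as gd
from equipop import synthpop as sp

rng = np.random.default_rng(11)
freqs = sp.bn_frequencies(None, 0.10, 4, 3000, seed=12)
calls, ids = [], []
for i in range(4):
    h = sp.draw_haplotypes(freqs[i], 40, seed=13 + i, sample_prefix=f"p{i}_")
    calls.append(h.to_genotypes().calls)
    ids += list(h.sample_ids)
gm = gd.GenotypeMatrix(np.vstack(calls), sp.make_variant_table(3000),
                       pd.DataFrame({"id": ids}))
pops = np.repeat([f"p{i}" for i in range(4)], 20)

theta, p = diff.fst_permutation(
    gm.take_samples(np.where(np.isin(pops, ["p0", "p1"]))[0]),
    pops[np.isin(pops, ["p0", "p1"])], n_perm=999, seed=14)
print(f"pairwise Weir-Cockerham F_ST (p0 vs p1): {theta:.4f}  (simulated F: ~0.10)")
print(f"permutation p-value (999 permutations):  {p:.4f}")

hier = diff.Hierarchy(dict(zip(ids, pops)),
                      {"p0": "gA", "p1": "gA", "p2": "gB", "p3": "gB"})
res = diff.amova(gm, hier, n_perm=199, seed=15)
print("\nAMOVA variance partition:")
for level in ("among_groups", "among_pops", "among_individuals", "within_individuals"):
    pval = res.p_values.get(level)
    ptxt = f"p = {pval:.3f}" if pval is not None else ""
    print(f"  {level:<22} {res.percentages[level]:6.2f}%  {ptxt}")
print("Phi statistics:", {k: round(v, 4) for k, v in res.phi.items()})
print("\nPhi_SC (populations within groups) estimates the simulated drift 0.10; "
      "with all populations equally drifted, the among-group level carries ~0.")
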