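"""Per-individual heterozygosity, inbreeding and IBD-based sample filtering.

Two populations differing in drift: the more drifted one shows lower
observed heterozygosity.  A duplicated sample demonstrates the PI_HAT
relatedness filter.
"""

import numpy as np
import pandas as pd

from equipop import diversity as div
from equipop import genodata as gd
from equipop import synthpop as sp

freqs = sp.bn_frequencies(None, [0.02, 0.25], 2, 4000, seed=3)
h1 = sp.draw_haplotypes(freqs[0], 40, seed=4, sample_prefix="lowF_")
h2 = sp.draw_haplotypes(freqs[1], 40, seed=5, sample_prefix="highF_")
calls = np.vstack([h1.to_genotypes().calls, h2.to_genotypes().calls])
calls = np.vstack([calls, calls[0:1]])                      # duplicate of sample 0
ids = list(h1.sample_ids) + list(h2.sample_ids) + ["dup_of_lowF_0"]
gm = gd.GenotypeMatrix(calls, h1.variants.copy(), pd.DataFrame({"id": ids}))
labels = ["lowF"] * 20 + ["highF"] * 20 + ["lowF"]

summary, comparisons = div.group_diversity(gm, labels)
print("group diversity (mean Ho, He, mean F):")
print(summary.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print("\npairwise comparison (Tukey-Kramer on per-sample Ho):")
print(comparisons.to_string(index=False, float_format=lambda x: f"{x:.2e}"))

f3 = div.fhat3(gm)
thr = div.fhat3_outlier_threshold(f3)
print(f"\nFhat3 cohort threshold (mean + 2 SD): {thr:.3f}; "
      f"{(f3 > thr).sum()} sample(s) above it")

rel = div.pairwise_ibd(gm)
print(f"\nPI_HAT duplicate pair: {rel.loc['lowF_0', 'dup_of_lowF_0']:.3f}")
kept = div.relatedness_filter(rel, ibd_max=0.25)
print(f"retained after IBD < 0.25 filter: {len(kept)} of {gm.n_samples} "
      "(one member of the duplicate pair dropped)")
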