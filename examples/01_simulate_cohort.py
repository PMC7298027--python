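"""Simulate the standard structured/admixed/swept cohort and look at truth.

Builds four reference populations under the Balding-Nichols model, one
admixed group (30% donor ancestry, 9 generations since admixture) and a
panel with an implanted hard sweep, then prints the ground truth that the
downstream analyses will try to recover.
"""

import numpy as np

from equipop import synthpop as sp

cfg = sp.SimConfig(n_variants=2500, spacing_bp=8000, n_admixed=6, seed=42)
bundle = sp.simulate_cohort(cfg)

print("reference panels (population: haplotypes x variants):")
for name, haps in bundle["ref_haps"].items():
    print(f"  {name:<14} {haps.n_haplotypes} x {haps.n_variants}")

tr = bundle["admix_truth"].tracts
n_tracts = tr.groupby("haplotype").size()
donor_bp = tr.loc[tr.source == cfg.admix_donor, "end"].sub(
    tr.loc[tr.source == cfg.admix_donor, "start"]).add(1).sum()
total_bp = tr["end"].sub(tr["start"]).add(1).sum()
print(f"\nadmixed haplotypes: {bundle['admixed'].n_haplotypes}")
print(f"mean ancestry tracts per haplotype: {n_tracts.mean():.1f} "
      f"(expect ~{1 + 9 * 1e-8 * (cfg.n_variants - 1) * cfg.spacing_bp:.1f} at G=9, 1 cM/Mb)")
print(f"realized donor fraction: {donor_bp / total_bp:.3f} (target {cfg.admix_proportion})")

st = bundle["sweep_truth"]
print(f"\nsweep implanted at {st.sweep_position:,} bp with "
      f"{len(st.sweep_carriers)} carrier haplotypes; "
      f"mean tract length {np.mean(st.sweep_tracts.end - st.sweep_tracts.start):,.0f} bp")
print("\nThe truth tracts are what the ancestry module must recover; the sweep "
      "carriers define where the scan statistics should peak.")
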