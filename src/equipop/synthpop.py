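"""Synthetic phased-genotype generator with ground truth.

Generates datasets carrying exactly the statistical structure the analysis
modules assume, each feature controlled by construction:

* structured populations via the Balding-Nichols model (per-population allele
  frequencies Beta-distributed around a global frequency, parameterized by a
  drift coefficient F that plays the role of the target F_ST);
* recent admixture mosaics: per-haplotype ancestry tracts with Poisson
  recombination breakpoints at rate G x recombination-rate, sources drawn
  from the admixture proportions, alleles copied from reference haplotypes,
  truth tracts recorded;
* hard selective sweeps: a shared core haplotype copied into a carrier
  fraction with exponentially decaying one-sided tract lengths (elevated H
  and H12, depressed diversity at the locus);
* neutral-SFS sites (derived-allele count ~ 1/i) for which E[pi] =
  E[theta_W] per site, calibrating windowed Tajima's D around zero;
* SNP-array-style minor-allele-frequency ascertainment.

Reference panels are linkage-free (independent sites); haplotype structure
enters only through mosaics and sweeps, so each statistic's null and
alternative are controlled by construction.  All generators are pure
functions of their arguments and a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix, HaplotypeMatrix


class SynthError(ValueError):
    pass


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    tracts: pd.DataFrame | None = None        # haplotype, chrom, start, end, source, source_hap
    sweep_position: int | None = None
    sweep_carriers: list[int] = field(default_factory=list)
    sweep_tracts: pd.DataFrame | None = None  # haplotype, start, end
    pop_frequencies: np.ndarray | None = None
    seed: int | None = None

    def to_json(self, path) -> None:
        obj = {
            "sweep_position": self.sweep_position,
            "sweep_carriers": list(map(int, self.sweep_carriers)),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    def tracts_to_bed(self, path) -> None:
        if self.tracts is None:
            raise SynthError("no ancestry tracts recorded")
        with open(path, "w") as fh:
            for _, r in self.tracts.iterrows():
                fh.write(
                    f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t"
                    f"{r['source']}\thap{int(r['haplotype'])}\n"
                )


def make_variant_table(n_variants: int, chrom: str = "1", spacing_bp: int = 1000,
                       start_bp: int = 1) -> pd.DataFrame:
    """Evenly spaced biallelic A/G variant records."""
    pos = start_bp + spacing_bp * np.arange(n_variants, dtype=np.int64)
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "allele1": "A", "allele2": "G",
         "id": [f"{chrom}_{p}" for p in pos]}
    )


# ---------------------------------------------------------------------------
# Balding-Nichols panels


def bn_frequencies(
    p_global: np.ndarray | None,
    F,
    n_pops: int,
    n_variants: int,
    seed: int = 0,
) -> np.ndarray:
    """Per-population allele frequencies under the Balding-Nichols model.

    ``p_pop ~ Beta(p (1 - F) / F, (1 - p)(1 - F) / F)`` independently per
    population and variant; ``F = 0`` returns the global frequencies exactly.
    ``F`` may be a scalar or one value per population.  When ``p_global`` is
    None the global frequencies are drawn Uniform(0.05, 0.95).
    """
    rng = np.random.default_rng(seed)
    if p_global is None:
        p_global = rng.uniform(0.05, 0.95, size=n_variants)
    p = np.asarray(p_global, dtype=float)
    if p.ndim == 0:
        p = np.full(n_variants, float(p))
    Fs = np.broadcast_to(np.asarray(F, dtype=float), (n_pops,))
    if ((Fs < 0) | (Fs >= 1)).any():
        raise SynthError("Balding-Nichols F must lie in [0, 1)")
    out = np.empty((n_pops, n_variants))
    for i, f in enumerate(Fs):
        if f == 0:
            out[i] = p
        else:
            a = p * (1 - f) / f
            b = (1 - p) * (1 - f) / f
            out[i] = rng.beta(a, b)
    return out


def draw_haplotypes(
    freqs: np.ndarray,
    n_haps: int,
    seed: int = 0,
    variants: pd.DataFrame | None = None,
    sample_prefix: str = "S",
) -> HaplotypeMatrix:
    """Independent Bernoulli haplotypes at the given allele-1 frequencies.

    ``n_haps`` must be even (haplotypes are paired into diploid samples).
    """
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise SynthError("frequencies must lie in [0, 1]")
    if n_haps % 2:
        raise SynthError("n_haps must be even (2 haplotypes per sample)")
    rng = np.random.default_rng(seed)
    alleles = (rng.random((n_haps, len(freqs))) < freqs[None, :]).astype(np.int8)
    if variants is None:
        variants = make_variant_table(len(freqs))
    ids = [f"{sample_prefix}{i}" for i in range(n_haps // 2)]
    return HaplotypeMatrix(alleles, variants, ids)


# ---------------------------------------------------------------------------
# admixture mosaics


def simulate_admixed(
    ref_haps_by_pop: dict[str, HaplotypeMatrix],
    proportions: dict[str, float],
    G: int = 9,
    recomb_rate_cm_per_mb: float = 1.0,
    n_samples: int = 10,
    seed: int = 0,
    sample_prefix: str = "ADM",
) -> tuple[HaplotypeMatrix, SimTruth]:
    """Admixed haplotypes as tract mosaics over reference panels.

    Breakpoints follow a Poisson process along the chromosome with rate
    ``G x recomb_rate`` (in Morgans: cM/Mb x bp x 1e-8); each tract's source
    population is drawn from ``proportions`` and its alleles are copied from
    a uniformly chosen haplotype of that population's panel.
    """
    pops = list(ref_haps_by_pop)
    if not pops:
        raise SynthError("empty reference panel")
    props = np.array([proportions[p] for p in pops], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
        raise SynthError("proportions must be non-negative and sum to 1")
    if G < 1:
        raise SynthError("G must be >= 1")
    first = ref_haps_by_pop[pops[0]]
    positions = first.positions
    for p in pops[1:]:
        if not np.array_equal(ref_haps_by_pop[p].positions, positions):
            raise SynthError("reference panels disagree on variant positions")
    chrom = str(first.variants["chrom"].iloc[0])
    span_start, span_end = int(positions[0]), int(positions[-1])
    rate_per_bp = G * recomb_rate_cm_per_mb * 1e-8  # breakpoints per bp

    rng = np.random.default_rng(seed)
    n_haps = 2 * n_samples
    alleles = np.empty((n_haps, len(positions)), dtype=np.int8)
    truth_rows = []
    for h in range(n_haps):
        n_bp = rng.poisson(rate_per_bp * (span_end - span_start))
        cuts = np.sort(rng.uniform(span_start, span_end, size=n_bp)).astype(np.int64)
        bounds = np.concatenate([[span_start], cuts, [span_end]])
        for t in range(len(bounds) - 1):
            lo = int(bounds[t]) if t == 0 else int(bounds[t]) + 1
            hi = int(bounds[t + 1])
            if hi < lo:
                continue
            src = pops[rng.choice(len(pops), p=props)]
            panel = ref_haps_by_pop[src]
            src_hap = int(rng.integers(panel.n_haplotypes))
            j0, j1 = np.searchsorted(positions, [lo, hi + 1])
            alleles[h, j0:j1] = panel.alleles[src_hap, j0:j1]
            truth_rows.append(
                {"haplotype": h, "chrom": chrom, "start": lo, "end": hi,
                 "source": src, "source_hap": src_hap}
            )
    ids = [f"{sample_prefix}{i}" for i in range(n_samples)]
    haps = HaplotypeMatrix(alleles, first.variants.copy(), ids)
    truth = SimTruth(tracts=pd.DataFrame(truth_rows), seed=seed)
    return haps, truth


# ---------------------------------------------------------------------------
# sweeps


def implant_sweep(
    haps: HaplotypeMatrix,
    position: int,
    carrier_fraction: float = 0.6,
    mean_tract_bp: float = 500_000.0,
    seed: int = 0,
) -> tuple[HaplotypeMatrix, SimTruth]:
    """Overwrite a carrier fraction with a shared core haplotype.

    One donor haplotype is chosen; each carrier's alleles within
    ``[position - L_left, position + L_right]`` (independent exponentials
    with the given mean) are replaced by the donor's, so carriers share a
    core that decays with distance — the footprint of a hard sweep.
    """
    positions = haps.positions
    if not positions[0] <= position <= positions[-1]:
        raise SynthError("sweep position outside the chromosome span")
    if not 0 < carrier_fraction <= 1:
        raise SynthError("carrier_fraction must lie in (0, 1]")
    n = haps.n_haplotypes
    n_carriers = int(np.floor(carrier_fraction * n))
    if n_carriers < 2:
        raise SynthError("fewer than 2 carriers: no sweep signal possible")
    rng = np.random.default_rng(seed)
    donor = int(rng.integers(n))
    carriers = rng.choice(n, size=n_carriers, replace=False)
    alleles = haps.alleles.copy()
    rows = []
    for h in carriers:
        left = position - rng.exponential(mean_tract_bp)
        right = position + rng.exponential(mean_tract_bp)
        j0, j1 = np.searchsorted(positions, [left, right + 1])
        alleles[h, j0:j1] = haps.alleles[donor, j0:j1]
        rows.append({"haplotype": int(h), "start": int(max(left, positions[0])),
                     "end": int(min(right, positions[-1]))})
    out = HaplotypeMatrix(alleles, haps.variants.copy(), list(haps.sample_ids))
    truth = SimTruth(
        sweep_position=int(position),
        sweep_carriers=[int(h) for h in carriers],
        sweep_tracts=pd.DataFrame(rows),
        seed=seed,
    )
    return out, truth


# ---------------------------------------------------------------------------
# neutral SFS sites


def neutral_sfs_sites(
    n_haps: int,
    n_sites: int,
    seed: int = 0,
    variants: pd.DataFrame | None = None,
) -> HaplotypeMatrix:
    """Independent sites with derived-allele count i drawn with P(i) ~ 1/i.

    Under this sampling every site is polymorphic and E[pi] = E[theta_W] =
    1/a1 per site, so windowed Tajima's D is centered at zero — the
    calibration null for the scan module.
    """
    if n_haps < 4:
        raise SynthError("need >= 4 haplotypes")
    if n_haps % 2:
        raise SynthError("n_haps must be even")
    rng = np.random.default_rng(seed)
    i_vals = np.arange(1, n_haps)
    w = 1.0 / i_vals
    counts = rng.choice(i_vals, size=n_sites, p=w / w.sum())
    alleles = np.zeros((n_haps, n_sites), dtype=np.int8)
    for j, c in enumerate(counts):
        alleles[rng.choice(n_haps, size=c, replace=False), j] = 1
    if variants is None:
        variants = make_variant_table(n_sites)
    ids = [f"N{i}" for i in range(n_haps // 2)]
    return HaplotypeMatrix(alleles, variants, ids)


# ---------------------------------------------------------------------------
# ascertainment


def ascertain(data, maf_min: float = 0.01):
    """Array-style ascertainment: drop variants with MAF <= ``maf_min``.

    ``maf_min = 0`` is the identity (monomorphic sites retained).  Works on
    either container; positions are preserved.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise SynthError("maf_min must lie in [0, 0.5]")
    if isinstance(data, HaplotypeMatrix):
        freq = data.alleles.mean(axis=0)
    elif isinstance(data, GenotypeMatrix):
        obs = data.calls != MISSING
        with np.errstate(invalid="ignore"):
            freq = np.where(obs, data.calls, 0).sum(axis=0) / np.maximum(2 * obs.sum(axis=0), 1)
    else:
        raise SynthError(f"unsupported container {type(data).__name__}")
    maf = np.minimum(freq, 1 - freq)
    keep = np.ones(len(maf), dtype=bool) if maf_min == 0 else maf > maf_min
    return data.take_variants(np.where(keep)[0])


# ---------------------------------------------------------------------------
# the standard structured/admixed/swept fixture


@dataclass
class SimConfig:
    """Knobs of the standard fixture (a desk-scale rendering of a structured,
    recently admixed cohort with one hard sweep).

    Four reference populations with Balding-Nichols drift spanning weak to
    strong differentiation, one admixed group (30% donor, G = 9 generations),
    and a sweep at mid-chromosome.
    """

    n_variants: int = 5000
    chrom: str = "1"
    spacing_bp: int = 1000
    pop_names: tuple = ("thoroughbred", "nonracing", "turkemen", "icelandic")
    pop_f: tuple = (0.01, 0.03, 0.15, 0.30)
    pop_n_haps: tuple = (40, 40, 40, 40)
    admix_donor: str = "thoroughbred"
    admix_recipient: str = "nonracing"
    admix_proportion: float = 0.30
    admix_generations: int = 9
    recomb_rate_cm_per_mb: float = 1.0
    n_admixed: int = 10
    sweep_carrier_fraction: float = 0.6
    sweep_mean_tract_bp: float = 500_000.0
    ascertainment_maf: float = 0.01
    seed: int = 0


def simulate_cohort(config: SimConfig) -> dict:
    """Build the standard fixture; returns panels, admixed haplotypes, truth.

    Keys: ``ref_haps`` (dict of HaplotypeMatrix), ``admixed``
    (HaplotypeMatrix), ``admix_truth``, ``swept`` (admixed with the sweep
    implanted at mid-chromosome), ``sweep_truth``, ``pop_freqs``,
    ``variants``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    variants = make_variant_table(cfg.n_variants, cfg.chrom, cfg.spacing_bp)
    freqs = bn_frequencies(None, cfg.pop_f, len(cfg.pop_names), cfg.n_variants,
                           seed=int(rng.integers(2**31)))
    ref_haps = {
        name: draw_haplotypes(freqs[i], cfg.pop_n_haps[i], seed=int(rng.integers(2**31)),
                              variants=variants.copy(), sample_prefix=f"{name}_")
        for i, name in enumerate(cfg.pop_names)
    }
    proportions = {name: 0.0 for name in cfg.pop_names}
    proportions[cfg.admix_donor] = cfg.admix_proportion
    proportions[cfg.admix_recipient] = 1.0 - cfg.admix_proportion
    admixed, admix_truth = simulate_admixed(
        {cfg.admix_donor: ref_haps[cfg.admix_donor],
         cfg.admix_recipient: ref_haps[cfg.admix_recipient]},
        {cfg.admix_donor: proportions[cfg.admix_donor],
         cfg.admix_recipient: proportions[cfg.admix_recipient]},
        G=cfg.admix_generations,
        recomb_rate_cm_per_mb=cfg.recomb_rate_cm_per_mb,
        n_samples=cfg.n_admixed,
        seed=int(rng.integers(2**31)),
    )
    mid = int(variants["pos"].iloc[len(variants) // 2])
    swept, sweep_truth = implant_sweep(
        ref_haps[cfg.pop_names[1]], mid, cfg.sweep_carrier_fraction,
        cfg.sweep_mean_tract_bp, seed=int(rng.integers(2**31)),
    )
    return {
        "config": cfg,
        "variants": variants,
        "pop_freqs": freqs,
        "ref_haps": ref_haps,
        "admixed": admixed,
        "admix_truth": admix_truth,
        "swept": swept,
        "sweep_truth": sweep_truth,
    }


def write_group_tsv(groups: dict[str, list[str]], path) -> None:
    """Two-column TSV: sample id, group label."""
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for g, ids in groups.items():
            for s in ids:
                fh.write(f"{s}\t{g}\n")
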