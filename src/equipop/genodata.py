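"""Genotype/haplotype containers, text-format I/O, and the QC filter chain.

The in-memory model is deliberately small: a :class:`GenotypeMatrix` holds
diploid alternate-allele counts (samples x variants, ``-1`` missing) next to a
variant table and a sample table; a :class:`HaplotypeMatrix` holds phased
binary haplotypes (two rows per sample).  Coordinates are 1-based inclusive in
memory and in MAP/VCF; BED output elsewhere in the package is 0-based
half-open.

Filters mirror the standard SNP-array QC chain: genotyping-rate (missingness),
minor-allele-frequency, Hardy-Weinberg equilibrium on a designated sample
subset with Bonferroni correction, and sliding-window LD pruning.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1

_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


class GenodataError(ValueError):
    """Raised for malformed inputs or contract violations in this module."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Diploid genotypes as alternate-allele counts.

    Parameters
    ----------
    calls
        ``(n_samples, n_variants)`` integer array with values in
        ``{0, 1, 2, MISSING}``; entry ``(i, j)`` counts copies of
        ``allele2`` carried by sample ``i`` at variant ``j``.
    variants
        DataFrame with columns ``chrom, pos, allele1, allele2, id``;
        positions strictly increasing within a chromosome, ids unique.
    samples
        DataFrame with column ``id`` (unique) and optional group-label
        columns (``breed``, ``lineage``, ``use`` ...).
    """

    calls: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.ndim != 2:
            raise GenodataError("calls must be 2-D (samples x variants)")
        n, m = self.calls.shape
        if len(self.samples) != n or len(self.variants) != m:
            raise GenodataError("calls shape does not match sample/variant tables")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise GenodataError("calls contain values outside {0,1,2,missing}")
        if self.samples["id"].duplicated().any():
            dup = self.samples["id"][self.samples["id"].duplicated()].iloc[0]
            raise GenodataError(f"duplicate sample id: {dup!r}")
        if self.variants["id"].duplicated().any():
            raise GenodataError("duplicate variant ids")
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise GenodataError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def take_variants(self, index) -> "GenotypeMatrix":
        """Subset to the variant positions in ``index`` (kept in order)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            self.calls[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            self.samples.copy(),
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.calls[index, :],
            self.variants.copy(),
            self.samples.iloc[index].reset_index(drop=True),
        )


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes, two consecutive rows per sample.

    ``alleles`` is ``(2 * n_samples, n_variants)`` with values in ``{0, 1}``
    (phased data are complete: no missing sentinel).  Row ``2i`` is sample
    ``i``'s first haplotype, row ``2i + 1`` its second.
    """

    alleles: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise GenodataError("alleles must be 2-D")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise GenodataError("expected exactly 2 haplotypes per sample")
        if not np.isin(self.alleles, (0, 1)).all():
            raise GenodataError("haplotype alleles must be 0/1 (no missing)")
        if len(self.variants) != self.alleles.shape[1]:
            raise GenodataError("variant table does not match allele columns")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self.variants["pos"].to_numpy()

    def to_genotypes(self, samples: pd.DataFrame | None = None) -> GenotypeMatrix:
        """Collapse phased haplotypes to diploid alternate-allele counts."""
        calls = self.alleles[0::2] + self.alleles[1::2]
        if samples is None:
            samples = pd.DataFrame({"id": list(self.sample_ids)})
        return GenotypeMatrix(calls, self.variants.copy(), samples)

    def take_variants(self, index) -> "HaplotypeMatrix":
        index = np.asarray(index)
        return HaplotypeMatrix(
            self.alleles[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            list(self.sample_ids),
        )

    def take_haplotypes(self, hap_index, sample_ids) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.alleles[np.asarray(hap_index), :],
            self.variants.copy(),
            list(sample_ids),
        )


@dataclass
class FilterReport:
    """Bookkeeping for a filter stage: what was removed, why, with what knobs."""

    stage: str
    n_input: int
    n_retained: int
    removed: dict[str, int] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_retained + sum(self.removed.values()) != self.n_input:
            raise GenodataError("FilterReport does not balance: removed + retained != input")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": self.stage, "criterion": k, "removed": v} for k, v in self.removed.items()]
        rows.append({"stage": self.stage, "criterion": "retained", "removed": self.n_retained})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# frequencies


def allele_frequencies(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant alternate-allele frequency and non-missing allele count.

    Returns ``(p, n_alleles)``; ``p`` is NaN where every call is missing.
    """
    calls = np.asarray(calls)
    obs = calls != MISSING
    n_alleles = 2 * obs.sum(axis=0)
    alt = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return p, n_alleles


def minor_allele_frequency(calls: np.ndarray) -> np.ndarray:
    p, _ = allele_frequencies(calls)
    return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# PED/MAP


def read_ped_map(ped_path, map_path, ref_alleles=None) -> GenotypeMatrix:
    """Read white-space separated PLINK text PED/MAP genotypes.

    Missing genotypes are coded ``0 0`` in the PED and become :data:`MISSING`.
    Allele coding per variant: ``allele1`` is the first allele observed in
    file order and the counted allele is ``allele2``, unless ``ref_alleles``
    supplies explicit ``(allele1, allele2)`` pairs (one per variant), in which
    case calls count the given ``allele2``.
    """
    vmap = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos"], dtype={"chrom": str, "id": str},
    )
    m = len(vmap)
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    a1 = [None] * m
    a2 = [None] * m
    if ref_alleles is not None:
        if len(ref_alleles) != m:
            raise GenodataError("ref_alleles length does not match MAP variant count")
        a1 = [str(a) for a, _ in ref_alleles]
        a2 = [str(b) for _, b in ref_alleles]

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != 6 + 2 * m:
                raise GenodataError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields, got {len(toks)}"
                )
            sid = toks[1]
            if sid in sample_ids:
                raise GenodataError(f"duplicate sample id {sid!r} at line {lineno}")
            sample_ids.append(sid)
            g = np.full(m, MISSING, dtype=np.int16)
            for j in range(m):
                x, y = toks[6 + 2 * j], toks[7 + 2 * j]
                if x == "0" or y == "0":
                    continue
                for al in (x, y):
                    if a1[j] is None:
                        a1[j] = al
                    elif a2[j] is None and al != a1[j]:
                        a2[j] = al
                cnt = 0
                for al in (x, y):
                    if al == a2[j]:
                        cnt += 1
                    elif al != a1[j]:
                        raise GenodataError(
                            f"line {lineno}, variant {vmap['id'][j]!r}: third allele {al!r}"
                        )
                g[j] = cnt
            rows.append(g)
    if not rows:
        raise GenodataError(f"{ped_path}: no samples")
    variants = pd.DataFrame(
        {
            "chrom": vmap["chrom"],
            "pos": vmap["pos"].astype(np.int64),
            "allele1": [a if a is not None else "0" for a in a1],
            "allele2": [a if a is not None else "0" for a in a2],
            "id": vmap["id"],
        }
    )
    return GenotypeMatrix(np.vstack(rows), variants, pd.DataFrame({"id": sample_ids}))


def write_ped_map(gm: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PED/MAP text; missing calls become ``0 0``."""
    v = gm.variants
    with open(map_path, "w") as fh:
        for _, row in v.iterrows():
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{row['pos']}\n")
    a1 = v["allele1"].to_numpy()
    a2 = v["allele2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.samples["id"]):
            fields = [str(sid), str(sid), "0", "0", "0", "-9"]
            for j, g in enumerate(gm.calls[i]):
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [a1[j], a1[j]]
                elif g == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# phased VCF


def read_vcf_phased(path) -> HaplotypeMatrix:
    """Read a biallelic, fully phased VCF into a :class:`HaplotypeMatrix`.

    Every GT must use the ``|`` separator; ``/`` records and multi-allelic
    records are collected and reported in a single error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    cols: list[np.ndarray] = []
    recs: list[tuple] = []
    unphased: list[str] = []
    multi: list[str] = []
    for var in vcf:
        label = f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            multi.append(label)
            continue
        gts = var.genotypes  # [a0, a1, phased] per sample
        if any((len(g) < 3 or not g[2] or g[0] < 0 or g[1] < 0) for g in gts):
            unphased.append(label)
            continue
        col = np.empty(2 * len(gts), dtype=np.int8)
        for i, g in enumerate(gts):
            col[2 * i] = g[0]
            col[2 * i + 1] = g[1]
        cols.append(col)
        recs.append((var.CHROM, var.POS, var.REF, var.ALT[0], var.ID or f"{var.CHROM}_{var.POS}"))
    vcf.close()
    if multi:
        raise GenodataError(f"multi-allelic records not supported: {', '.join(multi[:10])}")
    if unphased:
        raise GenodataError(
            f"unphased or missing GT records (need '|'): {', '.join(unphased[:10])}"
        )
    if not cols:
        raise GenodataError(f"{path}: no usable records")
    variants = pd.DataFrame(recs, columns=["chrom", "pos", "allele1", "allele2", "id"])
    return HaplotypeMatrix(np.column_stack(cols), variants, sample_ids)


def write_vcf_phased(haps: HaplotypeMatrix, path) -> None:
    """Write a minimal phased VCF v4.2 (uncompressed text)."""
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    for chrom in pd.unique(haps.variants["chrom"]):
        last = haps.variants.loc[haps.variants["chrom"] == chrom, "pos"].max()
        buf.write(f"##contig=<ID={chrom},length={int(last) + 1}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(str(s) for s in haps.sample_ids)
        + "\n"
    )
    A = haps.alleles
    for j, row in haps.variants.iterrows():
        gts = "\t".join(f"{A[2 * i, j]}|{A[2 * i + 1, j]}" for i in range(haps.n_samples))
        buf.write(
            f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['allele1']}\t"
            f"{row['allele2']}\t.\tPASS\t.\tGT\t{gts}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# merging


def merge(a: GenotypeMatrix, b: GenotypeMatrix) -> tuple[GenotypeMatrix, FilterReport]:
    """Merge two cohorts on the intersection of (chromosome, position).

    Alleles are reconciled by swapping (calls recoded ``2 - x``) when ``b``
    carries the same pair in the opposite order.  Variants whose allele pairs
    cannot be reconciled, and strand-ambiguous A/T / C/G variants (which
    cannot be reconciled safely without strand information), are dropped and
    counted in the report.
    """
    shared = set(a.samples["id"]) & set(b.samples["id"])
    if shared:
        raise GenodataError(f"shared sample ids between cohorts: {sorted(shared)[:5]}")
    key_a = {(r.chrom, r.pos): i for i, r in enumerate(a.variants.itertuples())}
    keep_a: list[int] = []
    keep_b: list[int] = []
    flip_b: list[bool] = []
    n_mismatch = 0
    n_ambig = 0
    for ib, r in enumerate(b.variants.itertuples()):
        ia = key_a.get((r.chrom, r.pos))
        if ia is None:
            continue
        ra = a.variants.iloc[ia]
        pair_a = (str(ra["allele1"]), str(ra["allele2"]))
        pair_b = (str(r.allele1), str(r.allele2))
        if frozenset(pair_a) in _AMBIGUOUS:
            n_ambig += 1
            continue
        if pair_a == pair_b:
            keep_a.append(ia)
            keep_b.append(ib)
            flip_b.append(False)
        elif pair_a == pair_b[::-1]:
            keep_a.append(ia)
            keep_b.append(ib)
            flip_b.append(True)
        else:
            n_mismatch += 1
    if not keep_a:
        raise GenodataError("no shared (chromosome, position) variants after reconciliation")
    order = np.argsort(keep_a, kind="stable")
    keep_a = np.asarray(keep_a)[order]
    keep_b = np.asarray(keep_b)[order]
    flip_b = np.asarray(flip_b)[order]
    calls_b = b.calls[:, keep_b].copy()
    flip_cols = np.where(flip_b)[0]
    sub = calls_b[:, flip_cols]
    calls_b[:, flip_cols] = np.where(sub == MISSING, MISSING, 2 - sub)
    merged = GenotypeMatrix(
        np.vstack([a.calls[:, keep_a], calls_b]),
        a.variants.iloc[keep_a].reset_index(drop=True),
        pd.concat([a.samples, b.samples], ignore_index=True),
    )
    n_inter = len(keep_a) + n_mismatch + n_ambig
    report = FilterReport(
        stage="merge",
        n_input=n_inter,
        n_retained=len(keep_a),
        removed={"allele_mismatch": n_mismatch, "strand_ambiguous": n_ambig},
        params={},
    )
    return merged, report


# ---------------------------------------------------------------------------
# HWE


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-degree-of-freedom chi-square Hardy-Weinberg test p-value.

    Expected counts come from the sample allele frequency; monomorphic sites
    return 1.0 by convention.
    """
    counts = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if (counts < 0).any():
        raise GenodataError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise GenodataError("hwe_test requires a positive genotype total")
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([p * p, 2 * p * q, q * q]) * n
    chi2 = float(((counts - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(calls: np.ndarray) -> np.ndarray:
    """Vectorized chi-square HWE p-values per variant (missing-aware)."""
    obs = calls != MISSING
    n0 = ((calls == 0) & obs).sum(axis=0).astype(float)
    n1 = (calls == 1).sum(axis=0).astype(float)
    n2 = (calls == 2).sum(axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n0 + n1) / (2 * np.maximum(n, 1))
        q = 1 - p
        e0, e1, e2 = p * p * n, 2 * p * q * n, q * q * n
        chi2 = np.zeros(calls.shape[1])
        for ob, ex in ((n0, e0), (n1, e1), (n2, e2)):
            chi2 += np.where(ex > 0, (ob - ex) ** 2 / np.maximum(ex, 1e-300), 0.0)
    pv = stats.chi2.sf(chi2, df=1)
    mono = (p == 0) | (q == 0) | (n == 0)
    pv = np.where(mono, 1.0, pv)
    return pv


# ---------------------------------------------------------------------------
# variant filters


def filter_variants(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    max_missing_rate: float = 0.20,
    hwe_alpha: float = 0.005,
    hwe_test_samples: list[str] | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the missingness -> MAF -> HWE filter chain.

    A variant failing several criteria is counted once under the first
    failing criterion in that fixed precedence.  The HWE test runs on the
    designated sample subset (``hwe_test_samples``; the full cohort when
    omitted) and ``hwe_alpha`` is Bonferroni-corrected over the number of
    variants actually tested.  ``hwe_alpha = 0`` disables the HWE filter.
    """
    for name, val in (("maf_min", maf_min), ("max_missing_rate", max_missing_rate),
                      ("hwe_alpha", hwe_alpha)):
        if not 0.0 <= val <= 1.0:
            raise GenodataError(f"{name} must be in [0, 1], got {val}")
    m = gm.n_variants
    miss_rate = (gm.calls == MISSING).mean(axis=0)
    fail_miss = miss_rate > max_missing_rate

    maf = minor_allele_frequency(gm.calls)
    fail_maf = ~fail_miss & (np.nan_to_num(maf, nan=0.0) < maf_min)

    fail_hwe = np.zeros(m, dtype=bool)
    n_tested = 0
    if hwe_alpha > 0:
        if hwe_test_samples is None:
            sub = gm.calls
        else:
            ids = list(gm.samples["id"])
            missing_ids = set(hwe_test_samples) - set(ids)
            if missing_ids:
                raise GenodataError(f"hwe_test_samples not in cohort: {sorted(missing_ids)[:5]}")
            idx = [ids.index(s) for s in hwe_test_samples]
            sub = gm.calls[idx, :]
        testable = ~fail_miss & ~fail_maf
        n_tested = int(testable.sum())
        if n_tested:
            pv = _hwe_pvalues(sub[:, testable])
            alpha = hwe_alpha / n_tested  # Bonferroni over tested variants
            fail_hwe[np.where(testable)[0][pv < alpha]] = True

    keep = ~(fail_miss | fail_maf | fail_hwe)
    if not keep.any():
        raise GenodataError("no variants retained by filter_variants")
    report = FilterReport(
        stage="filter_variants",
        n_input=m,
        n_retained=int(keep.sum()),
        removed={
            "missingness": int(fail_miss.sum()),
            "maf": int(fail_maf.sum()),
            "hwe": int(fail_hwe.sum()),
        },
        params={
            "maf_min": maf_min,
            "max_missing_rate": max_missing_rate,
            "hwe_alpha": hwe_alpha,
            "hwe_variants_tested": n_tested,
        },
    )
    return gm.take_variants(np.where(keep)[0]), report


# ---------------------------------------------------------------------------
# LD pruning


def _window_r2(calls: np.ndarray, widx: np.ndarray) -> np.ndarray:
    """Pairwise genotype-correlation r^2 matrix for one window.

    Missing calls are handled by pairwise-complete correlation; constant
    columns yield r^2 = 0 against everything.
    """
    B = calls[:, widx].astype(float)
    if (B == MISSING).any():
        Bm = np.ma.masked_equal(B, MISSING)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.ma.corrcoef(Bm.T).filled(0.0)
    else:
        sd = B.std(axis=0)
        if (sd == 0).any():
            C = np.zeros((len(widx), len(widx)))
            ok = np.where(sd > 0)[0]
            if len(ok) > 1:
                C[np.ix_(ok, ok)] = np.corrcoef(B[:, ok].T)
        else:
            C = np.corrcoef(B.T)
    R2 = np.nan_to_num(C, nan=0.0) ** 2
    np.fill_diagonal(R2, 0.0)
    return R2


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.5,
) -> np.ndarray:
    """Sliding-window LD pruning; returns indices of retained variants.

    Within each window, while any retained pair exceeds ``r2_max``, the
    later-positioned member of the highest-r^2 pair is removed (among tied
    pairs the one with the later, then the earlier, member latest in the
    window, keeping output deterministic).  Windows advance by
    ``step_snps`` per chromosome.
    """
    if not window_snps > step_snps >= 1:
        raise GenodataError("require window_snps > step_snps >= 1")
    removed = np.zeros(gm.n_variants, dtype=bool)
    chroms = gm.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cidx = np.where(chroms == chrom)[0]
        for start in range(0, len(cidx), step_snps):
            widx = cidx[start:start + window_snps]
            widx = widx[~removed[widx]]
            if len(widx) > 1:
                R2 = _window_r2(gm.calls, widx)
                alive = np.ones(len(widx), dtype=bool)
                while alive.sum() > 1:
                    sub = np.triu(R2 * np.outer(alive, alive), k=1)
                    m = sub.max()
                    if m <= r2_max:
                        break
                    ii, jj = np.where(sub == m)
                    k = np.lexsort((ii, jj))[-1]       # tie: latest pair
                    alive[jj[k]] = False               # drop later-positioned member
                removed[widx[~alive]] = True
            if start + window_snps >= len(cidx):
                break
    return np.where(~removed)[0]
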