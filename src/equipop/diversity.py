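"""Per-individual heterozygosity, inbreeding, and relatedness estimators.

The estimators mirror the classic SNP-array toolkit: observed vs expected
homozygosity and the method-of-moments inbreeding coefficient F (the ``--het``
style estimate), the Fhat3 correlation-based inbreeding coefficient, per-group
diversity summaries with a Levene + Tukey-Kramer comparison of observed
heterozygosity, and genome-wide identity-by-descent (PI_HAT) from
method-of-moments IBS sharing, with a greedy relatedness filter.

Allele frequencies for IBD and Fhat3 default to the full input sample set;
pass an explicit ``freqs`` array to use a different reference panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import MISSING, GenotypeMatrix, allele_frequencies


class DiversityError(ValueError):
    pass


@dataclass
class SampleDiversity:
    sample_id: str
    ho: float          # observed heterozygosity over non-missing calls
    o_hom: int         # observed homozygous count
    e_hom: float       # expected homozygous count under HWE at sample freqs
    n_nonmissing: int
    f: float           # method-of-moments inbreeding coefficient
    fhat3: float | None = None


def individual_heterozygosity(gm: GenotypeMatrix) -> pd.DataFrame:
    """Observed/expected homozygosity and moment F per sample.

    For sample *i* with L non-missing calls, ``Ho = n_het / L``,
    ``E(hom) = sum_j [1 - 2 p_j (1 - p_j) n_j / (n_j - 1)]`` over that
    sample's non-missing variants (``p_j`` the cohort allele frequency and
    ``n_j`` the non-missing allele count at variant *j*), and
    ``F = (O(hom) - E(hom)) / (L - E(hom))``.
    """
    if gm.n_samples < 2:
        raise DiversityError("need >= 2 samples to estimate allele frequencies")
    p, n_alleles = allele_frequencies(gm.calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        # per-variant expected heterozygosity with the small-sample factor
        ehet_j = 2 * p * (1 - p) * n_alleles / np.maximum(n_alleles - 1, 1)
    ehet_j = np.nan_to_num(ehet_j, nan=0.0)
    obs = gm.calls != MISSING
    het = gm.calls == 1
    rows = []
    for i, sid in enumerate(gm.samples["id"]):
        mask = obs[i]
        L = int(mask.sum())
        if L == 0:
            raise DiversityError(f"sample {sid!r} has zero non-missing calls")
        o_het = int(het[i].sum())
        o_hom = L - o_het
        e_hom = float(L - ehet_j[mask].sum())
        denom = L - e_hom
        f = (o_hom - e_hom) / denom if denom != 0 else 0.0
        rows.append(
            {"sample_id": sid, "ho": o_het / L, "o_hom": o_hom, "e_hom": e_hom,
             "n_nonmissing": L, "f": f}
        )
    return pd.DataFrame(rows)


def fhat3(gm: GenotypeMatrix, freqs: np.ndarray | None = None) -> pd.Series:
    """Fhat3 inbreeding coefficient per sample.

    ``Fhat3_i = (1/m) sum_j [x_ij^2 - (1 + 2 p_j) x_ij + 2 p_j^2] /
    (2 p_j (1 - p_j))`` with ``x in {0, 1, 2}``; variants with MAF = 0 are
    excluded and missing calls are skipped with *m* reduced accordingly.
    """
    if freqs is None:
        freqs, _ = allele_frequencies(gm.calls)
    p = np.asarray(freqs, dtype=float)
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    x = gm.calls[:, poly].astype(float)
    p = p[poly]
    obs = x != MISSING
    with np.errstate(invalid="ignore"):
        term = (x * x - (1 + 2 * p) * x + 2 * p * p) / (2 * p * (1 - p))
    term = np.where(obs, term, 0.0)
    m = obs.sum(axis=1)
    if (m == 0).any():
        bad = gm.samples["id"][m == 0].iloc[0]
        raise DiversityError(f"sample {bad!r} has no usable polymorphic calls")
    return pd.Series(term.sum(axis=1) / m, index=gm.samples["id"].to_numpy(), name="fhat3")


def fhat3_outlier_threshold(values: pd.Series, sd_mult: float = 2.0) -> float:
    """Cohort exclusion threshold: mean + ``sd_mult`` * SD of Fhat3."""
    return float(values.mean() + sd_mult * values.std(ddof=1))


def group_diversity(gm: GenotypeMatrix, group_labels) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean Ho, He and mean F, plus pairwise Ho comparisons.

    He per group is the mean over variants of ``2 p (1 - p) n / (n - 1)``
    using within-group frequencies.  Pairwise group differences in per-sample
    Ho use the Tukey-Kramer procedure (reported alongside a Levene test for
    variance heterogeneity).  Groups of fewer than 2 samples are excluded.
    """
    labels = np.asarray(group_labels)
    if len(labels) != gm.n_samples:
        raise DiversityError("group_labels length must match sample count")
    per_sample = individual_heterozygosity(gm)
    groups = []
    ho_by_group: dict[str, np.ndarray] = {}
    for g in pd.unique(labels):
        idx = np.where(labels == g)[0]
        if len(idx) < 2:
            import warnings

            warnings.warn(f"group {g!r} has < 2 samples; excluded from summaries")
            continue
        sub = gm.calls[idx, :]
        p, n_alleles = allele_frequencies(sub)
        ok = n_alleles >= 2
        with np.errstate(invalid="ignore"):
            he_j = 2 * p[ok] * (1 - p[ok]) * n_alleles[ok] / (n_alleles[ok] - 1)
        ho_vals = per_sample["ho"].to_numpy()[idx]
        groups.append(
            {
                "group": g,
                "n": len(idx),
                "mean_ho": float(ho_vals.mean()),
                "he": float(he_j.mean()),
                "mean_f": float(per_sample["f"].to_numpy()[idx].mean()),
            }
        )
        ho_by_group[g] = ho_vals
    summary = pd.DataFrame(groups)
    names = list(ho_by_group)
    comparisons = []
    if len(names) >= 2:
        lev_stat, lev_p = stats.levene(*ho_by_group.values())
        res = stats.tukey_hsd(*ho_by_group.values())
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                comparisons.append(
                    {
                        "group_a": names[a],
                        "group_b": names[b],
                        "mean_diff": float(np.mean(ho_by_group[names[a]]) - np.mean(ho_by_group[names[b]])),
                        "p_tukey": float(res.pvalue[a, b]),
                        "levene_p": float(lev_p),
                    }
                )
    return summary, pd.DataFrame(comparisons)


# ---------------------------------------------------------------------------
# identity by descent


def _expected_ibs_probs(p: np.ndarray) -> dict[str, np.ndarray]:
    """Per-variant P(IBS = s | IBD = k) under random allele draws at freq p."""
    q = 1.0 - p
    return {
        "p00": 2 * p**2 * q**2,
        "p10": 4 * p**3 * q + 4 * p * q**3,
        "p20": p**4 + q**4 + 4 * p**2 * q**2,
        "p11": 2 * p**2 * q + 2 * p * q**2,
        "p21": p**3 + q**3 + p**2 * q + p * q**2,
    }


def pairwise_ibd(gm: GenotypeMatrix, freqs: np.ndarray | None = None) -> pd.DataFrame:
    """Method-of-moments genome-wide IBD; returns a square PI_HAT matrix.

    Observed IBS0/1/2 counts over jointly non-missing variants are equated to
    their expectations given allele frequencies to solve sequentially for
    P(IBD=0), P(IBD=1), P(IBD=2); probabilities are clamped to [0, 1] and
    renormalized.  ``PI_HAT = P(IBD=1)/2 + P(IBD=2)``.
    """
    if freqs is None:
        freqs, _ = allele_frequencies(gm.calls)
    p = np.asarray(freqs, dtype=float)
    informative = np.isfinite(p) & (p > 0) & (p < 1)
    calls = gm.calls[:, informative]
    probs = _expected_ibs_probs(p[informative])
    n = gm.n_samples
    obs = calls != MISSING
    pihat = np.eye(n)
    ids = gm.samples["id"].to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            ok = obs[i] & obs[j]
            m = int(ok.sum())
            if m == 0:
                raise DiversityError(
                    f"samples {ids[i]!r}, {ids[j]!r} share no non-missing variants"
                )
            d = np.abs(calls[i, ok] - calls[j, ok])
            n_ibs0 = float((d == 2).sum())
            n_ibs1 = float((d == 1).sum())
            n_ibs2 = float((d == 0).sum())
            e00 = probs["p00"][ok].sum()
            e10 = probs["p10"][ok].sum()
            e20 = probs["p20"][ok].sum()
            e11 = probs["p11"][ok].sum()
            e21 = probs["p21"][ok].sum()
            p0 = n_ibs0 / e00 if e00 > 0 else 0.0
            p1 = (n_ibs1 - p0 * e10) / e11 if e11 > 0 else 0.0
            p2 = (n_ibs2 - p0 * e20 - p1 * e21) / m
            vec = np.clip([p0, p1, p2], 0.0, 1.0)
            tot = vec.sum()
            if tot > 0:
                vec = vec / tot
            pihat[i, j] = pihat[j, i] = vec[1] / 2 + vec[2]
    return pd.DataFrame(pihat, index=ids, columns=ids)


def relatedness_filter(rel: pd.DataFrame, ibd_max: float = 0.25) -> list:
    """Greedy conflict removal: repeatedly drop the sample in the most pairs
    with PI_HAT >= ``ibd_max`` (tie: the later sample in input order) until no
    such pair remains.  Returns retained sample ids in input order.
    """
    mat = rel.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise DiversityError("relatedness matrix must be square and symmetric")
    n = mat.shape[0]
    conflict = (mat >= ibd_max).astype(bool)
    np.fill_diagonal(conflict, False)
    alive = np.ones(n, dtype=bool)
    while True:
        deg = (conflict & alive[None, :] & alive[:, None]).sum(axis=1)
        deg[~alive] = 0
        if deg.max() == 0:
            break
        worst = np.where(deg == deg.max())[0][-1]  # tie: later sample
        alive[worst] = False
    return [rel.index[i] for i in range(n) if alive[i]]
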