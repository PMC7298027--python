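"""Population differentiation: Weir-Cockerham F_ST and hierarchical AMOVA.

``wc_fst`` implements the Weir & Cockerham (1984) multi-locus theta as a
ratio of sums of the per-variant variance components a (among populations),
b (among individuals within populations) and c (within individuals), with
missing-aware per-variant sample sizes.  ``amova`` implements the
Excoffier-style four-level decomposition of allele-level squared differences
(among groups / among populations within groups / among individuals within
populations / within individuals) with variance components obtained from the
general unbalanced nested random-effects expected-mean-square equations.

Significance for both comes from label permutations with the +1 correction,
so a p-value is never exactly zero: the smallest attainable value with
``n_perm`` permutations is ``1 / (n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix


class DifferentiationError(ValueError):
    pass


@dataclass
class Hierarchy:
    """Sample -> population -> group nesting for AMOVA."""

    sample_to_pop: dict[str, str]
    pop_to_group: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.sample_to_pop.values()) - set(self.pop_to_group)
        if missing:
            raise DifferentiationError(f"populations without a group: {sorted(missing)}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Hierarchy":
        """Build from a 3-column table (sample, population, group)."""
        s2p = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        p2g: dict[str, str] = {}
        for _, row in df.iterrows():
            pop, grp = row.iloc[1], row.iloc[2]
            if pop in p2g and p2g[pop] != grp:
                raise DifferentiationError(f"population {pop!r} assigned to two groups")
            p2g[pop] = grp
        return cls(s2p, p2g)


@dataclass
class AmovaResult:
    components: dict[str, float]       # sigma2 for among_groups, among_pops, among_individuals, within_individuals
    percentages: dict[str, float]
    phi: dict[str, float]              # phi_CT, phi_SC, phi_IS, phi_IT
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    degenerate_levels: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Weir-Cockerham


def _wc_components(calls: np.ndarray, membership: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant W&C (a, b, c) for the two populations coded in membership.

    ``membership`` is (n_samples, 2) one-hot.  Variants where either
    population has no data, or that are monomorphic overall, yield NaN.
    """
    obs = (calls != MISSING).astype(float)
    x = np.where(calls == MISSING, 0, calls).astype(float)
    het = (calls == 1).astype(float)

    n_i = membership.T @ obs                      # (2, m) samples with data
    alt_i = membership.T @ x                      # alt allele counts * 1 (genotype sums)
    het_i = membership.T @ het
    valid = (n_i >= 1).all(axis=0) & (n_i.sum(axis=0) > 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = alt_i / (2 * n_i)
        h_i = het_i / n_i
        r = 2.0
        n_bar = n_i.mean(axis=0)
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
        inner = p_bar * (1 - p_bar) - ((r - 1) / r) * s2
        a = (n_bar / n_c) * (s2 - (inner - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (inner - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar)
        c = h_bar / 2
    poly = valid & (p_bar > 0) & (p_bar < 1)
    a = np.where(poly, a, np.nan)
    b = np.where(poly, b, np.nan)
    c = np.where(poly, c, np.nan)
    return a, b, c


def wc_fst(gm: GenotypeMatrix, pop_labels) -> float:
    """Multi-locus Weir-Cockerham theta between exactly two populations."""
    labels = np.asarray(pop_labels)
    pops = pd.unique(labels)
    if len(pops) != 2:
        raise DifferentiationError(f"wc_fst requires exactly 2 populations, got {len(pops)}")
    for p in pops:
        if (labels == p).sum() < 2:
            raise DifferentiationError(f"population {p!r} has < 2 samples")
    membership = np.column_stack([(labels == p).astype(float) for p in pops])
    a, b, c = _wc_components(gm.calls, membership)
    ok = np.isfinite(a)
    if not ok.any():
        raise DifferentiationError("no polymorphic variants between the two populations")
    denom = np.nansum(a + b + c)
    if denom == 0:
        raise DifferentiationError("zero total variance; theta undefined")
    return float(np.nansum(a) / denom)


def fst_permutation(gm: GenotypeMatrix, pop_labels, n_perm: int = 20000, seed: int = 0) -> tuple[float, float]:
    """Permutation p-value for theta: labels shuffled over samples.

    Returns ``(theta_obs, p)`` with ``p = (1 + #{theta_perm >= theta_obs}) /
    (1 + n_perm)``.
    """
    labels = np.asarray(pop_labels)
    theta_obs = wc_fst(gm, labels)
    rng = np.random.default_rng(seed)
    pops = pd.unique(labels)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        membership = np.column_stack([(perm == p).astype(float) for p in pops])
        a, b, c = _wc_components(gm.calls, membership)
        denom = np.nansum(a + b + c)
        theta = np.nansum(a) / denom if denom != 0 else -np.inf
        if theta >= theta_obs:
            exceed += 1
    return theta_obs, (1 + exceed) / (1 + n_perm)


# ---------------------------------------------------------------------------
# AMOVA


def _amova_sums(calls: np.ndarray, ind_pop: np.ndarray, pop_group: np.ndarray):
    """Pooled nested sums of squares and EMS coefficients over variants.

    Observations are the two allele copies per individual (0/1 coded);
    individuals missing at a variant are dropped for that variant only.
    Returns (SS, df, K) dictionaries pooled over variants, where K holds the
    coefficients of the expected-mean-square linear system.
    """
    n_ind, m = calls.shape
    P = pop_group.shape[0]
    # one-hot matrices
    IP = np.zeros((n_ind, P))
    IP[np.arange(n_ind), ind_pop] = 1.0
    G = int(pop_group.max()) + 1
    PG = np.zeros((P, G))
    PG[np.arange(P), pop_group] = 1.0
    IG = IP @ PG

    obs = (calls != MISSING).astype(float)
    x = np.where(calls == MISSING, 0, calls).astype(float)
    het = (calls == 1).astype(float)

    # per-variant allele totals at each nesting level
    n_c = 2 * obs                                  # alleles per individual (0 or 2)
    N_p = IP.T @ n_c                               # (P, m)
    N_g = IG.T @ n_c                               # (G, m)
    N = n_c.sum(axis=0)                            # (m,)
    X_p = IP.T @ x
    X_g = IG.T @ x
    X = x.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        T_obs = X                                  # alleles are 0/1 so sum of squares = sum
        T_C = (x * x / 2.0) * obs                  # guard: missing -> 0
        T_C = T_C.sum(axis=0)
        T_B = np.where(N_p > 0, X_p**2 / np.maximum(N_p, 1), 0.0).sum(axis=0)
        T_A = np.where(N_g > 0, X_g**2 / np.maximum(N_g, 1), 0.0).sum(axis=0)
        T_mu = np.where(N > 0, X**2 / np.maximum(N, 1), 0.0)

    ss = {
        "d": T_obs - T_C,        # within individuals
        "c": T_C - T_B,          # among individuals within populations
        "b": T_B - T_A,          # among populations within groups
        "a": T_A - T_mu,         # among groups
    }
    I_v = obs.sum(axis=0)                          # individuals with data
    P_v = (N_p > 0).sum(axis=0)                    # populations with data
    G_v = (N_g > 0).sum(axis=0)
    df = {
        "d": I_v,                                  # N - I = 2I - I
        "c": I_v - P_v,
        "b": P_v - G_v,
        "a": G_v - 1,
    }

    # EMS coefficients via sums of squared cell sizes
    n_c2 = n_c**2                                  # 4 per observed individual
    Sc_b = IP.T @ n_c2                             # sum over inds in pop of n_c^2
    Sc_a = IG.T @ n_c2
    Sb_a = PG.T @ (N_p**2)                         # (G, m)
    with np.errstate(invalid="ignore", divide="ignore"):
        rb = np.where(N_p > 0, Sc_b / np.maximum(N_p, 1), 0.0).sum(axis=0)
        ra = np.where(N_g > 0, Sc_a / np.maximum(N_g, 1), 0.0).sum(axis=0)
        rba = np.where(N_g > 0, Sb_a / np.maximum(N_g, 1), 0.0).sum(axis=0)
        r0 = np.where(N > 0, n_c2.sum(axis=0) / np.maximum(N, 1), 0.0)
        rb0 = np.where(N > 0, (N_p**2).sum(axis=0) / np.maximum(N, 1), 0.0)
        ra0 = np.where(N > 0, (N_g**2).sum(axis=0) / np.maximum(N, 1), 0.0)
    K = {
        "c_c": N - rb,                             # coeff of sigma2_c in E[SS_c]
        "b_b": N - rba,                            # coeff of sigma2_b in E[SS_b]
        "b_c": rb - ra,
        "a_a": N - ra0,
        "a_b": rba - rb0,
        "a_c": ra - r0,
    }
    pooled_ss = {k: float(np.nansum(v)) for k, v in ss.items()}
    pooled_df = {k: float(np.nansum(v)) for k, v in df.items()}
    pooled_K = {k: float(np.nansum(v)) for k, v in K.items()}
    return pooled_ss, pooled_df, pooled_K


def _solve_components(ss, df, K) -> dict[str, float]:
    s_d = ss["d"] / df["d"] if df["d"] > 0 else 0.0
    s_c = (ss["c"] - df["c"] * s_d) / K["c_c"] if K["c_c"] > 0 else 0.0
    s_b = (ss["b"] - df["b"] * s_d - K["b_c"] * s_c) / K["b_b"] if K["b_b"] > 0 else 0.0
    s_a = (
        (ss["a"] - df["a"] * s_d - K["a_c"] * s_c - K["a_b"] * s_b) / K["a_a"]
        if K["a_a"] > 0
        else 0.0
    )
    return {
        "among_groups": s_a,
        "among_pops": s_b,
        "among_individuals": s_c,
        "within_individuals": s_d,
    }


def _encode_hierarchy(gm: GenotypeMatrix, hierarchy: Hierarchy):
    ids = gm.samples["id"].tolist()
    unassigned = [s for s in ids if s not in hierarchy.sample_to_pop]
    if unassigned:
        raise DifferentiationError(f"samples without a population: {unassigned[:5]}")
    pops = sorted({hierarchy.sample_to_pop[s] for s in ids})
    groups = sorted({hierarchy.pop_to_group[p] for p in pops})
    pop_idx = {p: i for i, p in enumerate(pops)}
    grp_idx = {g: i for i, g in enumerate(groups)}
    ind_pop = np.array([pop_idx[hierarchy.sample_to_pop[s]] for s in ids])
    pop_group = np.array([grp_idx[hierarchy.pop_to_group[p]] for p in pops])
    return ind_pop, pop_group, pops, groups


def amova(
    gm: GenotypeMatrix,
    hierarchy: Hierarchy,
    n_perm: int = 0,
    seed: int = 0,
) -> AmovaResult:
    """Four-level AMOVA with optional per-level permutation tests.

    Permutation schemes per level: alleles among individuals within
    populations (within-individual / Phi_IS level), individuals among
    populations within groups (Phi_SC level), whole populations among groups
    (Phi_CT level).  Negative component estimates are reported as estimated
    (they can be slightly negative by sampling); percentages use the total of
    the raw components.
    """
    ind_pop, pop_group, pops, groups = _encode_hierarchy(gm, hierarchy)
    for i, p in enumerate(pops):
        if (ind_pop == i).sum() < 2:
            raise DifferentiationError(f"population {p!r} has < 2 individuals")
    if len(groups) < 2:
        raise DifferentiationError("need >= 2 groups")

    ss, df, K = _amova_sums(gm.calls, ind_pop, pop_group)
    comps = _solve_components(ss, df, K)
    degenerate = []
    if df["b"] == 0:
        comps["among_pops"] = 0.0
        degenerate.append("among_pops")
    if df["a"] == 0:
        comps["among_groups"] = 0.0
        degenerate.append("among_groups")
    total = sum(comps.values())
    perc = {k: 100.0 * v / total for k, v in comps.items()}
    s_a, s_b, s_c, s_d = (
        comps["among_groups"],
        comps["among_pops"],
        comps["among_individuals"],
        comps["within_individuals"],
    )
    phi = {
        "phi_CT": s_a / total if total else np.nan,
        "phi_SC": s_b / (s_b + s_c + s_d) if (s_b + s_c + s_d) else np.nan,
        "phi_IS": s_c / (s_c + s_d) if (s_c + s_d) else np.nan,
        "phi_IT": (s_a + s_b + s_c) / total if total else np.nan,
    }

    p_values: dict[str, float] = {}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = {"among_groups": 0, "among_pops": 0, "among_individuals": 0}

        # level a: permute whole populations among groups
        for _ in range(n_perm):
            pg = rng.permutation(pop_group)
            c = _solve_components(*_amova_sums(gm.calls, ind_pop, pg))
            if c["among_groups"] >= s_a:
                exceed["among_groups"] += 1

        # level b: permute individuals among populations within their group
        grp_of_ind = pop_group[ind_pop]
        for _ in range(n_perm):
            ip = ind_pop.copy()
            for g in range(int(pop_group.max()) + 1):
                idx = np.where(grp_of_ind == g)[0]
                ip[idx] = ip[idx][rng.permutation(len(idx))]
            c = _solve_components(*_amova_sums(gm.calls, ip, pop_group))
            if c["among_pops"] >= s_b:
                exceed["among_pops"] += 1

        # level c: permute alleles among individuals within populations
        for _ in range(n_perm):
            calls_p = _permute_alleles_within_pops(gm.calls, ind_pop, rng)
            c = _solve_components(*_amova_sums(calls_p, ind_pop, pop_group))
            if c["among_individuals"] >= s_c:
                exceed["among_individuals"] += 1

        p_values = {k: (1 + v) / (1 + n_perm) for k, v in exceed.items()}

    return AmovaResult(
        components=comps,
        percentages=perc,
        phi=phi,
        p_values=p_values,
        n_permutations=n_perm,
        degenerate_levels=degenerate,
    )


def _permute_alleles_within_pops(calls: np.ndarray, ind_pop: np.ndarray, rng) -> np.ndarray:
    """Reassort allele copies randomly among individuals within each
    population, independently per variant (missing individuals keep missing).
    """
    out = calls.copy()
    for p in np.unique(ind_pop):
        idx = np.where(ind_pop == p)[0]
        sub = calls[idx, :]
        obs = sub != MISSING
        k = len(idx)
        # expand genotypes to two allele rows, shuffle columns independently
        al = np.zeros((2 * k, sub.shape[1]), dtype=np.int8)
        al[0::2] = np.where(obs, (sub >= 1).astype(np.int8), 0)
        al[1::2] = np.where(obs, (sub == 2).astype(np.int8), 0)
        alive = np.repeat(obs, 2, axis=0)
        order = np.argsort(rng.random(al.shape) + (~alive) * 10.0, axis=0, kind="stable")
        shuffled = np.take_along_axis(al, order, axis=0)
        # re-pair consecutive alleles into genotypes; rows beyond the observed
        # count are padding (within-population placement does not affect any SS)
        geno = (shuffled[0::2] + shuffled[1::2]).astype(calls.dtype)
        n_obs_per_var = obs.sum(axis=0)
        padded = np.where(np.arange(k)[:, None] < n_obs_per_var[None, :], geno, MISSING)
        slot = np.argsort(~obs, axis=0, kind="stable")      # observed rows first
        inv = np.argsort(slot, axis=0, kind="stable")
        out[idx, :] = np.take_along_axis(padded, inv, axis=0)
    return out
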