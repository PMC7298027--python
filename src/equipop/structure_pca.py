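"""PCA of standardized genotypes for population-structure visualization.

Matches the R ``prcomp(scale = TRUE)`` convention: samples are rows, variants
are columns, each variant column is centered and scaled to unit variance
(ddof = 1), and scores come from the SVD.  Because the SVD sign is arbitrary
and downstream sample-selection rules are sign-dependent, each component's
sign is fixed so that its largest-magnitude loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix


class PcaError(ValueError):
    pass


@dataclass
class PcaResult:
    scores: pd.DataFrame          # samples x PC1..PCk
    loadings: np.ndarray          # variants x k
    percent_variance: np.ndarray  # length k
    center: np.ndarray
    scale: np.ndarray
    kept_variants: np.ndarray     # indices of non-monomorphic variants used


def pca(gm: GenotypeMatrix, k: int = 10, impute_mean: bool = False) -> PcaResult:
    """Principal components of the standardized genotype matrix.

    Missing calls are an error unless ``impute_mean=True`` (the analysis is
    meant to run on complete-genotyping data); monomorphic variants carry no
    information after scaling and are dropped (their indices are recorded).
    """
    X = gm.calls.astype(float)
    miss = X == MISSING
    if miss.any():
        if not impute_mean:
            raise PcaError(
                "missing calls present; filter to complete genotyping first "
                "or pass impute_mean=True"
            )
        X = np.where(miss, np.nan, X)
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean[None, :], X)
    n, m = X.shape
    if n < 2:
        raise PcaError("need >= 2 samples")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    X = X[:, keep]
    sd = sd[keep]
    if X.shape[1] == 0:
        raise PcaError("all variants monomorphic")
    kmax = min(n - 1, X.shape[1])
    if k > kmax:
        raise PcaError(f"k = {k} exceeds min(n - 1, m) = {kmax}")
    center = X.mean(axis=0)
    Z = (X - center) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    # fix signs: largest-magnitude loading of each component positive
    V = Vt.T[:, :k]
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    V = V * flip
    scores = (U[:, :k] * S[:k]) * flip
    eig = S**2 / (n - 1)
    pct = 100.0 * eig[:k] / eig.sum()
    scores_df = pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(k)], index=gm.samples["id"].to_numpy()
    )
    return PcaResult(
        scores=scores_df,
        loadings=V,
        percent_variance=pct,
        center=center,
        scale=sd,
        kept_variants=np.where(keep)[0],
    )


class _GuardedScores(dict):
    def __missing__(self, key):
        raise PcaError(f"unknown component name {key!r}")


def select_by_pc(result: PcaResult, predicate) -> list:
    """Samples whose scores satisfy ``predicate``.

    ``predicate`` is a callable receiving a mapping of component name
    (``"PC1"`` ...) to that sample's score; referencing an unknown component
    raises.  Comparisons are as written in the predicate (a strict ``<`` at a
    boundary excludes the boundary sample).
    """
    selected = []
    cols = list(result.scores.columns)
    for sid, row in result.scores.iterrows():
        env = _GuardedScores({c: float(row[c]) for c in cols})
        if predicate(env):
            selected.append(sid)
    return selected
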