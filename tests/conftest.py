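import numpy as np
import pandas as pd
import pytest

from equipop import genodata as gd
from equipop import synthpop as sp


def make_gm(calls, positions=None, chrom="1", sample_ids=None, **sample_cols):
    """Hand-build a GenotypeMatrix from a nested list / array of calls."""
    calls = np.asarray(calls)
    n, m = calls.shape
    if positions is None:
        positions = 1 + 1000 * np.arange(m)
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(positions, dtype=np.int64),
         "allele1": "A", "allele2": "G", "id": [f"v{j}" for j in range(m)]}
    )
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    samples = pd.DataFrame({"id": sample_ids, **sample_cols})
    return gd.GenotypeMatrix(calls, variants, samples)


def make_haps(alleles, positions=None, chrom="1"):
    alleles = np.asarray(alleles, dtype=np.int8)
    n, m = alleles.shape
    assert n % 2 == 0
    if positions is None:
        positions = 1 + 1000 * np.arange(m)
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(positions, dtype=np.int64),
         "allele1": "A", "allele2": "G", "id": [f"v{j}" for j in range(m)]}
    )
    return gd.HaplotypeMatrix(alleles, variants, [f"s{i}" for i in range(n // 2)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def bn_two_pop_gm():
    """Two Balding-Nichols populations, F = 0.10, 2 x 50 samples, 5000 variants."""
    freqs = sp.bn_frequencies(None, 0.10, 2, 5000, seed=7)
    v = sp.make_variant_table(5000)
    h1 = sp.draw_haplotypes(freqs[0], 100, seed=1, variants=v, sample_prefix="A")
    h2 = sp.draw_haplotypes(freqs[1], 100, seed=2, variants=v, sample_prefix="B")
    calls = np.vstack([h1.to_genotypes().calls, h2.to_genotypes().calls])
    labels = np.array(["A"] * 50 + ["B"] * 50)
    gm = gd.GenotypeMatrix(
        calls, v.copy(),
        pd.DataFrame({"id": [f"A{i}" for i in range(50)] + [f"B{i}" for i in range(50)],
                      "pop": labels}),
    )
    return gm, labels
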