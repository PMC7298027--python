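"""Genotype containers, PED/MAP + VCF I/O, merging and the QC filter chain."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equipop import genodata as gd
from equipop import synthpop as sp

from conftest import make_gm, make_haps


# ---------------------------------------------------------------------------
# containers


def test_genotype_matrix_rejects_bad_calls():
    with pytest.raises(gd.GenodataError):
        make_gm([[0, 3], [1, 2]])


def test_genotype_matrix_rejects_duplicate_sample_ids():
    with pytest.raises(gd.GenodataError, match="duplicate sample"):
        make_gm([[0, 1], [1, 2]], sample_ids=["x", "x"])


def test_genotype_matrix_rejects_unsorted_positions():
    with pytest.raises(gd.GenodataError, match="increasing"):
        make_gm([[0, 1], [1, 2]], positions=[100, 50])


def test_haplotype_collapse_matches_genotypes():
    haps = make_haps([[0, 1, 1], [1, 1, 0], [0, 0, 1], [0, 0, 1]])
    gm = haps.to_genotypes()
    assert gm.calls.tolist() == [[1, 2, 1], [0, 0, 2]]


def test_filter_report_must_balance():
    with pytest.raises(gd.GenodataError):
        gd.FilterReport(stage="x", n_input=10, n_retained=8, removed={"maf": 1})


# ---------------------------------------------------------------------------
# PED/MAP


def test_ped_map_round_trip_hand_built(tmp_path):
    """A 2-sample, 3-variant file with explicit allele coding round-trips."""
    (tmp_path / "t.map").write_text("1\tv0\t0\t100\n1\tv1\t0\t200\n1\tv2\t0\t300\n")
    (tmp_path / "t.ped").write_text(
        "s0 s0 0 0 0 -9 A A A G G G\n"
        "s1 s1 0 0 0 -9 G G A G A A\n"
    )
    gm = gd.read_ped_map(tmp_path / "t.ped", tmp_path / "t.map",
                         ref_alleles=[("A", "G")] * 3)
    assert gm.calls.tolist() == [[0, 1, 2], [2, 1, 0]]
    assert list(gm.samples["id"]) == ["s0", "s1"]


def test_ped_missing_genotype_becomes_sentinel(tmp_path):
    (tmp_path / "t.map").write_text("1\tv0\t0\t100\n1\tv1\t0\t200\n")
    (tmp_path / "t.ped").write_text("s0 s0 0 0 0 -9 A A 0 0\n")
    gm = gd.read_ped_map(tmp_path / "t.ped", tmp_path / "t.map")
    assert (gm.calls == gd.MISSING).sum() == 1
    assert gm.calls[0, 1] == gd.MISSING


def test_ped_ragged_row_raises_with_line_number(tmp_path):
    (tmp_path / "t.map").write_text("1\tv0\t0\t100\n")
    (tmp_path / "t.ped").write_text("s0 s0 0 0 0 -9 A A\ns1 s1 0 0 0 -9 A\n")
    with pytest.raises(gd.GenodataError, match="line 2"):
        gd.read_ped_map(tmp_path / "t.ped", tmp_path / "t.map")


def test_ped_duplicate_sample_id_raises(tmp_path):
    (tmp_path / "t.map").write_text("1\tv0\t0\t100\n")
    (tmp_path / "t.ped").write_text("s0 s0 0 0 0 -9 A A\nf2 s0 0 0 0 -9 A G\n")
    with pytest.raises(gd.GenodataError, match="duplicate sample"):
        gd.read_ped_map(tmp_path / "t.ped", tmp_path / "t.map")


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_ped_map_round_trip_random_matrices(seed):
    import tempfile
    from pathlib import Path

    rng = np.random.default_rng(seed)
    calls = rng.integers(0, 3, size=(4, 12))
    calls[rng.random(calls.shape) < 0.1] = gd.MISSING
    gm = make_gm(calls)
    with tempfile.TemporaryDirectory() as d:
        d = Path(d)
        gd.write_ped_map(gm, d / "x.ped", d / "x.map")
        back = gd.read_ped_map(
            d / "x.ped", d / "x.map",
            ref_alleles=list(zip(gm.variants["allele1"], gm.variants["allele2"])))
    assert np.array_equal(gm.calls, back.calls)
    assert list(back.variants["pos"]) == list(gm.variants["pos"])


def test_ped_map_write_read_write_is_stable(tmp_path):
    """read(write(read(f))) equals read(f) even without explicit alleles."""
    (tmp_path / "t.map").write_text("1\tv0\t0\t100\n1\tv1\t0\t200\n")
    (tmp_path / "t.ped").write_text(
        "s0 s0 0 0 0 -9 A G C C\n"
        "s1 s1 0 0 0 -9 G G C T\n"
    )
    gm = gd.read_ped_map(tmp_path / "t.ped", tmp_path / "t.map")
    gd.write_ped_map(gm, tmp_path / "u.ped", tmp_path / "u.map")
    back = gd.read_ped_map(tmp_path / "u.ped", tmp_path / "u.map")
    assert np.array_equal(gm.calls, back.calls)


# ---------------------------------------------------------------------------
# phased VCF


def test_vcf_single_het_site(tmp_path):
    p = tmp_path / "a.vcf"
    p.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\n"
    )
    haps = gd.read_vcf_phased(p)
    assert haps.alleles.tolist() == [[0], [1]]


def test_vcf_unphased_rejected(tmp_path):
    p = tmp_path / "a.vcf"
    p.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
    )
    with pytest.raises(gd.GenodataError, match="1:100"):
        gd.read_vcf_phased(p)


def test_vcf_round_trip_and_collapse(tmp_path, rng):
    haps = make_haps(rng.integers(0, 2, size=(8, 20)))
    gd.write_vcf_phased(haps, tmp_path / "h.vcf")
    back = gd.read_vcf_phased(tmp_path / "h.vcf")
    assert np.array_equal(haps.alleles, back.alleles)
    assert np.array_equal(haps.positions, back.positions)
    assert np.array_equal(back.to_genotypes().calls, haps.to_genotypes().calls)


# ---------------------------------------------------------------------------
# merge


def test_merge_self_under_renamed_samples():
    gm = make_gm([[0, 1, 2], [2, 1, 0]])
    other = make_gm([[0, 1, 2], [2, 1, 0]], sample_ids=["t0", "t1"])
    merged, report = gd.merge(gm, other)
    assert merged.n_samples == 4
    assert merged.n_variants == 3
    assert sum(report.removed.values()) == 0


def test_merge_swapped_alleles_recoded():
    a = make_gm([[0, 2], [1, 1]])
    b = make_gm([[0, 2], [1, 1]], sample_ids=["t0", "t1"])
    b.variants.loc[1, ["allele1", "allele2"]] = ["G", "A"]  # swapped pair
    merged, _ = gd.merge(a, b)
    # b's calls at the swapped variant are recoded 2 - x
    assert merged.calls[2:, 1].tolist() == [0, 1]
    assert merged.calls[2:, 0].tolist() == [0, 1]


def test_merge_mismatched_alleles_dropped_and_counted():
    a = make_gm([[0, 1], [1, 2]])
    b = make_gm([[0, 1], [1, 2]], sample_ids=["t0", "t1"])
    b.variants.loc[0, ["allele1", "allele2"]] = ["A", "C"]  # a has A/G
    merged, report = gd.merge(a, b)
    assert merged.n_variants == 1
    assert report.removed["allele_mismatch"] == 1


def test_merge_strand_ambiguous_dropped():
    a = make_gm([[0, 1], [1, 2]])
    a.variants.loc[0, ["allele1", "allele2"]] = ["A", "T"]
    b = make_gm([[0, 1], [1, 2]], sample_ids=["t0", "t1"])
    b.variants.loc[0, ["allele1", "allele2"]] = ["A", "T"]
    merged, report = gd.merge(a, b)
    assert report.removed["strand_ambiguous"] == 1
    assert merged.n_variants == 1


def test_merge_shared_sample_ids_rejected():
    gm = make_gm([[0, 1], [1, 2]])
    with pytest.raises(gd.GenodataError, match="shared sample"):
        gd.merge(gm, gm)


def test_merge_symmetric_up_to_sample_order():
    rng = np.random.default_rng(5)
    a = make_gm(rng.integers(0, 3, (3, 8)))
    b = make_gm(rng.integers(0, 3, (4, 8)), sample_ids=[f"t{i}" for i in range(4)])
    ab, _ = gd.merge(a, b)
    ba, _ = gd.merge(b, a)
    sa = ab.samples["id"].tolist()
    order = [ba.samples["id"].tolist().index(s) for s in sa]
    assert np.array_equal(ab.calls, ba.calls[order, :])


# ---------------------------------------------------------------------------
# HWE


@pytest.mark.parametrize(
    "counts,expected",
    [((25, 50, 25), 1.0), ((50, 0, 0), 1.0), ((0, 0, 50), 1.0)],
    ids=["exact-hwe", "monomorphic-ref", "monomorphic-alt"],
)
def test_hwe_trivial_values(counts, expected):
    assert gd.hwe_test(*counts) == pytest.approx(expected)


def test_hwe_het_deficit_is_significant():
    # hand evaluation: p_hat = 0.45, chi2 = 15.52
    p = gd.hwe_test(30, 30, 40)
    assert p < 0.005
    assert p == pytest.approx(8.1688e-05, rel=1e-3)


def test_hwe_zero_total_rejected():
    with pytest.raises(gd.GenodataError):
        gd.hwe_test(0, 0, 0)


def test_hwe_matches_enumeration_oracle_small_totals():
    """Chi-square HWE equals an independent exact-expected-counts evaluation
    for every count triple with total <= 30 (erfc-based 1-df p-value)."""
    for total in range(1, 31):
        for n0 in range(total + 1):
            for n1 in range(total + 1 - n0):
                n2 = total - n0 - n1
                p_impl = gd.hwe_test(n0, n1, n2)
                p = (2 * n0 + n1) / (2 * total)
                if p in (0.0, 1.0):
                    assert p_impl == 1.0
                    continue
                exp = [p * p * total, 2 * p * (1 - p) * total, (1 - p) ** 2 * total]
                chi2 = sum((o - e) ** 2 / e for o, e in zip((n0, n1, n2), exp))
                p_oracle = math.erfc(math.sqrt(chi2 / 2.0))
                assert p_impl == pytest.approx(p_oracle, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# filter_variants


def test_filter_identity_when_disabled():
    gm = make_gm([[0, 1, 2], [2, 1, 0], [1, 1, 1]])
    out, report = gd.filter_variants(gm, maf_min=0.0, max_missing_rate=1.0, hwe_alpha=0.0)
    assert out.n_variants == gm.n_variants
    assert sum(report.removed.values()) == 0


def test_filter_removes_monomorphic_at_maf_threshold():
    calls = np.array([[0, 1, 0, 2, 1], [0, 1, 2, 0, 1], [0, 2, 1, 1, 0], [0, 0, 1, 2, 2]])
    gm = make_gm(calls)
    out, report = gd.filter_variants(gm, maf_min=0.01, max_missing_rate=1.0, hwe_alpha=0.0)
    assert out.n_variants == 4
    assert report.removed["maf"] == 1
    assert "v0" not in list(out.variants["id"])


def test_filter_hwe_bonferroni_matches_oracle(rng):
    """A variant forced to (30, 30, 40) is removed iff its chi-square p-value
    falls below 0.005 / n_tested."""
    n = 100
    calls = rng.integers(0, 3, size=(n, 20))
    forced = np.array([0] * 30 + [1] * 30 + [2] * 40)
    calls[:, 7] = rng.permutation(forced)
    gm = make_gm(calls)
    out, report = gd.filter_variants(gm, maf_min=0.0, max_missing_rate=1.0, hwe_alpha=0.005)
    p_forced = gd.hwe_test(30, 30, 40)
    n_tested = report.params["hwe_variants_tested"]
    should_remove = p_forced < 0.005 / n_tested
    assert ("v7" not in list(out.variants["id"])) == should_remove


def test_filter_precedence_counts_each_variant_once(rng):
    calls = rng.integers(0, 3, size=(10, 30))
    calls[0:8, 3] = gd.MISSING            # missingness failure
    calls[:, 4] = 0                        # MAF failure
    gm = make_gm(calls)
    out, report = gd.filter_variants(gm, maf_min=0.05, max_missing_rate=0.2, hwe_alpha=0.005)
    assert report.n_input == 30
    assert report.n_retained == out.n_variants
    assert sum(report.removed.values()) + report.n_retained == 30
    # retained variants violate no active threshold
    miss = (out.calls == gd.MISSING).mean(axis=0)
    maf = gd.minor_allele_frequency(out.calls)
    assert (miss <= 0.2).all()
    assert (np.nan_to_num(maf) >= 0.05).all()


def test_filter_empty_result_is_error():
    gm = make_gm([[0, 0], [0, 0]])
    with pytest.raises(gd.GenodataError, match="no variants"):
        gd.filter_variants(gm, maf_min=0.05, max_missing_rate=1.0, hwe_alpha=0.0)


# ---------------------------------------------------------------------------
# LD pruning


def _ld_prune_oracle(gm, window_snps, step_snps, r2_max):
    """Plain per-pair greedy re-implementation (independent of the vectorized
    path): highest-r2 pair, ties to the latest (j, then i), remove j."""
    removed = set()
    chroms = gm.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cidx = [i for i in range(gm.n_variants) if chroms[i] == chrom]
        for start in range(0, len(cidx), step_snps):
            widx = [i for i in cidx[start:start + window_snps] if i not in removed]
            while len(widx) > 1:
                best = None
                for a in range(len(widx)):
                    for b in range(a + 1, len(widx)):
                        x = gm.calls[:, widx[a]].astype(float)
                        y = gm.calls[:, widx[b]].astype(float)
                        ok = (x != gd.MISSING) & (y != gd.MISSING)
                        if ok.sum() < 2 or x[ok].std() == 0 or y[ok].std() == 0:
                            r2 = 0.0
                        else:
                            r2 = float(np.corrcoef(x[ok], y[ok])[0, 1]) ** 2
                        key = (r2, widx[b], widx[a])
                        if best is None or key > best:
                            best = key
                if best[0] > r2_max:
                    removed.add(best[1])
                    widx.remove(best[1])
                else:
                    break
            if start + window_snps >= len(cidx):
                break
    return [i for i in range(gm.n_variants) if i not in removed]


def test_ld_prune_keeps_uncorrelated_variants():
    gm = make_gm(np.eye(8, dtype=int) * 2)  # orthogonal indicator columns
    keep = gd.ld_prune(gm, window_snps=4, step_snps=2, r2_max=0.5)
    assert len(keep) == 8


def test_ld_prune_removes_one_of_duplicated_pair(rng):
    calls = rng.integers(0, 3, size=(20, 10))
    calls[:, 7] = calls[:, 6]
    gm = make_gm(calls)
    keep = set(gd.ld_prune(gm, window_snps=5, step_snps=2, r2_max=0.5))
    assert (6 in keep) != (7 in keep)
    assert 6 in keep  # later-positioned member removed


@pytest.mark.parametrize("seed", range(6))
def test_ld_prune_matches_greedy_oracle(seed):
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 3, size=(30, 20))
    # induce correlation blocks so pruning has work to do
    for j in range(1, 20, 3):
        noisy = base[:, j - 1].copy()
        flip = rng.random(30) < 0.2
        noisy[flip] = rng.integers(0, 3, flip.sum())
        base[:, j] = noisy
    gm = make_gm(base)
    keep = gd.ld_prune(gm, window_snps=7, step_snps=3, r2_max=0.3)
    assert list(keep) == _ld_prune_oracle(gm, 7, 3, 0.3)
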