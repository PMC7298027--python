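"""Selection-scan statistics, scaling, peak calling and intersection."""

import numpy as np
import pandas as pd
import pytest

from equipop import sweepscan as sws
from equipop import synthpop as sp

from conftest import make_haps


# ---------------------------------------------------------------------------
# density pruning


def test_density_prune_leaves_sparse_bins_alone():
    pos = np.arange(1, 100_001, 10_000)  # 10 SNPs in the first bin
    keep = sws.density_prune(pos)
    assert len(keep) == len(pos)


def test_density_prune_thins_dense_bin_keeping_ends():
    pos = np.linspace(1, 99_000, 20).astype(np.int64)  # 20 SNPs in one 0.1 Mb bin
    keep = sws.density_prune(pos)
    assert len(keep) == 13
    assert 0 in keep and 19 in keep


def test_density_prune_idempotent(rng):
    pos = np.sort(rng.choice(np.arange(1, 1_000_000), size=400, replace=False))
    once = sws.density_prune(pos)
    twice = sws.density_prune(pos[once])
    assert np.array_equal(pos[once][twice], pos[once])


# ---------------------------------------------------------------------------
# H statistic


def test_h_identical_haplotypes_span():
    pos = [100, 300, 1000]
    haps = make_haps([[0, 1, 0], [0, 1, 0]], positions=pos)
    t = sws.h_scan(haps)
    assert np.allclose(t.raw, 900.0)


def test_h_single_mismatch_tract_boundary():
    # two haplotypes differ only at position 500; at focal 400 the shared
    # tract runs from the first SNP (100) to the mismatch (500)
    pos = [100, 400, 500, 900]
    haps = make_haps([[0, 0, 0, 1], [0, 0, 1, 1]], positions=pos)
    t = sws.h_scan(haps)
    assert t.raw[list(pos).index(400)] == pytest.approx(400.0)
    # at the mismatch itself the pair contributes 0
    assert t.raw[2] == 0.0


@pytest.mark.parametrize("seed", range(4))
def test_h_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    n, m = 6, 30
    A = rng.integers(0, 2, (n, m)).astype(np.int8)
    pos = np.sort(rng.choice(np.arange(1, 50_000), size=m, replace=False))
    haps = make_haps(A, positions=pos)
    t = sws.h_scan(haps)
    assert np.array_equal(t.raw, sws.h_scan_bruteforce(A, pos))


# ---------------------------------------------------------------------------
# H12


def test_h12_monomorphic_window_is_one():
    haps = make_haps(np.zeros((6, 5), dtype=np.int8))
    t = sws.h12_windows(haps, window_snps=5)
    assert t.raw.tolist() == [1.0]


def test_h12_known_frequency_spectrum():
    assert sws.h12_from_counts(np.array([5, 3, 2])) == pytest.approx(0.68)
    assert sws.h12_from_counts(np.ones(10, dtype=int)) == pytest.approx(0.12)


def test_h12_reported_at_center_snp(rng):
    A = rng.integers(0, 2, (8, 10)).astype(np.int8)
    pos = 1 + 100 * np.arange(10)
    t = sws.h12_windows(make_haps(A, positions=pos), window_snps=5)
    assert t.positions.tolist() == [pos[2], pos[7]]  # centers of the two windows


def test_h12_duplicate_haplotype_never_decreases_top_mass(rng):
    A = rng.integers(0, 2, (8, 6)).astype(np.int8)
    t1 = sws.h12_windows(make_haps(A, positions=1 + np.arange(6)), window_snps=6)
    A2 = np.vstack([A, A[0], A[0]])
    t2 = sws.h12_windows(make_haps(A2, positions=1 + np.arange(6)), window_snps=6)
    assert t2.raw[0] >= t1.raw[0] - 0.05
    assert 0 < t1.raw[0] <= 1


# ---------------------------------------------------------------------------
# Tajima's D


def test_tajimas_d_singleton_window_hand_value():
    # n = 4 haplotypes, one singleton site: D = -0.612 by direct evaluation
    assert sws.tajimas_d(np.array([1]), 4) == pytest.approx(-0.6124, abs=1e-4)


def test_tajimas_d_zero_when_pi_equals_theta():
    # n = 4, a1 = 11/6; 8 singleton sites and 3 doubleton sites give
    # pi = 8*(1/2) + 3*(2/3) = 6 = 11 / a1 = theta_W, so D = 0 exactly
    counts = np.array([1] * 8 + [2] * 3)
    assert sws.tajimas_d(counts, 4) == pytest.approx(0.0, abs=1e-12)


def test_tajimas_d_windows_skip_invariant_windows():
    A = np.zeros((4, 10), dtype=np.int8)
    A[0, 7] = 1  # only window 2 has a segregating site
    t = sws.tajimas_d_windows(make_haps(A, positions=1 + np.arange(10)), window_snps=5)
    assert len(t.raw) == 1


def test_tajimas_d_needs_four_haplotypes():
    A = np.zeros((2, 10), dtype=np.int8)
    with pytest.raises(sws.SweepscanError):
        sws.tajimas_d_windows(make_haps(A), window_snps=5)


def test_neutral_sfs_windows_center_d_at_zero():
    haps = sp.neutral_sfs_sites(50, 50_000, seed=13)
    t = sws.tajimas_d_windows(haps, window_snps=100)
    se = t.raw.std(ddof=1) / np.sqrt(len(t.raw))
    assert abs(t.raw.mean()) < 3 * se


# ---------------------------------------------------------------------------
# scaling


def test_scale_track_h_direct_and_d_reflected():
    th = sws.ScanTrack("1", [10, 20, 30], [2.0, 4.0, 6.0], "H")
    assert sws.scale_track(th).scaled.tolist() == [0.0, 0.5, 1.0]
    td = sws.ScanTrack("1", [10, 20, 30], [-2.0, 0.0, 2.0], "D")
    assert sws.scale_track(td).scaled.tolist() == [1.0, 0.5, 0.0]


def test_scale_track_monotonicity(rng):
    raw = rng.normal(size=50)
    t = sws.scale_track(sws.ScanTrack("1", np.arange(1, 51), raw, "H12"))
    assert np.array_equal(np.argsort(t.scaled), np.argsort(raw))


def test_scale_constant_track_is_error():
    with pytest.raises(sws.SweepscanError, match="constant"):
        sws.scale_track(sws.ScanTrack("1", [1, 2], [3.0, 3.0], "H"))


def test_scale_joint_tracks_share_min_max():
    t1 = sws.ScanTrack("1", [1, 2], [0.0, 5.0], "H")
    t2 = sws.ScanTrack("2", [1, 2], [5.0, 10.0], "H")
    s1, s2 = sws.scale_track([t1, t2])
    assert s1.scaled.tolist() == [0.0, 0.5]
    assert s2.scaled.tolist() == [0.5, 1.0]


# ---------------------------------------------------------------------------
# peak calling


def _flat_track(n=200, spacing=10_000):
    pos = 1 + spacing * np.arange(n)
    raw = np.zeros(n)
    return pos, raw


def test_single_spike_yields_single_peak():
    pos, raw = _flat_track()
    raw[100] = 1.0
    t = sws.scale_track(sws.ScanTrack("1", pos, raw, "H"))
    ps = sws.call_peaks(t, percentile=99)
    assert len(ps.intervals) == 1
    iv = ps.intervals.iloc[0]
    assert iv["start"] <= pos[100] <= iv["end"]


def test_nearby_spikes_merged_within_gap():
    pos, raw = _flat_track()
    raw[100] = 1.0
    raw[105] = 0.9  # 50 kb apart at 10 kb spacing
    t = sws.scale_track(sws.ScanTrack("1", pos, raw, "H"))
    ps = sws.call_peaks(t, percentile=99, merge_gap_bp=100_000)
    assert len(ps.intervals) == 1


def test_broad_plateau_excluded():
    pos, raw = _flat_track(n=1500, spacing=10_000)
    raw[100:701] = 1.0  # 6 Mb plateau
    t = sws.scale_track(sws.ScanTrack("1", pos, raw, "H"))
    ps = sws.call_peaks(t, percentile=50, max_span_bp=5_000_000)
    assert len(ps.intervals) == 0


# ---------------------------------------------------------------------------
# intersection


def _peakset(intervals, statistic="H", group="g"):
    df = pd.DataFrame(intervals, columns=["start", "end"])
    df.insert(0, "chrom", "1")
    df["max_scaled"] = 1.0
    return sws.PeakSet(df, statistic, group, threshold=0.9)


def test_identical_peaksets_count_k():
    ps = _peakset([(100, 200), (500, 600)])
    out = sws.intersect_peaks([ps, ps, ps], min_count=3)
    assert list(out["max_count"]) == [3, 3]
    assert set(zip(out["start"], out["end"])) == {(100, 200), (500, 600)}


def test_disjoint_peaksets_have_no_shared_region():
    a = _peakset([(100, 200)])
    b = _peakset([(300, 400)], statistic="H12")
    out = sws.intersect_peaks([a, b], min_count=2)
    assert len(out) == 0


def test_three_tracks_share_common_core():
    a = _peakset([(1000, 5000)])
    b = _peakset([(2000, 6000)], statistic="H12")
    c = _peakset([(2500, 4500)], statistic="D")
    out = sws.intersect_peaks([a, b, c], min_count=3)
    assert len(out) == 1
    assert out.iloc[0]["start"] == 2500 and out.iloc[0]["end"] == 4500
    # headline ranking: highest count first, smaller interval on ties
    out2 = sws.intersect_peaks([a, b, c], min_count=2)
    assert out2.iloc[0]["max_count"] == 3


def test_sweep_fixture_recovery_single_seed():
    """All three scaled statistics peak at the implanted sweep and the
    intersection ranks that region first (the multi-seed version runs in the
    acceptance suite)."""
    rng = np.random.default_rng(0)
    n_snp, spacing = 2500, 8000
    v = sp.make_variant_table(n_snp, spacing_bp=spacing)
    base = sp.draw_haplotypes(rng.uniform(0.05, 0.95, n_snp), 50, seed=100, variants=v)
    locus = 10_000_000
    swept, _ = sp.implant_sweep(base, locus, 0.6, 500_000, seed=200)
    tracks = [sws.scale_track(sws.h_scan(swept)),
              sws.scale_track(sws.h12_windows(swept, 51)),
              sws.scale_track(sws.tajimas_d_windows(swept, 51))]
    for t in tracks:
        assert abs(int(t.positions[np.argmax(t.scaled)]) - locus) <= 250_000
    cand = sws.intersect_peaks([sws.call_peaks(t) for t in tracks], min_count=2)
    top = cand.iloc[0]
    assert top["start"] <= locus <= top["end"]


def test_neutral_windows_rarely_exceed_sweep_threshold():
    """Specificity: neutral-genome H12 windows exceed a sweep genome's
    99th-percentile threshold in < 2.5% of windows."""
    rng = np.random.default_rng(1)
    n_snp, spacing = 2500, 8000
    v = sp.make_variant_table(n_snp, spacing_bp=spacing)
    base = sp.draw_haplotypes(rng.uniform(0.05, 0.95, n_snp), 50, seed=300, variants=v)
    swept, _ = sp.implant_sweep(base, 10_000_000, 0.6, 500_000, seed=301)
    t_sweep = sws.scale_track(sws.h12_windows(swept, 51))
    thr = np.percentile(t_sweep.scaled, 99)
    lo = (-t_sweep.raw if t_sweep.statistic == "D" else t_sweep.raw).min()
    hi = (-t_sweep.raw if t_sweep.statistic == "D" else t_sweep.raw).max()
    neutral = sws.h12_windows(base, 51)
    neutral_scaled = (neutral.raw - lo) / (hi - lo)
    assert (neutral_scaled >= thr).mean() < 0.025


# ---------------------------------------------------------------------------
# annotation


def test_annotate_nested_and_abutting_features(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("1\t150\t250\tGENE_IN\n1\t400\t500\tGENE_ABUT\n")
    regions = pd.DataFrame({"chrom": ["1"], "start": [101], "end": [400]})
    out = sws.annotate_regions(regions, bed)
    # nested feature reported; feature starting exactly at the half-open end excluded
    assert out.iloc[0]["features"] == "GENE_IN"


def test_annotate_malformed_bed_line_number(tmp_path):
    bed = tmp_path / "bad.bed"
    bed.write_text("1\t100\t200\tok\n1\txx\t300\tbad\n")
    with pytest.raises(sws.SweepscanError, match="line 2"):
        sws.annotate_regions(pd.DataFrame({"chrom": ["1"], "start": [1], "end": [10]}), bed)


@pytest.mark.parametrize("seed", range(3))
def test_annotate_matches_all_pairs_oracle(seed, tmp_path):
    rng = np.random.default_rng(seed)
    feats = []
    for i in range(40):
        s = int(rng.integers(0, 10_000))
        feats.append((s, s + int(rng.integers(1, 500)), f"f{i}"))
    bed = tmp_path / "r.bed"
    bed.write_text("".join(f"1\t{s}\t{e}\t{n}\n" for s, e, n in feats))
    regions = pd.DataFrame({
        "chrom": "1",
        "start": rng.integers(1, 9000, size=10),
    })
    regions["end"] = regions["start"] + rng.integers(100, 2000, size=10)
    out = sws.annotate_regions(regions, bed)
    for _, row in out.iterrows():
        lo, hi = row["start"] - 1, row["end"]
        expected = sorted(n for s, e, n in feats if s < hi and e > lo)
        got = row["features"].split(",") if row["features"] else []
        assert got == expected
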