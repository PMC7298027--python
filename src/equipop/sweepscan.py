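"""Haplotype-based selection scans and peak calling.

Three complementary statistics over phased haplotypes:

* **H** — at every SNP, the average base-pair length of pairwise haplotype
  homozygosity tracts around the focal position (elevated under recent
  sweeps);
* **H12** — the haplotype-frequency-spectrum statistic with the top two
  haplotype classes pooled, over fixed-SNP-count windows (sensitive to hard
  and soft sweeps);
* **windowed Tajima's D** — variance-normalized, "reflected" (negated) when
  scaled so that sweep-like diversity deficits appear as peaks.

Tracks are min-max scaled to [0, 1] per statistic per group (genome-wide over
the tracks passed together), peaks are called at a percentile threshold with
broad-region exclusion, and peak sets from several statistics/groups are
intersected to rank candidate regions by how many scans support them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genodata import HaplotypeMatrix


class SweepscanError(ValueError):
    pass


@dataclass
class ScanTrack:
    chrom: str
    positions: np.ndarray            # bp, strictly increasing
    raw: np.ndarray
    statistic: str                   # "H" | "H12" | "D"
    group: str = ""
    window_snps: int | None = None
    scaled: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.positions) != len(self.raw):
            raise SweepscanError("positions and values differ in length")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise SweepscanError("positions must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"chrom": self.chrom, "pos": self.positions, "raw": self.raw,
             "statistic": self.statistic, "group": self.group}
        )
        if self.scaled is not None:
            df["scaled"] = self.scaled
        return df


@dataclass
class PeakSet:
    """Non-overlapping above-threshold intervals from one scaled track.

    Intervals are 1-based inclusive in memory; ``to_bed_frame`` converts to
    the 0-based half-open BED dialect.
    """

    intervals: pd.DataFrame          # chrom, start, end, max_scaled
    statistic: str
    group: str
    threshold: float

    def __post_init__(self) -> None:
        iv = self.intervals
        if len(iv) and not (iv["start"] < iv["end"]).all():
            raise SweepscanError("peak intervals must satisfy start < end")

    def to_bed_frame(self) -> pd.DataFrame:
        df = self.intervals.copy()
        df["start"] = df["start"] - 1
        df["name"] = [f"{self.statistic}:{self.group}" for _ in range(len(df))]
        return df[["chrom", "start", "end", "name", "max_scaled"]]


# ---------------------------------------------------------------------------
# density pruning


def density_prune(positions, max_per_bin: int = 16, keep_per_bin: int = 13,
                  bin_bp: int = 100_000) -> np.ndarray:
    """Thin SNPs in high-density bins; returns indices to keep.

    The chromosome is tiled into non-overlapping ``bin_bp`` bins anchored at
    position 1; a bin containing more than ``max_per_bin`` SNPs retains
    exactly ``keep_per_bin``, chosen evenly spaced by rank within the bin
    (the bin's first and last SNP are always kept).
    """
    pos = np.asarray(positions, dtype=np.int64)
    if len(pos) > 1 and not (np.diff(pos) > 0).all():
        raise SweepscanError("positions must be sorted strictly increasing")
    bins = (pos - 1) // bin_bp
    keep: list[np.ndarray] = []
    for b in np.unique(bins):
        idx = np.where(bins == b)[0]
        if len(idx) <= max_per_bin:
            keep.append(idx)
        else:
            ranks = np.round(np.linspace(0, len(idx) - 1, keep_per_bin)).astype(int)
            keep.append(idx[ranks])
    return np.sort(np.concatenate(keep)) if keep else np.array([], dtype=int)


# ---------------------------------------------------------------------------
# H statistic


def h_scan(haps: HaplotypeMatrix, chrom=None) -> ScanTrack:
    """Average pairwise haplotype homozygosity tract length at every SNP.

    For haplotypes *i*, *j* and focal SNP at position *x*, the shared tract
    runs from the nearest discordant SNP strictly left of *x* (or the first
    SNP of the chromosome) to the nearest discordant SNP strictly right of
    *x* (or the last SNP); a pair discordant at *x* itself contributes 0.
    H(x) is the mean tract length in bp over all pairs.
    """
    A, variants = _on_chrom(haps, chrom)
    n, m = A.shape
    if n < 2 or m < 2:
        raise SweepscanError("need >= 2 haplotypes and >= 2 SNPs")
    pos = variants["pos"].to_numpy(dtype=np.int64)
    focal = np.arange(m)
    total = np.zeros(m, dtype=float)
    for i, j in itertools.combinations(range(n), 2):
        diffs = np.flatnonzero(A[i] != A[j])
        if len(diffs) == 0:
            total += float(pos[-1] - pos[0])
            continue
        idx = np.searchsorted(diffs, focal, side="left")
        at_focal = (idx < len(diffs)) & (diffs[np.minimum(idx, len(diffs) - 1)] == focal)
        left = np.where(idx > 0, pos[diffs[np.maximum(idx - 1, 0)]], pos[0])
        right = np.where(idx < len(diffs), pos[diffs[np.minimum(idx, len(diffs) - 1)]], pos[-1])
        tract = np.where(at_focal, 0.0, (right - left).astype(float))
        total += tract
    h = total / (n * (n - 1) / 2)
    return ScanTrack(chrom=str(variants["chrom"].iloc[0]), positions=pos, raw=h, statistic="H")


def h_scan_bruteforce(alleles: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Reference O(n^2 m^2) evaluation of the H statistic (oracle-grade)."""
    A = np.asarray(alleles)
    pos = np.asarray(positions, dtype=np.int64)
    n, m = A.shape
    out = np.zeros(m)
    for k in range(m):
        s = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                if A[i, k] != A[j, k]:
                    continue
                left = pos[0]
                for q in range(k - 1, -1, -1):
                    if A[i, q] != A[j, q]:
                        left = pos[q]
                        break
                right = pos[m - 1]
                for q in range(k + 1, m):
                    if A[i, q] != A[j, q]:
                        right = pos[q]
                        break
                s += right - left
        out[k] = s / (n * (n - 1) / 2)
    return out


# ---------------------------------------------------------------------------
# windowed statistics


def _on_chrom(haps: HaplotypeMatrix, chrom):
    if chrom is None:
        chroms = pd.unique(haps.variants["chrom"])
        if len(chroms) != 1:
            raise SweepscanError("multiple chromosomes present; pass chrom explicitly")
        chrom = chroms[0]
    mask = (haps.variants["chrom"] == chrom).to_numpy()
    if not mask.any():
        raise SweepscanError(f"no variants on chromosome {chrom!r}")
    return haps.alleles[:, mask], haps.variants.loc[mask].reset_index(drop=True)


def _windows(m: int, window_snps: int):
    """Start indices of non-overlapping full windows (remainder dropped)."""
    return range(0, m - window_snps + 1, window_snps)


def h12_from_counts(counts: np.ndarray) -> float:
    """H12 from haplotype-class counts: pool the top two classes."""
    freq = np.sort(counts / counts.sum())[::-1]
    top2 = freq[:2].sum()
    rest = freq[2:]
    return float(top2**2 + (rest**2).sum())


def h12_windows(haps: HaplotypeMatrix, window_snps: int = 351, chrom=None) -> ScanTrack:
    """H12 over non-overlapping windows of ``window_snps`` SNPs.

    Haplotypes are grouped within a window by exact allele-string identity;
    with class frequencies p1 >= p2 >= ..., H12 = (p1 + p2)^2 + sum_{i>=3}
    p_i^2, reported at the window's center SNP position.
    """
    A, variants = _on_chrom(haps, chrom)
    m = A.shape[1]
    pos = variants["pos"].to_numpy(dtype=np.int64)
    if m < window_snps:
        import warnings

        warnings.warn("fewer SNPs than one window; empty H12 track")
        return ScanTrack(chrom=str(variants["chrom"].iloc[0]), positions=np.array([], dtype=np.int64),
                         raw=np.array([]), statistic="H12", window_snps=window_snps)
    centers, vals = [], []
    for s in _windows(m, window_snps):
        W = A[:, s:s + window_snps]
        _, counts = np.unique(W, axis=0, return_counts=True)
        vals.append(h12_from_counts(counts))
        centers.append(pos[s + window_snps // 2])
    return ScanTrack(chrom=str(variants["chrom"].iloc[0]), positions=np.array(centers),
                     raw=np.array(vals), statistic="H12", window_snps=window_snps)


def tajima_constants(n: int) -> dict[str, float]:
    """The standard variance-normalization constants for n sampled sequences."""
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": c1 / a1, "e2": c2 / (a1**2 + a2)}


def tajimas_d(counts: np.ndarray, n: int) -> float:
    """Variance-normalized Tajima's D from derived-allele counts at the
    segregating sites of one window (``counts`` in 1..n-1)."""
    counts = np.asarray(counts, dtype=float)
    S = len(counts)
    if S == 0:
        return np.nan
    k = tajima_constants(n)
    pi = float((2.0 * counts * (n - counts) / (n * (n - 1))).sum())
    theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return np.nan
    return (pi - theta_w) / np.sqrt(var)


def tajimas_d_windows(haps: HaplotypeMatrix, window_snps: int = 351, chrom=None) -> ScanTrack:
    """Windowed Tajima's D at window-center SNPs; S = 0 windows emit nothing."""
    A, variants = _on_chrom(haps, chrom)
    n, m = A.shape
    if n < 4:
        raise SweepscanError("Tajima's D needs >= 4 haplotypes")
    pos = variants["pos"].to_numpy(dtype=np.int64)
    counts_all = A.sum(axis=0)
    centers, vals = [], []
    for s in _windows(m, window_snps):
        c = counts_all[s:s + window_snps]
        seg = c[(c > 0) & (c < n)]
        d = tajimas_d(seg, n)
        if np.isfinite(d):
            centers.append(pos[s + window_snps // 2])
            vals.append(d)
    return ScanTrack(chrom=str(variants["chrom"].iloc[0]), positions=np.array(centers, dtype=np.int64),
                     raw=np.array(vals), statistic="D", window_snps=window_snps)


# ---------------------------------------------------------------------------
# scaling and peak calling


def scale_track(track: ScanTrack | list[ScanTrack]) -> ScanTrack | list[ScanTrack]:
    """Min-max scale raw values to [0, 1]; D is negated ("reflected") first.

    Pass a list to scale several chromosomes of one statistic/group jointly
    (one genome-wide min/max, hence one genome-wide threshold downstream).
    """
    tracks = track if isinstance(track, list) else [track]
    if not tracks:
        raise SweepscanError("no tracks to scale")
    stat = tracks[0].statistic
    if any(t.statistic != stat for t in tracks):
        raise SweepscanError("cannot scale mixed statistics together")
    raw = np.concatenate([t.raw for t in tracks])
    vals = -raw if stat == "D" else raw
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise SweepscanError("constant track cannot be scaled")
    out = []
    for t in tracks:
        v = -t.raw if stat == "D" else t.raw
        out.append(replace(t, scaled=(v - lo) / (hi - lo)))
    return out if isinstance(track, list) else out[0]


def call_peaks(
    track: ScanTrack,
    percentile: float = 99.0,
    max_span_bp: int = 5_000_000,
    merge_gap_bp: int = 100_000,
    threshold: float | None = None,
) -> PeakSet:
    """Peaks = runs of consecutive above-threshold positions.

    The threshold defaults to the given percentile of the track's scaled
    values (pass ``threshold`` to reuse a genome-wide value).  Runs separated
    by less than ``merge_gap_bp`` are merged; intervals spanning more than
    ``max_span_bp`` are discarded as broad, less-specific signals.
    Single-position runs are widened by half the median inter-position
    spacing on each side.
    """
    if track.scaled is None:
        raise SweepscanError("track must be scaled before peak calling")
    thr = float(np.percentile(track.scaled, percentile)) if threshold is None else threshold
    above = track.scaled >= thr
    pos = track.positions
    half = max(int(np.median(np.diff(pos)) // 2), 1) if len(pos) > 1 else 1
    runs = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            start, end = int(pos[i]), int(pos[j])
            peak_val = float(track.scaled[i:j + 1].max())
            if start == end:
                start, end = start - half, end + half
            runs.append([start, end, peak_val])
            i = j + 1
        else:
            i += 1
    merged: list[list] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < merge_gap_bp:
            merged[-1][1] = run[1]
            merged[-1][2] = max(merged[-1][2], run[2])
        else:
            merged.append(run)
    kept = [r for r in merged if r[1] - r[0] <= max_span_bp]
    iv = pd.DataFrame(kept, columns=["start", "end", "max_scaled"])
    iv.insert(0, "chrom", track.chrom)
    return PeakSet(intervals=iv, statistic=track.statistic, group=track.group, threshold=thr)


def intersect_peaks(peaksets: list[PeakSet], min_count: int = 2) -> pd.DataFrame:
    """Overlap count across peak sets; candidate regions ranked by support.

    Returns maximal intervals where at least ``min_count`` of the input peak
    sets overlap, with columns ``chrom, start, end, max_count``, sorted so the
    headline region (highest count; tie broken toward the smallest interval)
    comes first.
    """
    if len(peaksets) < 2:
        raise SweepscanError("need >= 2 peak sets to intersect")
    events: dict[str, list[tuple[int, int]]] = {}
    for ps in peaksets:
        for _, r in ps.intervals.iterrows():
            # closed bp intervals -> half-open arithmetic
            events.setdefault(r["chrom"], []).append((int(r["start"]), +1))
            events[r["chrom"]].append((int(r["end"]) + 1, -1))
    regions = []
    for chrom, evs in events.items():
        evs.sort()
        depth = 0
        segs = []  # (start, end, depth) elementary half-open segments
        last = None
        for x, delta in evs:
            if last is not None and x > last and depth > 0:
                segs.append((last, x, depth))
            depth += delta
            last = x
        cur = None
        for s, e, d in segs:
            if d >= min_count:
                if cur is not None and s == cur[1]:
                    cur = (cur[0], e, max(cur[2], d))
                else:
                    if cur is not None:
                        regions.append((chrom, cur[0], cur[1] - 1, cur[2]))
                    cur = (s, e, d)
            else:
                if cur is not None:
                    regions.append((chrom, cur[0], cur[1] - 1, cur[2]))
                    cur = None
        if cur is not None:
            regions.append((chrom, cur[0], cur[1] - 1, cur[2]))
    df = pd.DataFrame(regions, columns=["chrom", "start", "end", "max_count"])
    if len(df):
        df["span"] = df["end"] - df["start"]
        df = df.sort_values(["max_count", "span"], ascending=[False, True]).drop(columns="span")
        df = df.reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# gene annotation


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader (chrom, start, end[, name]); 0-based half-open."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            toks = line.split("\t") if "\t" in line else line.split()
            if len(toks) < 3:
                raise SweepscanError(f"{path}: line {lineno}: need >= 3 BED fields")
            try:
                start, end = int(toks[1]), int(toks[2])
            except ValueError as exc:
                raise SweepscanError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise SweepscanError(f"{path}: line {lineno}: start >= end")
            rows.append({"chrom": toks[0], "start": start, "end": end,
                         "name": toks[3] if len(toks) > 3 else f"feature_{lineno}"})
    return pd.DataFrame(rows)


def annotate_regions(regions: pd.DataFrame, bed_path) -> pd.DataFrame:
    """Features (from a BED file) overlapping each region by >= 1 bp.

    Regions use the package's 1-based inclusive convention; BED features are
    0-based half-open, so a feature abutting a region end is excluded.
    """
    from intervaltree import IntervalTree

    bed = read_bed(bed_path)
    trees: dict[str, IntervalTree] = {}
    for _, r in bed.iterrows():
        trees.setdefault(r["chrom"], IntervalTree()).addi(r["start"], r["end"], r["name"])
    out = []
    for _, region in regions.iterrows():
        lo = int(region["start"]) - 1  # to half-open
        hi = int(region["end"])
        tree = trees.get(region["chrom"])
        hits = sorted(h.data for h in tree.overlap(lo, hi)) if tree is not None else []
        out.append({"chrom": region["chrom"], "start": region["start"],
                    "end": region["end"], "features": ",".join(hits), "n_features": len(hits)})
    return pd.DataFrame(out)
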