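"""Genomic islands of divergence and valleys of similarity.

Per chromosome, windowed F_ST values are smoothed with a symmetric box
(moving-average) kernel and compared with the extrema of smoothed lines
obtained from random permutations of window order.  Islands are maximal
runs of windows whose smoothed value exceeds the permutation maximum;
valleys fall below the permutation minimum.  Same-kind runs separated by
``merge_gap`` windows or fewer are merged.  Regions are summarized with
mean F_ST/d_xy and a Wilcoxon signed-rank d_xy contrast against the
chromosomal background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ScanConfig:
    bandwidth: int = 20          # box kernel size, in windows
    kernel: str = "box"
    n_perm: int = 10_000
    merge_gap: int = 10          # windows
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.bandwidth < 1:
            raise ValueError("bandwidth must be ≥ 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be ≥ 1")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be ≥ 0")


@dataclass
class RegionCall:
    kind: str                    # "island" or "valley"
    chrom: str
    start: int                   # bp, 0-based half-open
    end: int
    n_windows: int
    mean_fst: float
    mean_dxy: float
    dxy_p: float | None = None
    dxy_direction: int = 0
    comparison: str = ""
    window_index: list = field(default_factory=list)  # row positions in chrom table

    @property
    def size_bp(self) -> int:
        return self.end - self.start


def kernel_smooth(values, bandwidth: int, kernel: str = "box") -> np.ndarray:
    """Box (moving-average) smoothing along one chromosome.

    The box spans ``bandwidth // 2`` windows on each side of the focal
    window; at chromosome edges the support is truncated and renormalized
    to the available windows.  Output length equals input length.
    """
    if kernel != "box":
        raise ValueError(f"unsupported kernel: {kernel!r}")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return v.copy()
    half = max(bandwidth // 2, 1)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(v.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, v.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _smooth_rows(mat: np.ndarray, bandwidth: int) -> np.ndarray:
    half = max(bandwidth // 2, 1)
    n = mat.shape[1]
    csum = np.concatenate([np.zeros((mat.shape[0], 1)), np.cumsum(mat, axis=1)],
                          axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[:, hi] - csum[:, lo]) / (hi - lo)


def permutation_envelope(values, cfg: ScanConfig,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[float, float]:
    """(upper, lower) thresholds from permuted-window smoothed lines.

    Window order is permuted within the chromosome ``cfg.n_perm`` times;
    each permuted series is smoothed and the global running maximum and
    minimum over all permutations and positions are kept (streamed —
    the full set of lines is never materialized).
    """
    v = np.asarray(values, dtype=float)
    if v.size < cfg.bandwidth:
        raise ValueError("chromosome shorter than the smoothing bandwidth")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    upper = -np.inf
    lower = np.inf
    chunk = max(1, min(cfg.n_perm, 2_000_000 // max(v.size, 1)))
    done = 0
    while done < cfg.n_perm:
        k = min(chunk, cfg.n_perm - done)
        order = np.argsort(rng.random((k, v.size)), axis=1)
        sm = _smooth_rows(v[order], cfg.bandwidth)
        upper = max(upper, float(sm.max()))
        lower = min(lower, float(sm.min()))
        done += k
    return upper, lower


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    """Merge [i, j] index runs separated by ≤ gap windows."""
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe - 1 <= gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def call_regions(chrom_windows: pd.DataFrame, smoothed: np.ndarray,
                 thresholds: tuple[float, float], cfg: ScanConfig,
                 comparison: str = "") -> list[RegionCall]:
    """Island/valley calls on one chromosome.

    ``chrom_windows`` is the window-table slice for the chromosome in
    positional order; ``smoothed`` the matching smoothed F_ST values;
    ``thresholds`` the (upper, lower) permutation envelope.  Islands are
    runs strictly above the upper threshold, valleys strictly below the
    lower one; same-kind runs separated by ≤ ``merge_gap`` windows are
    merged (gap windows join the region span).  Island and valley runs
    are never merged with each other.
    """
    upper, lower = thresholds
    starts = chrom_windows["start"].to_numpy()
    ends = chrom_windows["end"].to_numpy()
    fst = chrom_windows["fst"].to_numpy(float)
    dxy = chrom_windows["dxy"].to_numpy(float)
    chrom = chrom_windows["chrom"].iloc[0] if len(chrom_windows) else ""
    out: list[RegionCall] = []
    for kind, mask in (("island", smoothed > upper),
                       ("valley", smoothed < lower)):
        for s, e in _merge_runs(_runs_of(mask), cfg.merge_gap):
            idx = list(range(s, e + 1))
            out.append(RegionCall(
                kind=kind, chrom=chrom,
                start=int(starts[s]), end=int(ends[e]),
                n_windows=len(idx),
                mean_fst=float(np.nanmean(fst[idx])),
                mean_dxy=float(np.nanmean(dxy[idx])),
                comparison=comparison,
                window_index=idx,
            ))
    out.sort(key=lambda r: r.start)
    return out


def region_dxy_contrast(region: RegionCall, wt: pd.DataFrame,
                        ) -> tuple[float, int]:
    """Wilcoxon signed-rank test of region d_xy vs chromosomal background.

    One-sample signed-rank of the region's window d_xy values against the
    median of the background windows (same chromosome, outside the
    region).  Returns (p, direction) with direction the sign of region
    mean − background mean; p = 1 by convention when every region value
    equals the background median.
    """
    chrom_wt = wt.loc[wt["chrom"] == region.chrom]
    in_region = ((chrom_wt["start"] < region.end)
                 & (chrom_wt["end"] > region.start))
    reg = chrom_wt.loc[in_region, "dxy"].to_numpy(float)
    bg = chrom_wt.loc[~in_region, "dxy"].to_numpy(float)
    reg = reg[np.isfinite(reg)]
    bg = bg[np.isfinite(bg)]
    if reg.size < 1 or bg.size < 1:
        raise ValueError("region and background must each hold ≥1 window")
    med = float(np.median(bg))
    direction = int(np.sign(reg.mean() - bg.mean()))
    diffs = reg - med
    if np.all(diffs == 0):
        return 1.0, 0
    res = stats.wilcoxon(diffs, zero_method="wilcox")
    return float(res.pvalue), direction


def scan_comparison(wt: pd.DataFrame, cfg: ScanConfig, comparison: str = "",
                    ) -> list[RegionCall]:
    """Full island/valley scan of one comparison's window table.

    Runs the smoothing + permutation envelope per chromosome (window
    order permuted within chromosome; the threshold is the global
    extremum across that chromosome's positions), calls and merges
    regions, and attaches d_xy contrasts.  Windows with undefined F_ST
    are dropped before scanning.
    """
    rng = np.random.default_rng(cfg.seed)
    regions: list[RegionCall] = []
    wt = wt.loc[np.isfinite(wt["fst"].to_numpy(float))]
    for chrom, sub in wt.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        if len(sub) < cfg.bandwidth:
            continue
        v = sub["fst"].to_numpy(float)
        smoothed = kernel_smooth(v, cfg.bandwidth, cfg.kernel)
        thresholds = permutation_envelope(v, cfg, rng=rng)
        for r in call_regions(sub, smoothed, thresholds, cfg, comparison):
            if len(sub) - r.n_windows >= 1:
                r.dxy_p, r.dxy_direction = region_dxy_contrast(r, wt)
            regions.append(r)
    return regions


def compare_region_sizes(regions_by_comparison: dict[str, list[RegionCall]],
                         ) -> tuple[float, float]:
    """Kruskal–Wallis test of region bp sizes across comparisons."""
    groups = [np.array([r.size_bp for r in regs], float)
              for regs in regions_by_comparison.values() if regs]
    if len(groups) < 2:
        raise ValueError("Kruskal–Wallis needs ≥2 comparisons with regions")
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def shared_regions(regions_by_comparison: dict[str, list[RegionCall]],
                   ) -> pd.DataFrame:
    """Same-kind regions from different comparisons at overlapping positions.

    Overlapping bp intervals of the same kind are grouped transitively;
    only groups spanning ≥2 comparisons are reported, one row per member
    region with its per-comparison size.
    """
    items = [(label, r)
             for label, regs in regions_by_comparison.items() for r in regs]
    rows = []
    group_id = 0
    for kind in ("island", "valley"):
        per_chrom: dict[str, list[tuple[str, RegionCall]]] = {}
        for label, r in items:
            if r.kind == kind:
                per_chrom.setdefault(r.chrom, []).append((label, r))
        for chrom, members in per_chrom.items():
            members.sort(key=lambda t: t[1].start)
            cluster: list[tuple[str, RegionCall]] = []
            cluster_end = -1
            clusters = []
            for label, r in members:
                if cluster and r.start < cluster_end:
                    cluster.append((label, r))
                    cluster_end = max(cluster_end, r.end)
                else:
                    if cluster:
                        clusters.append(cluster)
                    cluster = [(label, r)]
                    cluster_end = r.end
            if cluster:
                clusters.append(cluster)
            for cl in clusters:
                if len({label for label, _ in cl}) < 2:
                    continue
                group_id += 1
                for label, r in cl:
                    rows.append((group_id, kind, chrom, label,
                                 r.start, r.end, r.size_bp))
    return pd.DataFrame(rows, columns=["group", "kind", "chrom", "comparison",
                                       "start", "end", "size_bp"])


def regions_table(regions: list[RegionCall]) -> pd.DataFrame:
    rows = [(r.comparison, r.kind, r.chrom, r.start, r.end, r.n_windows,
             r.mean_fst, r.mean_dxy, r.dxy_p, r.dxy_direction)
            for r in regions]
    return pd.DataFrame(rows, columns=[
        "comparison", "kind", "chrom", "start", "end", "n_windows",
        "mean_fst", "mean_dxy", "dxy_p", "dxy_direction"])
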