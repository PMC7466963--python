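"""Per-site and windowed divergence statistics: Weir–Cockerham F_ST and Nei d_xy.

The window estimator of F_ST is the ratio of summed variance components
Σa / Σ(a+b+c) over usable sites (not a mean of per-site ratios); window
d_xy is the mean per-site d_xy over all usable sites, variant and
invariant alike.  Windows with fewer than ``min_sites`` usable sites are
omitted, matching the study design this package reimplements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, ChromMap, GenotypeMatrix

logger = logging.getLogger("divscape")


@dataclass
class SiteComponents:
    """Per-site Weir–Cockerham variance components and d_xy for one pair."""

    chrom: np.ndarray
    pos: np.ndarray            # 1-based
    a: np.ndarray              # among-population component
    b: np.ndarray              # among-individual within-population
    c: np.ndarray              # within-individual (heterozygosity) component
    dxy: np.ndarray            # expected per-site difference, in [0, 1]
    usable: np.ndarray         # bool: both populations genotyped
    is_variant: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.pos.size


def pop_allele_stats(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n genotyped diploids, alt frequency, het frequency).

    ``geno``: (n_samples, n_sites) dosage codes with −1 missing.
    Sites with no genotyped sample return frequency 0 with n = 0.
    """
    called = geno != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, geno, 0).sum(axis=0)
    het = (geno == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), 0.0)
        h = np.where(n > 0, het / np.maximum(n, 1), 0.0)
    return n.astype(float), p, h


def weir_cockerham_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-population Weir & Cockerham (1984) variance components a, b, c.

    Arguments are per-site sample sizes (diploid counts), alt-allele
    frequencies and observed heterozygote frequencies.  Sites where either
    population has no genotyped individual, or where the mean sample size
    does not exceed 1, yield NaN components.
    """
    n1 = np.asarray(n1, float); n2 = np.asarray(n2, float)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
            / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
        c = hbar / 2.0
    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def site_components(gm: GenotypeMatrix, pop_a: str, pop_b: str,
                    ) -> SiteComponents:
    """Per-site W&C components and d_xy between two populations.

    d_xy for a biallelic site with alt frequencies p1, p2 is
    p1(1−p2) + (1−p1)p2; invariant sites get d_xy = 0 and NaN F_ST
    components.  Sites with a population entirely missing are flagged
    unusable and excluded from windows.
    """
    ia = gm.sample_indices(pop_a)
    ib = gm.sample_indices(pop_b)
    n1, p1, h1 = pop_allele_stats(gm.geno[ia])
    n2, p2, h2 = pop_allele_stats(gm.geno[ib])
    a, b, c = weir_cockerham_components(n1, p1, h1, n2, p2, h2)
    dxy = p1 * (1 - p2) + (1 - p1) * p2
    usable = (n1 >= 1) & (n2 >= 1)
    dxy = np.where(usable, dxy, np.nan)
    inv = ~gm.is_variant
    dxy[inv & usable] = 0.0
    for arr in (a, b, c):
        arr[inv] = np.nan
    return SiteComponents(chrom=gm.chrom, pos=gm.pos, a=a, b=b, c=c,
                          dxy=dxy, usable=usable, is_variant=gm.is_variant)


def fst_from_components(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Ratio-of-sums F_ST over a set of sites (NaN components ignored)."""
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    return float(num / den) if den != 0 else float("nan")


def windowed_stats(sc: SiteComponents, chrom_map: ChromMap, window_bp: int,
                   min_sites: int = 10) -> pd.DataFrame:
    """Non-overlapping windowed F_ST and d_xy.

    Windows are 0-based half-open tiles of ``window_bp``.  ``n_sites``
    counts usable sites (variant + invariant); windows with fewer than
    ``min_sites`` are omitted.  F_ST is NaN for windows with no variant
    information (e.g. all-invariant windows).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    for chrom in chrom_map.names:
        m = (sc.chrom == chrom) & sc.usable
        if not m.any():
            continue
        pos = sc.pos[m]
        widx = (pos - 1) // window_bp
        a, b, c, dxy = sc.a[m], sc.b[m], sc.c[m], sc.dxy[m]
        for w in np.unique(widx):
            sel = widx == w
            n = int(sel.sum())
            if n < min_sites:
                continue
            fst = fst_from_components(a[sel], b[sel], c[sel])
            start = int(w) * window_bp
            end = min(start + window_bp, chrom_map.length_bp[chrom])
            rows.append((chrom, start, end, n, fst, float(np.mean(dxy[sel]))))
    wt = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                     "n_sites", "fst", "dxy"])
    wt.attrs["window_bp"] = window_bp
    return wt


def harmonize_windows(tables: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Restrict ≥2 window tables to their common (chrom, start) keys.

    Mirrors the study rule that only windows with statistics for *all*
    pairwise comparisons are retained.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables to harmonize")
    keys = None
    for wt in tables:
        k = set(zip(wt["chrom"], wt["start"]))
        keys = k if keys is None else keys & k
    if not keys:
        raise ValueError("no windows shared by all comparisons")
    out = []
    for wt in tables:
        mask = [t in keys for t in zip(wt["chrom"], wt["start"])]
        sub = wt.loc[mask].sort_values(["chrom", "start"]).reset_index(drop=True)
        sub.attrs.update(wt.attrs)
        out.append(sub)
    return out


def mean_fst_by_partition(wt: pd.DataFrame, chrom_map: ChromMap) -> dict:
    """Mean window F_ST for autosomes and chromosome Z, with a rank-sum test.

    Returns ``{"autosomes": mean, "Z": mean, "p_value": p}``; a partition
    with no windows is absent (logged).  The p-value is a two-sided
    Mann–Whitney test of the autosome-vs-Z window F_ST distributions, with
    p = 1 by convention when the pooled values are all identical.
    """
    is_z = wt["chrom"].map(chrom_map.is_z).astype(bool)
    vals = wt["fst"].to_numpy(float)
    ok = np.isfinite(vals)
    auto = vals[ok & ~is_z.to_numpy()]
    zvals = vals[ok & is_z.to_numpy()]
    out: dict = {}
    if auto.size:
        out["autosomes"] = float(auto.mean())
    else:
        logger.info("mean_fst_by_partition: no autosomal windows")
    if zvals.size:
        out["Z"] = float(zvals.mean())
    else:
        logger.info("mean_fst_by_partition: no Z windows")
    if auto.size and zvals.size:
        pooled = np.concatenate([auto, zvals])
        if np.ptp(pooled) == 0:
            out["p_value"] = 1.0
        else:
            out["p_value"] = float(
                stats.mannwhitneyu(auto, zvals, alternative="two-sided").pvalue)
    return out
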