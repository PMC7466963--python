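"""PCA-based outlier-SNP scan (Mahalanobis statistic), LD pruning, overlaps.

The scan reimplements the published PCAdapt-style algorithm: genotypes
are mean-imputed, centered and scaled, the top-K principal axes
extracted, each SNP regressed on the K sample scores, and the robust
Mahalanobis distance of the resulting K-vectors converted to p-values
against a χ²_K after division by a genomic inflation factor; q-values
are Benjamini–Hochberg.  Exact numerical agreement with the original
package is not promised — the algorithm, not its implementation, is
reproduced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GeneAnnotation, GenotypeMatrix
from .landscape_scan import RegionCall

logger = logging.getLogger("divscape")


@dataclass
class OutlierConfig:
    k: int = 2                  # retained principal components
    min_maf: float = 0.2
    fdr: float = 0.01
    ld_window_kb: int = 1000
    ld_step: int = 1
    ld_r2: float = 0.8
    robust: bool = True         # MCD covariance for the Mahalanobis distance
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must be in [0, 0.5)")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")


def _dosage_imputed(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(samples × sites) float dosages with per-SNP mean imputation."""
    g = geno.astype(float)
    miss = geno == MISSING
    g[miss] = np.nan
    mean = np.nanmean(g, axis=0)
    inds = np.where(miss)
    g[inds] = mean[inds[1]]
    return g, mean / 2.0        # imputed matrix, allele frequency


def ld_prune(gm: GenotypeMatrix, cfg: OutlierConfig) -> np.ndarray:
    """Greedy LD pruning à la plink --indep-pairwise (window, 1-SNP step).

    Sites are visited in order; a site is removed when its genotype
    correlation r² with any *retained* earlier site within
    ``ld_window_kb`` on the same chromosome exceeds ``ld_r2`` (the later
    SNP of the pair is always the one removed).  Returns the retained
    site index.
    """
    var_idx = np.flatnonzero(gm.is_variant)
    g, _ = _dosage_imputed(gm.geno[:, var_idx])
    g = g - g.mean(axis=0)
    norm = np.sqrt((g ** 2).sum(axis=0))
    window_bp = cfg.ld_window_kb * 1000
    retained: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    for j, site in enumerate(var_idx):
        chrom = gm.chrom[site]
        pos = gm.pos[site]
        keep = True
        prev = kept_by_chrom.get(chrom, [])
        for i in reversed(prev):
            if gm.pos[var_idx[i]] < pos - window_bp:
                break
            if norm[i] == 0 or norm[j] == 0:
                continue
            r = float(g[:, i] @ g[:, j]) / (norm[i] * norm[j])
            if r * r > cfg.ld_r2:
                keep = False
                break
        if keep:
            retained.append(j)
            kept_by_chrom.setdefault(chrom, []).append(j)
    return var_idx[np.asarray(retained, dtype=np.intp)]


def pca_outlier_scan(gm: GenotypeMatrix, cfg: OutlierConfig) -> pd.DataFrame:
    """Per-SNP Mahalanobis outlier statistics, p-values and q-values.

    Returns a table with columns snp (chrom:pos), chrom, pos, stat, p,
    q, outlier; outliers are SNPs with q ≤ ``cfg.fdr``.  MAF is computed
    on the pooled sample; SNPs below ``cfg.min_maf`` (or constant after
    imputation) are excluded (logged).
    """
    if cfg.k >= gm.n_samples:
        raise ValueError("K must be smaller than the number of samples")
    if gm.n_samples < cfg.k + 2:
        raise ValueError("need at least K+2 samples")
    var_idx = np.flatnonzero(gm.is_variant)
    g, freq = _dosage_imputed(gm.geno[:, var_idx])
    maf = np.minimum(freq, 1 - freq)
    ok = maf >= cfg.min_maf
    sd = np.sqrt(2 * freq * (1 - freq))
    constant = (g.std(axis=0) == 0) | (sd == 0)
    n_const = int((ok & constant).sum())
    if n_const:
        logger.info("pca_outlier_scan: excluded %d constant SNPs", n_const)
    ok &= ~constant
    if ok.sum() < cfg.k + 2:
        raise ValueError("too few SNPs pass the MAF filter")
    idx = var_idx[ok]
    x = (g[:, ok] - 2 * freq[ok]) / sd[ok]

    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :cfg.k]                       # orthonormal sample scores
    # per-SNP regression on the K scores: coefficients b = scoresᵀ x,
    # z-scores b / residual-sd (design is orthonormal)
    b = scores.T @ x                            # (K, L)
    resid = x - scores @ b
    dof = max(gm.n_samples - cfg.k, 1)
    sigma = np.sqrt((resid ** 2).sum(axis=0) / dof)
    sigma[sigma == 0] = np.nan
    z = (b / sigma).T                           # (L, K)

    finite = np.all(np.isfinite(z), axis=1)
    d2 = np.full(z.shape[0], np.nan)
    zf = z[finite]
    if cfg.robust:
        from sklearn.covariance import MinCovDet
        mcd = MinCovDet(random_state=cfg.seed).fit(zf)
        d2[finite] = mcd.mahalanobis(zf)
    else:
        mu = zf.mean(axis=0)
        cov = np.cov(zf, rowvar=False)
        inv = np.linalg.inv(np.atleast_2d(cov))
        d = zf - mu
        d2[finite] = np.einsum("ij,jk,ik->i", d, inv, d)

    gif = np.nanmedian(d2) / stats.chi2.ppf(0.5, cfg.k)
    p = stats.chi2.sf(d2 / gif, cfg.k)

    from statsmodels.stats.multitest import multipletests
    q = np.full_like(p, np.nan)
    fin = np.isfinite(p)
    q[fin] = multipletests(p[fin], method="fdr_bh")[1]
    out = pd.DataFrame({
        "snp": [f"{c}:{pp}" for c, pp in zip(gm.chrom[idx], gm.pos[idx])],
        "chrom": gm.chrom[idx],
        "pos": gm.pos[idx],
        "stat": d2,
        "p": p,
        "q": q,
        "outlier": q <= cfg.fdr,
    })
    out.attrs["gif"] = float(gif)
    return out


def overlap_outliers_regions(outliers: pd.DataFrame,
                             regions: list[RegionCall]) -> dict[str, int]:
    """Counts of outlier SNPs inside island/valley bp intervals.

    Region intervals are 0-based half-open; a SNP at a region's first bp
    is counted.  Returns {"island": n, "valley": n}.
    """
    counts = {"island": 0, "valley": 0}
    hits = outliers.loc[outliers["outlier"].astype(bool)]
    for kind in counts:
        regs = [r for r in regions if r.kind == kind]
        n = 0
        for _, row in hits.iterrows():
            p0 = int(row["pos"]) - 1        # to 0-based
            if any(r.chrom == row["chrom"] and r.start <= p0 < r.end
                   for r in regs):
                n += 1
        counts[kind] = n
    return counts


def candidate_gene_overlap(genes: list[GeneAnnotation],
                           regions: list[RegionCall],
                           outliers: pd.DataFrame,
                           flank_bp: int = 10_000,
                           chrom_names: list[str] | None = None,
                           ) -> pd.DataFrame:
    """Per-gene island overlap and outlier-SNP hit flags.

    A gene is within an island when its 1-based inclusive interval
    overlaps an island's interval by any extent (UTRs and introns
    included).  An outlier hits a gene when its position lies within
    ``flank_bp`` of the gene span (exactly ``flank_bp`` past an end
    counts; one bp further does not).
    """
    if chrom_names is not None:
        for g in genes:
            if g.chrom not in chrom_names:
                raise ValueError(
                    f"gene {g.name}: chromosome {g.chrom!r} not in map")
    hits = outliers.loc[outliers["outlier"].astype(bool)]
    islands = [r for r in regions if r.kind == "island"]
    rows = []
    for g in genes:
        in_island = any(
            r.chrom == g.chrom and g.start <= r.end and g.end > r.start
            for r in islands)
        hit = any(
            row["chrom"] == g.chrom
            and g.start - flank_bp <= int(row["pos"]) <= g.end + flank_bp
            for _, row in hits.iterrows())
        rows.append((g.name, g.chrom, g.start, g.end, g.trait,
                     in_island, hit))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end",
                                       "trait", "in_island", "outlier_hit"])
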