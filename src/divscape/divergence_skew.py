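"""Distributional skew of windowed F_ST, randomization test, block bootstrap.

Skewness is the third standardized central moment with 1/n moments
(``g1 = m3 / m2^{3/2}``); a bias-corrected G1 variant is available by
flag.  The randomization test pools the window F_ST values of two
comparisons, reallocates them to groups of the original sizes without
replacement, and compares the observed |Δskew| with the permutation
distribution using the add-one Monte-Carlo convention
p = (1 + #{T_rand ≥ T_obs}) / (n_rand + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ChromMap


@dataclass
class SkewResult:
    comparison: str
    partition: str          # "autosomes" or "Z"
    skew: float
    n_windows: int
    ci_lower: float
    ci_upper: float


@dataclass
class SkewTestResult:
    comparison_a: str
    comparison_b: str
    t_obs: float            # |skew_A − skew_B|
    n_randomizations: int
    p_value: float


def skewness(values, corrected: bool = False) -> float:
    """Sample skewness g1 = m3 / m2^{3/2} (or bias-corrected G1).

    Requires ≥3 finite values with nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("skewness needs at least 3 finite values")
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        raise ValueError("degenerate distribution (zero variance)")
    g1 = np.mean((x - m) ** 3) / m2 ** 1.5
    if corrected:
        n = x.size
        g1 *= np.sqrt(n * (n - 1)) / (n - 2)
    return float(g1)


def _skew_rows(mat: np.ndarray) -> np.ndarray:
    """g1 along axis 1 of a 2-D array (no degeneracy checks)."""
    m = mat.mean(axis=1, keepdims=True)
    d = mat - m
    m2 = np.mean(d * d, axis=1)
    m3 = np.mean(d * d * d, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return m3 / m2 ** 1.5


def skew_randomization_test(vals_a, vals_b, n_rand: int = 10_000,
                            seed: int | None = None,
                            labels: tuple[str, str] = ("A", "B"),
                            ) -> SkewTestResult:
    """Randomization test for a difference in F_ST distributional skew."""
    if n_rand < 1:
        raise ValueError("n_rand must be ≥ 1")
    a = np.asarray(vals_a, float)
    b = np.asarray(vals_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both value vectors must be nonempty")
    t_obs = abs(skewness(a) - skewness(b))
    pooled = np.concatenate([a, b])
    na = a.size
    rng = np.random.default_rng(seed)
    n_ge = 0
    chunk = max(1, min(n_rand, 512 * 1024 // max(pooled.size, 1) + 1))
    done = 0
    while done < n_rand:
        k = min(chunk, n_rand - done)
        # k independent permutations via argsort of uniform keys
        order = np.argsort(rng.random((k, pooled.size)), axis=1)
        perm = pooled[order]
        t = np.abs(_skew_rows(perm[:, :na]) - _skew_rows(perm[:, na:]))
        n_ge += int(np.sum(t >= t_obs - 1e-15))
        done += k
    p = (1 + n_ge) / (n_rand + 1)
    return SkewTestResult(labels[0], labels[1], float(t_obs), n_rand, float(p))


def block_bootstrap_ci(wt: pd.DataFrame, statistic: str = "mean",
                       block_bp: int = 500_000, n_boot: int = 1000,
                       seed: int | None = None,
                       column: str = "fst") -> tuple[float, float]:
    """Percentile 95% CI by block bootstrap over ``block_bp`` blocks.

    Consecutive windows are grouped into blocks per chromosome (a block
    that straddles a chromosome end is kept if it holds ≥1 window); blocks
    are resampled with replacement and the statistic ("mean" or "skew")
    recomputed on the pooled window values.
    """
    vals = wt[column].to_numpy(float)
    ok = np.isfinite(vals)
    block_key = pd.Series(
        list(zip(wt["chrom"], wt["start"] // block_bp)))[ok]
    vals = vals[ok]
    codes = block_key.astype("category").cat.codes.to_numpy()
    n_blocks = codes.max() + 1 if codes.size else 0
    if n_blocks < 2:
        raise ValueError("block bootstrap needs at least 2 blocks")
    blocks = [vals[codes == i] for i in range(n_blocks)]
    if statistic == "mean":
        fn = np.mean
    elif statistic == "skew":
        fn = skewness
    else:
        raise ValueError(f"unknown statistic: {statistic!r}")
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for i in range(n_boot):
        pick = rng.integers(0, n_blocks, n_blocks)
        est[i] = fn(np.concatenate([blocks[j] for j in pick]))
    lo, hi = np.percentile(est, [2.5, 97.5])
    return float(lo), float(hi)


def skew_by_partition(wt: pd.DataFrame, chrom_map: ChromMap, comparison: str,
                      block_bp: int = 500_000, n_boot: int = 1000,
                      seed: int | None = None) -> list[SkewResult]:
    """Skew of window F_ST for autosomes and Z, with block-bootstrap CIs."""
    out = []
    is_z = wt["chrom"].map(chrom_map.is_z).astype(bool).to_numpy()
    for partition, mask in (("autosomes", ~is_z), ("Z", is_z)):
        sub = wt.loc[mask]
        vals = sub["fst"].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 3:
            continue
        lo, hi = block_bootstrap_ci(sub, "skew", block_bp, n_boot, seed)
        out.append(SkewResult(comparison, partition, skewness(vals),
                              vals.size, lo, hi))
    return out
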