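"""Forward-time individual-based neutral divergence simulator.

Two populations of diploid individuals evolve on discrete,
non-overlapping generations with density-regulated Poisson fitness,
monogamous ranked-fitness pairing, homogeneous Poisson recombination
along one chromosome, and symmetric per-offspring migration.  Allele
identity never affects fitness, pairing, migration or survival, so all
divergence is drift.  Windowed Weir–Cockerham F_ST between samples of
the two populations is reported along a generation trajectory.

Demographic defaults follow the calibration λ = 3.0 and
σ_dem = (λ − 2) / 400 = 0.0025: with fitness Poisson(λ) − N·σ_dem
truncated at zero, mean fitness is ≈ 2 at N ≈ 400, which holds each
population near its initial size of 400 (roughly 130–170 breeding pairs
per generation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popgen_stats import weir_cockerham_components

logger = logging.getLogger("divscape")


@dataclass
class SimConfig:
    n_pop_init: int = 400
    lam: float = 3.0                 # mean fitness λ (Poisson offspring mean)
    sigma_dem: float = 0.0025        # fitness decrement per extra individual
    m: float = 0.001                 # per-offspring migration probability
    c: float = 3e-8                  # crossovers per bp per generation (3 cM/Mb)
    chrom_length_bp: int = 62_000_000
    n_snps: int = 1000
    positions: np.ndarray | None = None   # overrides n_snps when given
    generations: int = 2000
    seed: int | None = None
    sample_size: int = 20            # diploids per population for F_ST
    window_bp: int = 500_000
    report_every: int = 20           # generations between F_ST reports
    min_window_sites: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.m <= 1:
            raise ValueError("m must lie in [0, 1]")
        if self.c < 0 or self.lam <= 0 or self.sigma_dem < 0:
            raise ValueError("require c ≥ 0, λ > 0, σ_dem ≥ 0")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")


@dataclass
class SimState:
    haplo: list[np.ndarray]          # per population: (N, 2, L) uint8
    sex: list[np.ndarray]            # per population: (N,) 0=female, 1=male
    positions: np.ndarray            # (L,) bp
    generation: int
    rng: np.random.Generator

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(h.shape[0] for h in self.haplo)


@dataclass
class SimResult:
    trajectory: pd.DataFrame         # generation, window_start, fst
    mean_fst: pd.DataFrame           # generation, mean windowed fst
    status: str                      # "completed" or "extinct"
    pop_sizes: pd.DataFrame          # generation, n0, n1
    final_state: SimState | None = None


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def default_positions(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform random SNP coordinates on the synthetic chromosome."""
    pos = rng.choice(np.arange(1, cfg.chrom_length_bp + 1, dtype=np.int64),
                     size=cfg.n_snps, replace=False)
    pos.sort()
    return pos


def init_populations(cfg: SimConfig,
                     allele_freqs: np.ndarray | None = None,
                     genotype_pool: np.ndarray | None = None,
                     rng: np.random.Generator | None = None) -> SimState:
    """Both populations drawn from the SAME ancestral pool.

    ``genotype_pool`` is an (n_individuals, L) dosage matrix: each new
    individual samples, per SNP and with replacement, a genotype from the
    pool column and phases heterozygotes randomly.  Alternatively
    ``allele_freqs`` gives per-SNP alt frequencies and haplotype alleles
    are Bernoulli draws (Hardy–Weinberg).  Sexes are i.i.d. fair coin.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.positions is not None:
        positions = cfg.positions
    else:
        positions = default_positions(cfg, rng)
    L = positions.size

    haplo = []
    sex = []
    for _ in range(2):
        n = cfg.n_pop_init
        if genotype_pool is not None:
            pool = np.asarray(genotype_pool, dtype=np.int8)
            if pool.size == 0:
                raise ValueError("empty genotype pool")
            pick = rng.integers(0, pool.shape[0], size=(n, L))
            g = pool[pick, np.arange(L)[None, :]]
            h0 = np.where(g == 2, 1, 0).astype(np.uint8)
            h1 = h0.copy()
            het = g == 1
            phase = rng.integers(0, 2, size=(n, L)).astype(bool)
            h0[het & phase] = 1
            h1[het & ~phase] = 1
            h = np.stack([h0, h1], axis=1)
        elif allele_freqs is not None:
            p = np.asarray(allele_freqs, dtype=float)
            if p.size != L:
                raise ValueError("allele_freqs length must match positions")
            h = (rng.random((n, 2, L)) < p).astype(np.uint8)
        else:
            raise ValueError("provide allele_freqs or genotype_pool")
        haplo.append(h)
        sex.append(rng.integers(0, 2, size=n).astype(np.int8))
    return SimState(haplo=haplo, sex=sex, positions=positions,
                    generation=0, rng=rng)


# ---------------------------------------------------------------------------
# per-generation mechanics
# ---------------------------------------------------------------------------

def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    base = np.floor(x)
    frac = x - base
    return (base + (rng.random(x.shape) < frac)).astype(np.int64)


def _largest_remainder(x: np.ndarray, total: int) -> np.ndarray:
    """Integer vector with the given total, proportional to x (≥0)."""
    if x.sum() == 0:
        out = np.full(x.size, total // max(x.size, 1), dtype=np.int64)
        out[: total % max(x.size, 1)] += 1  # degenerate: spread evenly
        return out
    scaled = x * (total / x.sum())
    base = np.floor(scaled).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(scaled - base), kind="stable")
        base[order[:short]] += 1
    return base


def assign_fitness(state: SimState, cfg: SimConfig, pop: int,
                   ) -> np.ndarray:
    """Per-individual integer offspring numbers for one population.

    Each individual draws Poisson(λ) − N·σ_dem truncated at zero
    (independent of genotype).  Female values are stochastically rounded
    to integers; male values are then rescaled with largest-remainder
    rounding so that Σ male = Σ female exactly.
    """
    n = state.haplo[pop].shape[0]
    decrement = n * cfg.sigma_dem
    if decrement >= cfg.lam + 5 * np.sqrt(cfg.lam):
        logger.warning("population %d collapsing (N·σ_dem=%.2f vs λ=%.2f)",
                       pop, decrement, cfg.lam)
    raw = np.maximum(state.rng.poisson(cfg.lam, n) - decrement, 0.0)
    fitness = np.zeros(n, dtype=np.int64)
    females = state.sex[pop] == 0
    fitness[females] = _stochastic_round(raw[females], state.rng)
    total_f = int(fitness[females].sum())
    males = ~females
    fitness[males] = _largest_remainder(raw[males], total_f)
    return fitness


def form_pairs(state: SimState, fitness: np.ndarray, pop: int,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Monogamous ranked-fitness pairing.

    Males and females with fitness > 0 are sorted by fitness (ties broken
    by index, stable) and paired by rank; surplus individuals stay
    unpaired.  Returns (mother index, father index, offspring counts)
    with offspring per pair = the female's fitness value.
    """
    sexes = state.sex[pop]
    f_idx = np.flatnonzero((sexes == 0) & (fitness > 0))
    m_idx = np.flatnonzero((sexes == 1) & (fitness > 0))
    if f_idx.size == 0 or m_idx.size == 0:
        logger.info("population %d: no possible pair this generation", pop)
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty
    f_rank = f_idx[np.argsort(-fitness[f_idx], kind="stable")]
    m_rank = m_idx[np.argsort(-fitness[m_idx], kind="stable")]
    k = min(f_rank.size, m_rank.size)
    mothers = f_rank[:k]
    fathers = m_rank[:k]
    return mothers, fathers, fitness[mothers]


def make_gamete(parent_haplotypes: np.ndarray, positions: np.ndarray,
                c: float, rng: np.random.Generator,
                length: int | None = None) -> np.ndarray:
    """One recombinant gamete (reference single-meiosis implementation).

    Crossover count ~ Poisson(c × chromosome length); breakpoints
    uniform on (0, length]; the gamete alternates source haplotype at
    each breakpoint starting from a fair-coin choice.  The vectorized
    batch used by :func:`run_simulation` is distributionally equivalent
    (only crossover-count parity between adjacent SNPs matters).
    """
    if length is None:
        length = int(positions[-1]) if positions.size else 0
    n_x = rng.poisson(c * length)
    start = rng.integers(0, 2)
    if n_x == 0:
        return parent_haplotypes[start].copy()
    breaks = np.sort(rng.uniform(0, length, n_x))
    source = (start + np.searchsorted(breaks, positions, side="left")) % 2
    return np.where(source == 0, parent_haplotypes[0], parent_haplotypes[1])


def _gametes_batch(haplo: np.ndarray, parents: np.ndarray,
                   p_odd: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Recombinant gametes for many offspring at once.

    ``haplo``: (N, 2, L); ``parents``: (T,) parent indices; ``p_odd``:
    (L−1,) probability of an odd crossover count in each inter-SNP
    interval, (1 − exp(−2c·gap))/2.  Returns (T, L) gametes.
    """
    T = parents.size
    L = haplo.shape[2]
    start = rng.integers(0, 2, size=(T, 1))
    if L > 1:
        switches = (rng.random((T, L - 1)) < p_odd).astype(np.int8)
        source = (start + np.concatenate(
            [np.zeros((T, 1), np.int8), np.cumsum(switches, axis=1)],
            axis=1)) % 2
    else:
        source = start % 2
    ph = haplo[parents]                        # (T, 2, L)
    return np.where(source == 0, ph[:, 0, :], ph[:, 1, :]).astype(np.uint8)


def migrate(pop_labels: np.ndarray, m: float, rng: np.random.Generator,
            ) -> np.ndarray:
    """Each offspring independently switches population with probability m."""
    if m == 0:
        return pop_labels
    switch = rng.random(pop_labels.size) < m
    return np.where(switch, 1 - pop_labels, pop_labels)


# ---------------------------------------------------------------------------
# F_ST reporting
# ---------------------------------------------------------------------------

def _windowed_fst(state: SimState, cfg: SimConfig) -> pd.DataFrame:
    """Windowed W&C F_ST between samples of the two populations."""
    genos = []
    for pop in range(2):
        h = state.haplo[pop]
        n = h.shape[0]
        k = min(cfg.sample_size, n)
        pick = state.rng.choice(n, size=k, replace=False)
        genos.append(h[pick].sum(axis=1).astype(np.int8))
    stats_ = []
    for g in genos:
        n = np.full(g.shape[1], float(g.shape[0]))
        p = g.mean(axis=0) / 2.0
        h = (g == 1).mean(axis=0)
        stats_.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats_
    a, b, c = weir_cockerham_components(n1, p1, h1, n2, p2, h2)
    widx = (state.positions - 1) // cfg.window_bp
    rows = []
    for w in np.unique(widx):
        sel = widx == w
        if sel.sum() < cfg.min_window_sites:
            continue
        num = np.nansum(a[sel])
        den = np.nansum(a[sel] + b[sel] + c[sel])
        if den == 0:
            continue
        rows.append((int(w) * cfg.window_bp, float(num / den)))
    return pd.DataFrame(rows, columns=["window_start", "fst"])


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def run_simulation(cfg: SimConfig,
                   allele_freqs: np.ndarray | None = None,
                   genotype_pool: np.ndarray | None = None,
                   keep_final_state: bool = False) -> SimResult:
    """Iterate the two-population model and record windowed F_ST.

    When neither ``allele_freqs`` nor ``genotype_pool`` is given, initial
    alt frequencies are Uniform(0.05, 0.95) (a polymorphic stand-in pool).
    F_ST is reported at generation 0, every ``report_every`` generations
    and at the final generation.  Ends early with status "extinct" if a
    population hits size 0.
    """
    rng = np.random.default_rng(cfg.seed)
    if allele_freqs is None and genotype_pool is None:
        if cfg.positions is not None:
            L = cfg.positions.size
        else:
            L = cfg.n_snps
        allele_freqs = rng.uniform(0.05, 0.95, L)
    state = init_populations(cfg, allele_freqs=allele_freqs,
                             genotype_pool=genotype_pool, rng=rng)
    gaps = np.diff(state.positions).astype(float)
    p_odd = 0.5 * (1.0 - np.exp(-2.0 * cfg.c * gaps))

    traj_rows = []
    mean_rows = []
    size_rows = []
    status = "completed"

    def report(gen: int) -> None:
        wf = _windowed_fst(state, cfg)
        for _, r in wf.iterrows():
            traj_rows.append((gen, int(r["window_start"]), float(r["fst"])))
        if len(wf):
            mean_rows.append((gen, float(wf["fst"].mean())))
        size_rows.append((gen,) + state.sizes)

    report(0)
    for gen in range(1, cfg.generations + 1):
        kids_h: list[np.ndarray] = []
        kids_pop: list[np.ndarray] = []
        for pop in range(2):
            if state.haplo[pop].shape[0] == 0:
                continue
            fitness = assign_fitness(state, cfg, pop)
            mothers, fathers, counts = form_pairs(state, fitness, pop)
            total = int(counts.sum())
            if total == 0:
                continue
            mother_of = np.repeat(mothers, counts)
            father_of = np.repeat(fathers, counts)
            g_m = _gametes_batch(state.haplo[pop], mother_of, p_odd, state.rng)
            g_f = _gametes_batch(state.haplo[pop], father_of, p_odd, state.rng)
            kids_h.append(np.stack([g_m, g_f], axis=1))
            kids_pop.append(np.full(total, pop, dtype=np.int8))
        if not kids_h:
            status = "extinct"
            state.generation = gen
            break
        h_all = np.concatenate(kids_h, axis=0)
        labels = migrate(np.concatenate(kids_pop), cfg.m, state.rng)
        sex_all = state.rng.integers(0, 2, size=h_all.shape[0]).astype(np.int8)
        new_h, new_s = [], []
        for pop in range(2):
            sel = labels == pop
            new_h.append(h_all[sel])
            new_s.append(sex_all[sel])
        state.haplo = new_h
        state.sex = new_s
        state.generation = gen
        if min(state.sizes) == 0:
            status = "extinct"
            logger.info("population extinct at generation %d", gen)
            break
        if gen % cfg.report_every == 0 or gen == cfg.generations:
            report(gen)

    return SimResult(
        trajectory=pd.DataFrame(traj_rows,
                                columns=["generation", "window_start", "fst"]),
        mean_fst=pd.DataFrame(mean_rows, columns=["generation", "mean_fst"]),
        status=status,
        pop_sizes=pd.DataFrame(size_rows, columns=["generation", "n0", "n1"]),
        final_state=state if keep_final_state else None,
    )


def equilibrium_mean_fst(result: SimResult, gen_from: int = 1000,
                         gen_to: int | None = None) -> float:
    """Mean of the per-generation mean windowed F_ST over a generation span."""
    mf = result.mean_fst
    sel = mf["generation"] >= gen_from
    if gen_to is not None:
        sel &= mf["generation"] <= gen_to
    return float(mf.loc[sel, "mean_fst"].mean())
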