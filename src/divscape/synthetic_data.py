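"""Synthetic genotype datasets with known ground truth.

Background differentiation follows the Balding–Nichols model: per-SNP
ancestral alt frequencies p are drawn from a chosen distribution and
each population's frequency from Beta(p(1−F)/F, (1−p)(1−F)/F), so the
expected Weir–Cockerham F_ST equals F.  Island intervals spike F up,
valley intervals combine F ≈ 0 with low ancestral minor-allele
frequencies (reduced diversity, hence reduced d_xy).  Invariant sites
are interleaved between variants so windowed d_xy denominators are
exercised, and missing genotypes are i.i.d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (MISSING, ChromMap, GeneAnnotation, GenotypeMatrix,
                         write_genes_bed, write_pop_table, write_vcf)


@dataclass
class SpikeSpec:
    """Layout of a spiked divergence landscape on one or more chromosomes."""

    background_f: float = 0.02
    island_f: float = 0.5
    valley_maf_max: float = 0.05      # low ancestral MAF → reduced d_xy
    islands: list[tuple[str, int, int]] = field(default_factory=list)
    valleys: list[tuple[str, int, int]] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000})
    n1: int = 20
    n2: int = 20
    snp_spacing_bp: int = 5000
    invariant_every: int = 5          # one invariant site per this many SNPs
    missing_rate: float = 0.0
    window_bp: int = 50_000

    def __post_init__(self) -> None:
        for kind, ivals in (("island", self.islands), ("valley", self.valleys)):
            for chrom, s, e in ivals:
                if chrom not in self.chrom_lengths:
                    raise ValueError(f"{kind} on unknown chromosome {chrom}")
                if not (0 <= s < e <= self.chrom_lengths[chrom]):
                    raise ValueError(f"{kind} interval outside {chrom}")
        both = sorted(self.islands + self.valleys)
        for (c1, s1, e1), (c2, s2, e2) in zip(both, both[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError("overlapping truth intervals")


def _bn_population_freqs(p_anc: np.ndarray, f: float,
                         rng: np.random.Generator) -> np.ndarray:
    if f == 0:
        return p_anc.copy()
    shape = (1.0 - f) / f
    return rng.beta(p_anc * shape, (1.0 - p_anc) * shape)


def _draw_genotypes(freqs: np.ndarray, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(2, freqs, size=(n, freqs.size)).astype(np.int8)


def balding_nichols(n1: int, n2: int, n_snps: int, f: float,
                    p_anc: tuple[float, float] = (0.05, 0.95),
                    missing_rate: float = 0.0,
                    seed: int | None = None,
                    chrom: str = "chr1",
                    spacing_bp: int = 1000,
                    invariant_every: int = 0) -> GenotypeMatrix:
    """Two-population Balding–Nichols genotype matrix with target F.

    Ancestral alt frequencies are Uniform(*p_anc*); population
    frequencies are Beta-distributed around them with differentiation
    parameter ``f`` (F = 0 gives identical frequencies).  Optionally one
    invariant site is interleaved per ``invariant_every`` variants, and
    genotypes go missing i.i.d. at ``missing_rate``.
    """
    if not 0 <= f < 1:
        raise ValueError("F must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    pa = rng.uniform(*p_anc, n_snps)
    p1 = _bn_population_freqs(pa, f, rng)
    p2 = _bn_population_freqs(pa, f, rng)
    g = np.concatenate([_draw_genotypes(p1, n1, rng),
                        _draw_genotypes(p2, n2, rng)], axis=0)
    is_variant = np.ones(n_snps, dtype=bool)
    if invariant_every > 0:
        n_inv = n_snps // invariant_every
        order = np.concatenate([np.ones(n_snps, bool), np.zeros(n_inv, bool)])
        rng.shuffle(order)
        g_full = np.zeros((n1 + n2, order.size), dtype=np.int8)
        g_full[:, order] = g
        g = g_full
        is_variant = order
    n_sites = g.shape[1]
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = MISSING
    samples = [f"A{i}" for i in range(n1)] + [f"B{i}" for i in range(n2)]
    pop_of = {s: ("popA" if s.startswith("A") else "popB") for s in samples}
    ref_alt = np.empty((n_sites, 2), dtype=object)
    ref_alt[:, 0] = "A"
    ref_alt[:, 1] = np.where(is_variant, "T", ".")
    gm = GenotypeMatrix(
        samples=samples, pop_of=pop_of,
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=np.arange(1, n_sites + 1, dtype=np.int64) * spacing_bp,
        ref_alt=ref_alt, geno=g, is_variant=is_variant)
    gm.validate()
    return gm


def spiked_landscape(spec: SpikeSpec, seed: int | None = None,
                     ) -> tuple[GenotypeMatrix, list[tuple[str, str, int, int]]]:
    """Genotype matrix with spiked islands/valleys at known coordinates.

    Returns the matrix and the truth intervals as
    ``(kind, chrom, start, end)`` tuples (0-based half-open bp).
    """
    rng = np.random.default_rng(seed)
    chroms, poss, genos, is_var = [], [], [], []
    truth = ([("island",) + t for t in spec.islands]
             + [("valley",) + t for t in spec.valleys])

    def interval_kind(chrom: str, pos: int) -> str:
        p0 = pos - 1
        for kind, c, s, e in truth:
            if c == chrom and s <= p0 < e:
                return kind
        return "background"

    n_tot = spec.n1 + spec.n2
    for chrom, length in spec.chrom_lengths.items():
        pos = np.arange(spec.snp_spacing_bp, length + 1, spec.snp_spacing_bp)
        for j, p in enumerate(pos):
            kind = interval_kind(chrom, int(p))
            invariant = spec.invariant_every > 0 and \
                (j % (spec.invariant_every + 1)) == spec.invariant_every
            if invariant:
                genos.append(np.zeros(n_tot, dtype=np.int8))
                is_var.append(False)
            else:
                if kind == "island":
                    pa = rng.uniform(0.2, 0.8)
                    f = spec.island_f
                elif kind == "valley":
                    pa = rng.uniform(0.005, spec.valley_maf_max)
                    f = 0.0
                else:
                    pa = rng.uniform(0.05, 0.95)
                    f = spec.background_f
                p1 = _bn_population_freqs(np.array([pa]), f, rng)[0]
                p2 = _bn_population_freqs(np.array([pa]), f, rng)[0]
                g = np.concatenate([
                    rng.binomial(2, p1, spec.n1),
                    rng.binomial(2, p2, spec.n2)]).astype(np.int8)
                genos.append(g)
                is_var.append(True)
            chroms.append(chrom)
            poss.append(int(p))
    geno = np.vstack(genos).T
    if spec.missing_rate > 0:
        geno[rng.random(geno.shape) < spec.missing_rate] = MISSING
    samples = ([f"A{i}" for i in range(spec.n1)]
               + [f"B{i}" for i in range(spec.n2)])
    pop_of = {s: ("popA" if s.startswith("A") else "popB") for s in samples}
    n_sites = len(poss)
    ref_alt = np.empty((n_sites, 2), dtype=object)
    ref_alt[:, 0] = "A"
    ref_alt[:, 1] = np.where(is_var, "T", ".")
    gm = GenotypeMatrix(
        samples=samples, pop_of=pop_of,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref_alt=ref_alt, geno=geno,
        is_variant=np.asarray(is_var, dtype=bool))
    gm.validate()
    return gm, [(k, c, s, e) for k, c, s, e in truth]


def fixture_annotations(spec: SpikeSpec | None = None,
                        ) -> tuple[ChromMap, list[GeneAnnotation]]:
    """Deterministic toy chromosome map and gene set.

    Three autosomes plus Z; genes are placed inside and outside any truth
    islands of ``spec`` and at exact 10 kb flank boundaries, so overlap
    rules can be tested against construction.
    """
    lengths = {"chr1": 20_000_000, "chr2": 15_000_000,
               "chr3": 10_000_000, "chrZ": 8_000_000}
    if spec is not None:
        lengths.update(spec.chrom_lengths)
    names = sorted(lengths, key=lambda c: (c == "chrZ", c))
    cm = ChromMap(names=names, length_bp=lengths, z_chroms={"chrZ"})
    genes = [
        GeneAnnotation("GENE_OUT", names[0], 1_000_001, 1_050_000, "body"),
        GeneAnnotation("GENE_Z", "chrZ", 2_000_001, 2_020_000, "bill"),
    ]
    if spec is not None and spec.islands:
        chrom, s, e = spec.islands[0]
        mid = (s + e) // 2
        genes.append(GeneAnnotation("GENE_IN_ISLAND", chrom,
                                    mid + 1, min(mid + 30_000, e), "bill"))
        genes.append(GeneAnnotation("GENE_FLANK", chrom,
                                    e + 10_001, e + 40_000, "body"))
    return cm, genes


def write_fixture_dataset(out_dir: str | Path, spec: SpikeSpec,
                          seed: int | None = None) -> dict[str, Path]:
    """Write a full VCF + population TSV + truth BED fixture set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gm, truth = spiked_landscape(spec, seed=seed)
    cm, genes = fixture_annotations(spec)
    paths = {
        "vcf": out / "synthetic.vcf",
        "pops": out / "populations.tsv",
        "truth": out / "truth_regions.bed",
        "chrom_map": out / "chrom_map.tsv",
        "genes": out / "genes.bed",
    }
    write_vcf(gm, paths["vcf"], chrom_map=cm)
    write_pop_table(gm.pop_of, paths["pops"])
    with open(paths["truth"], "w") as fh:
        for kind, chrom, s, e in truth:
            fh.write(f"{chrom}\t{s}\t{e}\t{kind}\t0\t.\n")
    cm.to_tsv(paths["chrom_map"])
    write_genes_bed(genes, paths["genes"])
    return paths
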