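"""Genotype containers, VCF/TSV/BED input-output, and the study-style filters.

Coordinate conventions (binding for the whole package):

* site positions are 1-based (VCF convention) inside :class:`GenotypeMatrix`;
* all window and BED arithmetic at module interfaces is 0-based half-open,
  so a 50 kb window starting at bp 1 is written as ``start=0, end=50000``;
* gene annotations are stored 1-based inclusive in memory and written as
  0-based half-open BED on disk.

Missing genotypes use the sentinel :data:`MISSING` (−1) and are never
conflated with homozygous reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("divscape")

#: genotype code for a missing diploid call
MISSING = -1

WINDOW_TABLE_COLUMNS = ["chrom", "start", "end", "n_sites", "fst", "dxy"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid genotypes (alt-allele dosage 0/1/2, −1 missing) × sites.

    ``geno`` has shape ``(n_samples, n_sites)``; positions are 1-based and
    strictly increasing within each chromosome; every sample carries a
    population label in ``pop_of``.
    """

    samples: list[str]
    pop_of: dict[str, str]
    chrom: np.ndarray          # (n_sites,) str
    pos: np.ndarray            # (n_sites,) int64, 1-based
    ref_alt: np.ndarray        # (n_sites, 2) str; alt "." at invariant sites
    geno: np.ndarray           # (n_samples, n_sites) int8
    is_variant: np.ndarray     # (n_sites,) bool
    gq: np.ndarray | None = None   # per-genotype quality, same shape as geno
    dp: np.ndarray | None = None   # per-genotype depth, same shape as geno

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.is_variant = np.asarray(self.is_variant, dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return self.pos.size

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.pop_of[s], None)
        return list(seen)

    def sample_indices(self, population: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples)
               if self.pop_of[s] == population]
        if not idx:
            raise ValueError(f"unknown population label: {population!r}")
        return np.asarray(idx, dtype=np.intp)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref_alt=self.ref_alt[index],
            geno=self.geno[:, index],
            is_variant=self.is_variant[index],
            gq=None if self.gq is None else self.gq[:, index],
            dp=None if self.dp is None else self.dp[:, index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        samples = [self.samples[i] for i in index]
        return replace(
            self,
            samples=samples,
            pop_of={s: self.pop_of[s] for s in samples},
            geno=self.geno[index, :],
            gq=None if self.gq is None else self.gq[index, :],
            dp=None if self.dp is None else self.dp[index, :],
        )

    def validate(self) -> None:
        if self.geno.shape != (self.n_samples, self.n_sites):
            raise ValueError("geno dimensions do not match samples × sites")
        for s in self.samples:
            if s not in self.pop_of:
                raise ValueError(f"sample {s!r} has no population label")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(
                    f"positions not strictly increasing on {c}")
        ok = (self.geno >= MISSING) & (self.geno <= 2)
        if not ok.all():
            raise ValueError("genotype codes outside {0,1,2,missing}")


@dataclass
class ChromMap:
    """Ordered chromosomes with lengths and an autosome/Z flag."""

    names: list[str]
    length_bp: dict[str, int]
    z_chroms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        for n in self.names:
            if self.length_bp[n] <= 0:
                raise ValueError(f"chromosome {n} has non-positive length")

    def is_z(self, name: str) -> bool:
        return name in self.z_chroms

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChromMap":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["name", "length", "type"], dtype=str)
        names = df["name"].tolist()
        lengths = {n: int(l) for n, l in zip(df["name"], df["length"])}
        z = {n for n, t in zip(df["name"], df["type"].fillna("A"))
             if str(t).upper() == "Z"}
        return cls(names, lengths, z)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for n in self.names:
                kind = "Z" if n in self.z_chroms else "A"
                fh.write(f"{n}\t{self.length_bp[n]}\t{kind}\n")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval (1-based inclusive) with a bill/body trait tag."""

    name: str
    chrom: str
    start: int
    end: int
    trait: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start > end")


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_pop_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample, population) → mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["pop"]))


def read_vcf(path: str | Path, pop_table: Mapping[str, str] | str | Path,
             ) -> GenotypeMatrix:
    """Read a VCF 4.x file (variant + invariant records) into a matrix.

    Multiallelic records and indels are dropped (count logged).  Every
    sample in the VCF must appear in ``pop_table``.
    """
    from cyvcf2 import VCF

    if not isinstance(pop_table, Mapping):
        pop_table = read_pop_table(pop_table)

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    for s in samples:
        if s not in pop_table:
            raise ValueError(f"sample {s!r} in VCF absent from the "
                             "population table")

    chroms: list[str] = []
    poss: list[int] = []
    ref_alt: list[tuple[str, str]] = []
    genos: list[np.ndarray] = []
    gqs: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    is_var: list[bool] = []
    n_multi = 0
    n_indel = 0
    has_gq = has_dp = False

    for v in vcf:
        alts = [a for a in v.ALT if a not in (".", "")]
        if len(alts) > 1:
            n_multi += 1
            continue
        if len(v.REF) != 1 or any(len(a) != 1 or a == "*" for a in alts):
            n_indel += 1
            continue
        # gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        chroms.append(v.CHROM)
        poss.append(v.POS)
        ref_alt.append((v.REF, alts[0] if alts else "."))
        genos.append(g)
        is_var.append(bool(alts))
        gq = v.gt_quals
        if gq is not None:
            has_gq = True
            gqs.append(np.asarray(gq, dtype=np.float32))
        dpv = v.gt_depths
        if dpv is not None:
            has_dp = True
            dps.append(np.asarray(dpv, dtype=np.int32))

    if not poss:
        raise ValueError(f"empty VCF (no usable records): {path}")
    if n_multi or n_indel:
        logger.info("read_vcf: dropped %d multiallelic and %d indel records",
                    n_multi, n_indel)

    gm = GenotypeMatrix(
        samples=samples,
        pop_of={s: pop_table[s] for s in samples},
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref_alt=np.asarray(ref_alt, dtype=object),
        geno=np.vstack(genos).T.astype(np.int8),
        is_variant=np.asarray(is_var, dtype=bool),
        gq=np.vstack(gqs).T if has_gq and len(gqs) == len(poss) else None,
        dp=np.vstack(dps).T if has_dp and len(dps) == len(poss) else None,
    )
    gm.validate()
    return gm


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path,
              chrom_map: ChromMap | None = None) -> None:
    """Write a plain-text VCF 4.2 with GT (and GQ/DP when present)."""
    fmt_keys = ["GT"]
    if gm.gq is not None:
        fmt_keys.append("GQ")
    if gm.dp is not None:
        fmt_keys.append("DP")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=divscape\n")
        if chrom_map is not None:
            for c in chrom_map.names:
                fh.write(f"##contig=<ID={c},length={chrom_map.length_bp[c]}>\n")
        else:
            seen: dict[str, int] = {}
            for c, p in zip(gm.chrom, gm.pos):
                seen[c] = max(seen.get(c, 0), int(p))
            for c, ln in seen.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.gq is not None:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                     'Description="Genotype quality">\n')
        if gm.dp is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                     'Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j in range(gm.n_sites):
            ref, alt = gm.ref_alt[j]
            fields = []
            for i in range(gm.n_samples):
                parts = [_GT_STR[int(gm.geno[i, j])]]
                if gm.gq is not None:
                    parts.append(str(int(gm.gq[i, j])))
                if gm.dp is not None:
                    parts.append(str(int(gm.dp[i, j])))
                fields.append(":".join(parts))
            fh.write(f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{ref}\t{alt}\t.\t.\t.\t"
                     + ":".join(fmt_keys) + "\t" + "\t".join(fields) + "\n")


def write_pop_table(pop_of: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, p in pop_of.items():
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_sites_and_individuals(
    gm: GenotypeMatrix,
    min_gq: float | None = 30,
    min_dp: float | None = 8,
    site_call_rate: float | None = 0.7,
    mac_rule: str | None = "mac_ge3",
    max_indiv_missing: float | None = 0.3,
) -> GenotypeMatrix:
    """Apply the study's genotype, site and individual filters (in that order).

    1. genotype mask: calls with GQ < ``min_gq`` or DP < ``min_dp`` become
       missing (requires ``gm.gq``/``gm.dp``);
    2. site filters: sites called in fewer than ``site_call_rate`` of
       individuals dropped; variant sites failing the minor-allele-count
       rule dropped.  ``mac_rule`` is ``"mac_ge3"`` (default: drop variant
       sites with MAC < 3, i.e. exclude singletons and doubletons),
       ``"literal_le2"`` (keep only variant sites with MAC ≤ 2) or None;
    3. individuals missing more than ``max_indiv_missing`` of the retained
       sites are dropped.

    Pass ``None`` for any threshold to disable that filter.
    """
    geno = gm.geno.copy()
    if min_gq is not None:
        if gm.gq is None:
            raise ValueError("min_gq requested but matrix has no GQ values")
        geno[gm.gq < min_gq] = MISSING
    if min_dp is not None:
        if gm.dp is None:
            raise ValueError("min_dp requested but matrix has no DP values")
        geno[gm.dp < min_dp] = MISSING

    called = geno != MISSING
    keep_site = np.ones(gm.n_sites, dtype=bool)
    if site_call_rate is not None:
        keep_site &= called.mean(axis=0) >= site_call_rate
    if mac_rule is not None:
        g = np.where(called, geno, 0)
        alt = g.sum(axis=0)
        n_called = 2 * called.sum(axis=0)
        mac = np.minimum(alt, n_called - alt)
        if mac_rule == "mac_ge3":
            mac_ok = mac >= 3
        elif mac_rule == "literal_le2":
            mac_ok = mac <= 2
        else:
            raise ValueError(f"unknown mac_rule: {mac_rule!r}")
        keep_site &= ~gm.is_variant | mac_ok
    if not keep_site.any():
        raise ValueError(f"all {gm.n_sites} sites removed by site filters")

    out = replace(gm, geno=geno).take_sites(np.flatnonzero(keep_site))

    if max_indiv_missing is not None:
        miss = (out.geno == MISSING).mean(axis=1)
        keep_ind = miss <= max_indiv_missing
        if not keep_ind.any():
            raise ValueError(
                f"all {gm.n_samples} individuals removed "
                f"(missingness > {max_indiv_missing})")
        n_drop = int((~keep_ind).sum())
        if n_drop:
            logger.info("filter: dropped %d individuals for missingness",
                        n_drop)
        out = out.take_samples(np.flatnonzero(keep_ind))
    return out


# ---------------------------------------------------------------------------
# window tables, regions, gene annotations
# ---------------------------------------------------------------------------

def write_window_table(wt: pd.DataFrame, path: str | Path) -> None:
    """Window table → TSV (chrom, start, end, n_sites, fst, dxy)."""
    wt.to_csv(path, sep="\t", index=False,
              columns=WINDOW_TABLE_COLUMNS, float_format="%.10g")


def read_window_table(path: str | Path) -> pd.DataFrame:
    wt = pd.read_csv(path, sep="\t")
    missing = set(WINDOW_TABLE_COLUMNS) - set(wt.columns)
    if missing:
        raise ValueError(f"window table missing columns: {sorted(missing)}")
    return wt


def write_regions_bed(regions: Sequence, path: str | Path) -> None:
    """Region calls → BED6 (0-based half-open; score = mean F_ST × 1000)."""
    with open(path, "w") as fh:
        for r in regions:
            score = int(r.mean_fst * 1000)  # truncation toward zero
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.kind}\t{score}\t.\n")


def read_genes_bed(path: str | Path) -> list[GeneAnnotation]:
    """BED4 + trait column → gene annotations (converted to 1-based)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end, name = parts[:4]
            trait = parts[4] if len(parts) > 4 else ""
            genes.append(GeneAnnotation(name=name, chrom=chrom,
                                        start=int(start) + 1, end=int(end),
                                        trait=trait))
    return genes


def write_genes_bed(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.name}\t{g.trait}\n")
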