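# Methods

`divscape` reimplements, as a tested library + CLI, the analytical pipeline
used to characterize the genomic landscape of divergence across a set of
diverging bird populations: windowed relative and absolute divergence,
distributional-skew analysis of F_ST, permutation-based detection of genomic
islands and valleys, a PCA-based outlier-SNP scan, and a neutral forward-time
divergence simulator. This note records the models, the parameters that
matter, the numerical choices, and the limits of what the synthetic tests
demonstrate.

## Divergence statistics

**Weir–Cockerham F_ST.** Per biallelic site, the two-population variance
components a (among populations), b (among individuals within populations)
and c (within individuals) are computed from per-population sample sizes
(genotyped diploids), alt-allele frequencies and *observed* heterozygote
frequencies — the 1984 moment estimator with r = 2. A window's F_ST is the
ratio of sums Σa / Σ(a+b+c) over its usable sites, not the mean of per-site
ratios: per-site ratios are noisy and bias-prone, and the ratio-of-sums is
the standard window estimator. Negative window values are retained (not
clamped) so the downstream skew statistic sees the estimator's true
distribution. Sites where either population has no genotyped individual are
unusable; invariant sites carry no F_ST information (they contribute nothing
to either sum).

**d_xy.** Per site, d_xy = p₁(1−p₂) + (1−p₁)p₂ with pᵢ the per-population
alt frequencies; invariant sites have d_xy = 0. A window's d_xy is the mean
over usable sites, *variant and invariant* — the genotyping pipeline this
mirrors emitted all confident sites, so the all-sites denominator is the
default (a variant-only denominator is selectable via site masks).

**Windows.** Non-overlapping tiles of 5 kb / 50 kb / 100 kb (library
functions take any size). Windows with fewer than 10 usable sites are
omitted; `harmonize_windows` restricts tables from several population
comparisons to their common windows, mirroring the rule that only windows
with statistics for all comparisons are analyzed. Internally site positions
are 1-based (VCF); every window/BED interface is 0-based half-open.

**Filters.** The study-style filter chain is fixed: genotype mask
(GQ < 30 or DP < 8 → missing), then site filters (call rate ≥ 70 %,
minor-allele-count rule), then individuals missing > 30 % of retained
sites are dropped. The source text's MAC wording ("≤ 2") would *keep only*
singletons and doubletons and discard nearly all variation; the default
`mac_rule="mac_ge3"` reads it as a typo and drops variant sites with
MAC < 3, while `"literal_le2"` reproduces the literal text. Neither is
asserted to be the original intent.

## Skew analysis

Skewness is g₁ = m₃ / m₂^{3/2} with 1/n central moments — the plainest
reading of "third moment"; the bias-corrected G₁ is available by flag but
all shipped results use g₁. The randomization test pools two comparisons'
window F_ST values, reallocates them without replacement into groups of the
original sizes (default 10,000 times), and uses the add-one Monte-Carlo
p-value p = (1 + #{T_rand ≥ T_obs}) / (n_rand + 1) for T = |Δskew|, which is
a valid p-value and never exactly zero. Confidence intervals for mean or
skew are percentile block bootstraps over 500 kb blocks of consecutive
windows per chromosome; blocks truncated by a chromosome end are kept if
they contain at least one window (discard rules would silently drop data).

## Island / valley scan

Per chromosome, window F_ST values are smoothed with a symmetric box moving
average. "Bandwidth 20" is implemented as half-width `bandwidth // 2`
(support 21 windows at the default); at chromosome edges the support is
truncated and renormalized rather than reflected — reflection fabricates
data at chromosome ends. The null envelope permutes window order within the
chromosome (default 10,000 permutations), smooths each permuted series, and
keeps the single most extreme smoothed value in each direction across all
permutations and positions (streamed; lines are never materialized). This
per-chromosome global extremum is the strictest reading of "most extreme
value"; whether the original permuted genome-wide is unknown, and
per-chromosome is the conservative default.

Islands are maximal runs strictly above the upper threshold, valleys
strictly below the lower one; same-kind runs separated by ≤ 10 windows are
merged (gap windows join the span), and island and valley runs are never
merged with each other. Each region's d_xy is contrasted against its
chromosomal background with a one-sample Wilcoxon signed-rank test of the
region's window d_xy values against the background median (the original
names signed-rank but not the pairing; a background excluding only the
tested region is the default). All region values equal to the background
median yields p = 1 by convention. Region sizes across comparisons are
compared with Kruskal–Wallis; same-kind regions of different comparisons at
overlapping positions are grouped transitively.

## Outlier scan

A faithful reimplementation of the published PCA/Mahalanobis scan — not a
wrapper, and exact numerical agreement with the original package is not
promised (its internals changed across versions). Genotypes are mean-imputed
per SNP (standard for PCA scans; the source is silent), centered and scaled
by √(2p(1−p)); the top K = 2 axes are extracted by SVD; each SNP is
regressed on the K orthonormal sample scores and its K-vector of z-scores
retained; the robust (minimum-covariance-determinant) Mahalanobis distance
of these vectors is divided by a genomic inflation factor
(median D² / χ²_K median) and referred to χ²_K; q-values are
Benjamini–Hochberg, outliers have q ≤ 0.01. MAF (default ≥ 0.2) is computed
on the pooled two-population sample, since the scan is run per comparison.
LD pruning precedes the scan: sliding 1000 kb windows advanced one SNP at a
time, removing the later SNP of any pair with genotype r² > 0.8 —
deterministic given input order.

Null calibration is interpreted as: on structureless data essentially no
SNP may be flagged (the falsely-flagged fraction of tests stays within 2×
the nominal FDR, and mean flags per replicate ≈ 0). The textbook FDP
(false/total discoveries) is degenerate on pure-null data — any single flag
makes it 1 — so the per-test fraction is the meaningful control quantity.

## Neutral divergence simulator

Two populations of diploids (initial size 400 each) evolve on discrete,
non-overlapping generations. Both are initialized from the same ancestral
pool — either per-SNP genotype frequencies (sampling with replacement,
random phasing) or allele frequencies under Hardy–Weinberg — so generation-0
F_ST ≈ 0. Sexes are fair Bernoulli. Each generation:

1. **Fitness**: every individual draws Poisson(λ) − N·σ_dem, truncated at
   zero, independent of genotype (neutrality). Female values are
   stochastically rounded to integers (mean-preserving); male values are
   rescaled with largest-remainder rounding so Σmale = Σfemale exactly.
   Defaults λ = 3.0 offspring and σ_dem = (λ−2)/400 = 0.0025 per extra
   individual: the equilibrium condition "mean fitness ≈ 2 at N ≈ 400"
   (monogamous replacement) fixes σ_dem once λ is chosen; the original
   study's exact demographic table is not printed in its main text, so
   these are calibrated, not transcribed, and both are config-exposed.
   This holds each population at ~410 individuals (~160 breeding pairs,
   inside the empirically motivated 100–300 range).
2. **Pairing**: males and females with positive fitness are sorted by
   fitness (ties broken by index, stable) and paired by rank; surplus
   individuals do not reproduce; a pair's offspring count is the female's
   fitness. Because fitness is random and genotype-independent, this is
   equivalent to random monogamous mating.
3. **Recombination**: crossovers form a homogeneous Poisson process along
   the chromosome (rate c per bp; 3 cM/Mb ↔ c = 3×10⁻⁸). The reference
   `make_gamete` draws Poisson(c·L) breakpoints uniformly and alternates
   source haplotypes from a fair-coin start. The production path uses an
   exactly equivalent vectorized form: only the *parity* of the crossover
   count between adjacent SNPs affects a gamete, and that parity is
   Bernoulli((1 − e^{−2c·gap})/2) independently per inter-SNP interval.
   A distributional test checks the two routes agree.
4. **Migration**: each offspring independently switches population with
   probability m. No mutation is modeled, so loci can fix permanently.
5. **Reporting**: at intervals, 20 diploids are sampled per population and
   windowed Weir–Cockerham F_ST (500 kb windows, ratio of sums; windows
   with no usable variance dropped) is recorded.

The default synthetic chromosome is 62 Mb with uniformly placed SNPs and
Uniform(0.05, 0.95) initial alt frequencies — a polymorphic stand-in pool;
SNP count is config-scaled for desk runs (1,000 by default).

**Expected behaviour and a known quantitative offset.** With m = 0 the mean
windowed F_ST exceeds 0.9 by generation 2,000 (fixation regime); with
m = 0.01 it stays below 0.1 throughout; with m = 0.001 it rises for a few
hundred generations and then plateaus. For the plateau level, two-deme
island-model theory gives F_ST ≈ 1/(1 + 8·N_e·m). The calibration above
yields a measured N_e ≈ 320 (from heterozygosity decay; N_e/N ≈ 0.8 matches
the offspring-count variance of this mating scheme), hence a plateau of
≈ 0.28 — and the simulator indeed equilibrates at ≈ 0.26–0.30 across seeds.
A plateau of ≈ 0.2, as the original study reports, would require N_e ≈ 500,
i.e. density regulation near the top of the 100–300 breeding-pair range.
Because the original demographic constants are unpublished, the calibration
is left as stated rather than being adjusted to reproduce the published
plateau, and the equilibrium acceptance check is expected to fail by this
documented margin (≈ 0.28 vs ≈ 0.2). All other regime properties hold.

## Synthetic data

The Balding–Nichols generator draws ancestral frequencies p and
per-population frequencies from Beta(p(1−F)/F, (1−p)(1−F)/F), so genome-wide
Weir–Cockerham F_ST recovers F (checked at F = 0.1 within ±0.02 at 20,000
SNPs). Spiked landscapes place island intervals (elevated F, moderate
ancestral MAF) and valley intervals (F ≈ 0 with ancestral MAF ≤ 0.05, hence
reduced diversity and d_xy) at known coordinates; invariant sites are
interleaved so windowed d_xy denominators are exercised. What these
fixtures do *not* emulate: linkage disequilibrium (sites are independent
given frequencies — the neutral simulator is the mechanistic generator with
real linkage), RAD-style ascertainment, genotyping-error structure, or
realistic site-frequency spectra. Passing tests therefore demonstrate
correctness of the estimators and callers under known truth, not robustness
to those real-data features.

## Problem sizes and determinism

Test-suite simulations use reduced problem sizes chosen as desk-scale
defaults: 300 SNPs for 2,000-generation regime checks, 100-window noise
landscapes with the full 10,000 permutations for false-call calibration,
5,000-SNP outlier power checks, and 500 replicate randomization tests for
type-I error. The acceptance script runs the simulator at 1,000 SNPs on the
full 62 Mb chromosome for 2,000 generations over three seeds. Every
stochastic component takes a `numpy` Generator seed; fixed seeds give
bit-identical trajectories and scan results, and the CLI derives per-module
substreams from one master seed via SHA-256 so a single integer reproduces a
whole pipeline run.

## Known limitations

* Chromosome Z is treated as diploid in both sexes (no sexing procedure is
  modeled); Z-linked F_ST is therefore comparable across comparisons but
  not corrected for hemizygosity.
* The empirical skew/island/valley values of the original study require its
  deposited VCFs and are not recomputed here; the pipeline reproduces the
  procedures, with the simulator and synthetic generators supplying truth.
* Single-chromosome simulation only; no mutation, selection, or phenotype
  layer.
* The outlier scan reproduces the published algorithm, not any specific
  release of the original package; counts on real data may differ in detail.
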