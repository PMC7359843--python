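# popgenpipe

Population-genomic inference for multi-population SNP datasets of the kind
produced by RAD sequencing of structured bird populations: demographic
history by approximate Bayesian computation (ABC), genome-wide diversity
and differentiation statistics, genome scans for local adaptation, and
detection and dating of polymorphic chromosomal inversions.

The motivating design is a passerine sampled across two nested contrasts —
a mainland/island split with moderate differentiation (F_ST ≈ 0.08) and
paired deciduous/evergreen forest habitats with very weak differentiation
(F_ST ≈ 0.003) — but every component takes ordinary VCF + metadata input.

## What is inside

| module | contents |
| --- | --- |
| `genotype_io` | VCF + sample-metadata I/O, the post-genotyping filter chain (depth, call rates, heterozygosity excess, GRM relatedness, population caps), LD pruning |
| `popgen_stats` | Weir–Cockerham F_ST (per SNP, pairwise with locus bootstrap, 200 kb and 50-SNP windows), Ho, MAF spectra, VanRaden GRM, composite-LD r² and decay curves, LD-based recent N_e, runs of homozygosity, Hardy–Weinberg χ², F_ST-versus-recombination analysis |
| `demography` | the 20 two-population divergence-model variants (PAN/EQ/SI/IM/AM/SC × N/M heterogeneity), prior sampling, msprime coalescent simulation of RAD-like loci, ABC summary statistics (π, θ_W, d_xy, Da, F_ST, Wakeley–Hey site classes) |
| `abc` | rejection + multinomial-logistic model choice, regression-adjusted parameter posteriors with prior-overlap diagnostics, unit conversions (M = 4N₀m, N_e·m migrants, generations → years at 2.3 yr/gen) |
| `rda` | redundancy analysis, partial RDA with conditioning covariates, permutation tests, 3-SD loading outliers |
| `inversion` | windowed PCA with exact 1-D cluster selection, local-PCA/MDS block scan, karyotype assignment, arrangement-stratified F_ST/π/d_xy, inversion dating T = Da/2µ, UPGMA trees |
| `synthetic_data` | study-like synthetic datasets with planted habitat outliers, a planted inversion, and JSON ground truth |
| `cli` | `popgenpipe` command with subcommands `simulate-data`, `filter`, `stats`, `scan-fst`, `scan-rda`, `abc-simulate`, `abc-fit`, `inversion` |

The `analysis/` directory holds the numbered drivers that run the full
study workflow over a synthetic dataset and write their tables under
`results/`.

## The core models

**Divergence scenarios.** Two populations are related by one of: panmixia
(PAN), the equilibrium two-deme island model (EQ), strict isolation (SI),
isolation with migration (IM), ancient migration (AM: gene flow from
T_split until T_am) or secondary contact (SC: gene flow since T_sc).
Migration is scaled as M = 4N₀m. Per-locus Beta-distributed scaling of N_e
or m (rescaled to mean 1) emulates linked selection and barrier loci,
giving 20 model variants. ABC compares models on mean/SD-across-loci
summary statistics after MAD standardisation, with multinomial logistic
regression on the accepted simulations.

**F_ST.** Weir & Cockerham (1984) variance components, combined as ratios
of sums for every multi-SNP estimate; window scans flag the top 1% as
empirical outliers.

**Inversions.** A segregating inversion shows up as three PC1 clusters
(arrangement homozygotes and heterozygotes) in windows, and as
covariance-outlier blocks in a local-PCA/MDS scan. Karyotypes come from
exact 1-D clustering of the region PC1; the net divergence between
arrangement homozygotes dates the inversion as T = Da/(2µ).

## Worked example

```
python analysis/01_simulate_study.py
python analysis/02_filter_genotypes.py
python analysis/06_inversion.py
```

prints (abridged):

```
study written to .../results/study
  samples: 120  (12 per population)
  inversion region: ['chr3', 1200001, 4000000], arrangement split 11000 generations ago
  planted karyotypes: {'INV/INV': 2, 'INV/STD': 8, 'STD/STD': 110}

input : 120 samples x 18044 variants
output: 120 samples x 17794 variants
  removed    29 variants (region_het_excess)
  removed   221 variants (monomorphic)

local PCA: 178 blocks, 8 outliers
confirmed inversion calls: 1 (truth: ['chr3', 1200001, 4000000])
  region ('chr3', 1140076, 3980004): karyotype accuracy 1.00,
  mainland arrangement freq 17% (HWE p = 0.23)
  FST inside 0.45 vs outside 0.0454; Da = 0.0051 -> age 12,790 generations
  pi: INV/INV 0.00728, STD/STD 0.00623, heterozygotes 0.00920
```

Reading this: the generator planted a 2.8 Mb inversion on chr3 whose two
arrangements split ~11,000 generations ago; the local-PCA scan finds one
candidate region within ~60 kb of the planted boundaries, assigns every
sample its true karyotype, measures strong arrangement differentiation
inside the region against near-zero background, reproduces the expected
diversity ordering (heterozygotes most diverse, because they carry both
arrangements), and dates the inversion within ~16% of truth from Da alone.
`analysis/03`–`05` run the diversity, ABC and genome-scan stages the same
way; between-region F_ST comes out at 0.077 and habitat-pair F_ST at
0.003–0.008, the magnitudes the generator is calibrated to.

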