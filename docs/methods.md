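# Methods

This note documents the models, estimators and numerical choices behind
`popgenpipe`, and what the synthetic study that exercises them does and does
not emulate.

## The inference problem

The pipeline addresses a common population-genomics design: diploid SNP
genotypes (RAD-seq scale, ~10⁴–10⁵ markers) from ~10 populations of a
passerine bird sampled across two nested contrasts — a mainland/island split
with moderate differentiation, and paired deciduous/evergreen forest
habitats with very weak differentiation. From these data it (1) infers
demographic history by ABC model choice among two-population divergence
scenarios, (2) quantifies diversity and differentiation (Ho, MAF spectra,
Weir–Cockerham F_ST, LD decay and LD-based recent N_e, runs of
homozygosity), (3) scans the genome for habitat-associated outliers (window
F_ST and redundancy analysis), and (4) detects, genotypes and dates
polymorphic chromosomal inversions.

## Divergence models and coalescent simulation (`demography`)

Six base scenarios relate two focal populations: panmixia (PAN), the
two-deme equilibrium island model (EQ, no divergence time), strict isolation
(SI), isolation with continuous migration (IM), ancient migration (AM: gene
flow from the split at T_split until T_am, then isolation) and secondary
contact (SC: isolation after the split, gene flow since T_sc). Migration is
parameterised as M = 4·N₀·m, with M₁₂ scaling migrants into population 1
from population 2. Genomic heterogeneity in drift (linked selection) and in
migration (barrier loci) is modelled by multiplying per-locus N_e or m by an
independent Beta(a, b) draw rescaled by its mean a/(a+b), so the genome-wide
average stays at the nominal parameter and the hyper-parameters stay
orthogonal to the scale parameters. Crossing the heterogeneity switches
gives 4 variants per gene-flow scenario and 2 for PAN/SI — 20 variants.

Loci are RAD-like: 85 bp, crossover-free, mutually independent,
infinite-sites mutation at rate `mu` per bp per generation (default 1e-8;
simulation budgets below use a compressed rate so short loci carry
realistic SNP numbers). The structured coalescent is simulated with
msprime; EQ requires M₁₂+M₂₁ > 0 so lineages can coalesce.

Summary statistics per dataset: mean and SD across loci of π per
population, Watterson θ per population, d_xy, net divergence
Da = d_xy − (π₁+π₂)/2, per-locus F_ST (1 − π_within/π_total), and the
Wakeley–Hey site classes (private s_x1/s_x2, shared s_s, fixed s_f), plus
the across-locus Pearson correlation of π₁ with π₂ — 23 values in a fixed
order.

Prior defaults (all configurable): log-uniform N_e ∈ [10², 10⁶]; log-uniform
T_split ∈ [10³, 3·10⁶] generations; T_am and T_sc uniform as fractions of
T_split; M ∈ [0, 40] uniform, with a documented wide option M ∈ [0, 200];
Beta hyper-parameters log-uniform in [0.1, 10]. These bounds are declared
package defaults, not estimates.

## ABC (`abc`)

Summary statistics are standardised by the reference table's median absolute
deviation (statistics with zero spread are dropped); distance is Euclidean.
Rejection keeps the closest `tolerance` fraction (at least 100, error below
50). Model probabilities come from multinomial logistic regression on the
accepted rows evaluated at the observed point, falling back to rejection
proportions when the regression cannot be fit; a hierarchical option picks
the base scenario family first, then the heterogeneity variant. Parameter
posteriors use the Beaumont local-linear regression adjustment with
Epanechnikov weights; positive-scale parameters (sizes, times) are adjusted
on the log scale. The prior-overlap diagnostic reports the posterior mass
inside the central 50% of the prior (≈0.5 when the posterior merely
reproduces the prior; flagged "differentiated" below 0.25 or above 0.75).

Candidate sets follow the study design rather than always using all 20
variants: habitat pairs are compared across gene-flow scenarios, while the
island–mainland contrast is an AM-versus-SI comparison. At desk scale an EQ
model with free migration absorbs the signature of a long migration epoch,
so including it there makes the comparison unidentifiable — the pairwise
re-comparison (renormalising the top two models) is available for exactly
this situation.

Unit conversions: years = generations × generation time (default 2.3
yr/generation); migrants per generation N_e·m; scaled migration 4·N₀·m.

## Core statistics (`popgen_stats`)

*F_ST.* Weir & Cockerham (1984) variance components a (among populations),
b (among individuals within populations) and c (within individuals) are
computed per SNP for two or more populations, requiring ≥2 genotyped
diploids in ≥2 groups. All multi-SNP estimates are ratios of sums
(Σa / Σ(a+b+c)) — not means of ratios — matching standard weighted-window
practice; windows come in a fixed-width mode (default 200 kb) and a
SNP-count mode (50-SNP blocks sliding by 5) that equalises information
across recombination environments. The top 1% of windows are flagged as
empirical outliers; no FDR correction is added. Pairwise F_ST carries a
locus-bootstrap p-value for F_ST > 0 and an autosome/Z split when a
chromosome-class map is supplied.

*Relatedness.* VanRaden GRM: dosages centred by 2p̂ and scaled by Σ2p̂(1−p̂);
missing entries contribute zero after centring. Note the centring uses
sample frequencies: with very small or heavily related panels the estimates
shrink, so relatedness filtering assumes a reasonably large panel.

*LD and N_e.* r² is the squared dosage correlation (composite LD, no
phasing needed). The decay curve is the mean per distance bin with an
optional moving average. The LD-based N_e estimator inverts
E[r²] ≈ 1/(α + 4N_e c) + 1/(2n) per bin (α = 2 by default, map distance at
1 cM/Mb), giving N_e at time ≈ 1/(2c) generations; bins whose
sample-size-corrected r² is non-positive are skipped with a warning.

*ROH.* Maximal stretches of non-missing homozygous genotypes (up to
`max_het` heterozygous calls, default 0), segmented at 100 SNPs, emitted at
≥500 kb; group contrasts use the Wilcoxon rank-sum test on segment lengths.

*HWE.* The textbook 1-df Pearson chi-square on genotype counts; fixed
samples return χ²=0, p=1.

*F_ST versus recombination.* Each SNP takes the ρ = 4N_e·r of its containing
track interval (SNPs outside the track are dropped); OLS slope and p, a
LOESS curve, and outlier enrichment over ρ deciles by chi-square plus a
Welch t-test on mean ρ. Fewer than two populated deciles (e.g. a constant
track) skips the enrichment.

## Redundancy analysis (`rda`)

Y is the mean-imputed, column-centred dosage matrix; predictors are
standardised, with constant and collinear columns dropped (warning). The
constrained axes are the SVD of the fitted values of the multivariate least
squares of Y on X; eigenvalues are singular values squared over (n−1).
Significance uses a pseudo-F permutation test over rows of X (global) and,
per predictor, permutation of that predictor's residuals given the others.
Partial RDA residualises both Y and X on the conditioning matrix first.
Loading outliers are SNPs more than 3 SD from the axis mean on the first
axes (axis 1 by default for the single-predictor habitat test).

## Inversion detection (`inversion`)

A polymorphic inversion suppresses recombination between arrangements, so
inside it samples separate into three PC1 clusters (two arrangement
homozygotes, heterozygotes between them) and the local sample covariance
differs from the genome background.

*Local PCA / MDS.* Non-overlapping 100-SNP blocks (split at chromosome
boundaries); the block distance is the Frobenius distance between
unit-normalised rank-2 approximations of the sample covariance; classical
MDS embeds blocks in 2-D. Outliers deviate by more than 3×1.4826×MAD on
either embedded axis — with strong shared population structure the
background occupies the first axis and an inversion can surface on the
second, so restricting to MDS1 misses it. Confirmed candidate regions need
at least three consecutive outlier blocks deviating on the same axis with
the same sign; isolated outlier blocks are treated as noise.

*Window PCA.* 10 Mb/1 Mb windows sliding by 1 Mb/100 kb; per window the PC1
scores are clustered in 1-D. Clustering is exact: contiguity of optimal
1-D clusters lets dynamic programming maximise a per-cluster Gaussian
likelihood (per-cluster variance floored at 2% of the range, multinomial
mixing weights, minimum cluster size 2) — plain k-means SSE sacrifices a
small extreme cluster to split a large diffuse bulk, which is precisely the
failure mode with a handful of inversion homozygotes. k ∈ {1,2,3} is chosen
by BIC. A window is flagged trimodal when k=3 wins, the middle centroid
lies within 25% of the outer centroids' half-span, and PC1 explains more
than twice the genome-median window variance fraction; the last condition
removes windows whose PC1 is a couple of chance-LD SNPs, which otherwise
produce genuinely trimodal dosage clusters in a large share of null
windows.

*Karyotyping.* Region PC1 is clustered at k=3, allowing singleton clusters
here (a single inverted homozygote is common at realistic arrangement
frequencies and is genuine evidence inside a region the MDS scan already
flagged; the genome-wide window scan keeps a minimum cluster size of 2 for
specificity); the call is demoted to an
unassigned candidate unless the middle cluster sits near the midpoint of
the outer centroids **and** is the most heterozygous cluster in the region
(this stands in for an admixture-proportion check on heterozygotes: same
prediction, no extra tool). The minor homozygote cluster is labelled the
inverted arrangement — polarity by minor frequency, which the synthetic
truth records so the assumption itself is testable. Detected regions are
then refined to SNP resolution: the per-SNP correlation between genotype
dosage and arrangement dosage is smoothed (25 SNPs), and the region becomes
the longest stretch above the midpoint of the inside/outside medians (gaps
up to 25 SNPs bridged) overlapping the block-level region.

*Arrangement statistics and dating.* F_ST between homozygote karyotype
groups (ratio of sums) inside versus outside the region; π per karyotype
group in 10-kb windows; d_xy between homozygote groups from group allele
frequencies, d_xy = Σ p_x(1−p_y) + p_y(1−p_x) per surveyed bp — equal to
haplotype d_xy in expectation, so no phasing is required. `surveyed_bp`
defaults to the region span (vcftools-style) but should be the RAD-covered
length for sparse data; the synthetic truth records it. The age is
T = Da/(2µ) generations (years at 2.3 yr/generation), valid under no gene
flow between arrangements; Da < 0 is an error, not an age.

*UPGMA.* Average-linkage agglomeration (scipy) emitted as an ultrametric
newick string; children are ordered shorter-branch-first for a canonical
form.

## The synthetic study (`synthetic_data`)

The generator produces the study-shaped fixture all recovery tests run on:
ten populations (A1D, A2D, A2E mainland; B3E–B6E island), 12 diploids each
by default, 85-bp loci every 20 kb on five 5-Mb chromosomes.

*Background demography* (defaults, diploid N_e and generations): leaf
populations split from their region ancestor 800 generations ago and
exchange within-region gene flow at 4Nm = 200; the two region ancestors
derive from a small founding population (N_anc = 100) 260,000 generations
ago, exchanged ancient migration at 4Nm = 40, and have been isolated for
the last 2,500 generations; N_e = 25,000 (mainland) and 10,000 (island).
This is a scaled-down rendition of the history the ABC analysis itself
infers for such systems — deep split with an ancestral bottleneck, a long
migration epoch at ~10 migrants/generation, isolation since the last
glaciation — and it lands the generator's calibration targets from
coalescent expectations: between-region F_ST ≈ 0.075 (target band
0.05–0.12), habitat-pair F_ST ≈ 0.003–0.008 (< 0.01), island Ho below
mainland Ho. The mutation rate default is 2e-7/bp/generation — deliberately
high so ~1,250 short loci yield ~15,000 SNPs; it stands in for the larger
genome fraction a real RAD experiment surveys, and all dating in the
synthetic truth uses the same rate, so recovered ages are internally
consistent.

*Planted habitat outliers.* Twenty whole RAD loci get a between-habitat
allele-frequency shift of δ = 0.25 (deciduous up, evergreen down) at all
their intermediate-frequency SNPs. Shifting whole loci, not isolated SNPs,
is both more faithful (a selected RAD tag carries the shift at every SNP)
and the scale window scans are designed to see. This is a detection-power
plant, not a selection simulation.

*Planted inversion.* A 2.8-Mb region of chr3 is replaced by draws from two
arrangement haplotype pools simulated under strict isolation with split
time T = Da_target/(2µ) (Da_target = 0.0044, pool N_e = 8,000 — chosen so
the region carries realistic SNP density while E[Da] stays at target).
Each chromosome copy of each sample draws its arrangement Bernoulli at the
population's planted frequency (0.14 mainland, 0 island → Hardy–Weinberg
karyotypes) and then one whole-region haplotype from that arrangement's
pool: zero recombination within the region and maximal arrangement LD.
Truth records per-sample karyotypes, the split time, polarity and the
surveyed bp.

*What the generator does not emulate:* read-level error and allele-specific
depth (mean depth is decorative, drawn in-band), linkage between
neighbouring RAD loci (loci are independent, so background LD decay and ROH
structure are thinner than in real data, and the recombination track used
by the F_ST–ρ analysis is an external input rather than an emergent
property), a Z chromosome, and selection as a process (outliers are
frequency shifts). Passing recovery tests therefore demonstrate that the
estimators and detectors see what they are built to see at realistic effect
sizes — not that they would be equally powered against every artefact of a
real sequencing pipeline.

## Filtering (`genotype_io`)

The chain runs in the order: mean-depth window [10, 100]; variant call rate
≥ 0.8; removal of variants with observed heterozygosity ≥ 0.65 within
either region (stacked-paralogue guard); sample call rate ≥ 0.85; GRM
relatedness pruning at ≥ 0.35 — pairs are visited in descending relatedness
and the member with more missing genotypes is removed (tie: lexicographic
sample id; the choice rule is a declared package decision); random
per-population cap of 60 using the run seed; monomorphic removal. The chain
repeats until no further removals occur, because sample removal can push
variants below the call-rate or polymorphism thresholds — this makes
filtering idempotent, which a single pass is not. The report records
removal counts per rule in application order.

## Problem sizes and reproducibility

Simulation budgets in the test suite and `scripts/acceptance.py` are
desk-scale by design: ABC reference tables of 400–500 simulations per model
at 100 loci and 10+10 diploids; 10-replicate model-choice experiments;
20-replicate coverage experiments; 500-replicate permutation-calibration
nulls; one default synthetic study (~120 samples × ~16,000 SNPs). The
statistical thresholds these runs are held to (≥7/10 correct model choice,
≥80% credible-interval coverage, 3–7% null rejection at α = 0.05, ≥95%
karyotype accuracy, boundary recovery within one 100-SNP block) do not
depend on the budget. Every stochastic step takes an explicit seed;
regeneration of a study from the same seed is byte-identical.

## Known limitations

- The ABC model probabilities are conditional on the candidate set and the
  declared priors; with wide migration priors EQ and PAN overlap for weakly
  differentiated pairs, and EQ absorbs ancient-migration signal (hence the
  AM-vs-SI design for the island–mainland contrast).
- The LD-based N_e estimator inherits the usual bias of its closed form at
  small sample sizes and short distances; on the synthetic study (no
  intra-locus recombination, independent loci) it only sees between-locus
  pseudo-distances, so its output there is a machinery check, not an
  estimate with real-data meaning.
- Karyotype assignment needs all three karyotypes present and separable; at
  low arrangement frequency and small n the inverted-homozygote cluster may
  hold just 2–3 samples, which the exact 1-D clustering is specifically
  built to keep separate.
- d_xy from unphased dosages equals haplotype d_xy only in expectation;
  per-window values are noisier than phased estimates.
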