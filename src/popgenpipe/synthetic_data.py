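"""Synthetic study generator: a multi-population SNP dataset emulating the
blue-tit study design, with known ground truth.

The default configuration produces ten populations in two regions (three
mainland "A" populations, seven island "B" populations), each population
paired to a deciduous (D) or evergreen (E) habitat, genotyped at RAD-like
short independent loci tiled along five synthetic chromosomes.  The neutral
background is a structured coalescent: leaf populations exchange strong
gene flow within regions, the two region ancestors were connected by weak
ancient migration and have been isolated since a recent epoch — which
yields weak within-region differentiation (FST of a few per mille) and
moderate between-region differentiation (FST close to 0.08).  On top of the
background the generator plants (a) habitat-associated outlier SNPs (a
between-habitat allele-frequency shift, not a selection simulation) and
(b) a polymorphic inversion: a contiguous region where each chromosome copy
carries one of two deeply diverged arrangement haplotypes, with karyotypes
drawn at Hardy-Weinberg proportions at a configured frequency and no
recombination within the region.

Ground truth (planted coordinates, per-sample karyotypes, seeds) round-trips
through JSON so every detector can be scored offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from .genotype_io import (
    GenotypeMatrix,
    METADATA_COLUMNS,
    habitat_of,
    region_of,
    write_metadata,
    write_vcf,
)

DEFAULT_POPULATIONS = (
    "A1D", "A2D", "A2E", "B3E", "B4D", "B4E", "B5D", "B5E", "B6D", "B6E"
)


@dataclass
class StudyConfig:
    """Generator settings; defaults are the study-like desk-scale conditions.

    Sizes/times are in diploids and generations.  The mutation rate is
    per bp per generation and deliberately high for an 85 bp RAD locus so a
    desk-scale number of loci yields enough SNPs for the window machinery;
    it stands in for a larger surveyed genome.
    """

    populations: tuple = DEFAULT_POPULATIONS
    samples_per_population: int = 12
    n_chromosomes: int = 5
    loci_per_chromosome: int = 250
    locus_spacing_bp: int = 20_000
    locus_length_bp: int = 85
    mu: float = 2e-7
    # background demography
    ne_mainland: float = 25_000.0
    ne_island: float = 10_000.0
    ne_ancestral: float = 100.0       # bottleneck at the region split
    t_pop_split: float = 800.0        # leaf populations split from region ancestor
    t_region_isolation: float = 2_500.0   # gene flow between regions stops
    t_region_split: float = 260_000.0
    m_within_scaled: float = 200.0    # 4Nm among populations within a region
    m_ancient_scaled: float = 40.0    # 4Nm between region ancestors before isolation
    # planted habitat outliers: whole RAD loci shifted between habitats
    n_outlier_loci: int = 20
    outlier_delta: float = 0.25
    # planted inversion
    inversion: bool = True
    inversion_chrom: str = "chr3"
    inversion_start: int = 1_200_001
    inversion_end: int = 4_000_000
    inversion_freq_mainland: float = 0.14
    inversion_freq_island: float = 0.0
    inversion_da_target: float = 0.0044
    inversion_ne: float = 8_000.0
    inversion_pool_size: int = 60     # haplotypes simulated per arrangement
    missing_rate: float = 0.02


@dataclass
class StudyTruth:
    """Ground truth of one generated study; JSON round-trippable."""

    seed: int
    config: dict
    outlier_snps: list          # [{chrom, pos, delta}]
    inversion_region: list      # [chrom, start, end] or []
    inversion_t_split: float
    inversion_frequencies: dict  # population -> planted arrangement frequency
    karyotypes: dict            # sample_id -> "INV/INV" | "INV/STD" | "STD/STD"
    surveyed_bp_inversion: int

    FIELDS = (
        "seed", "config", "outlier_snps", "inversion_region",
        "inversion_t_split", "inversion_frequencies", "karyotypes",
        "surveyed_bp_inversion",
    )


def write_truth(truth: StudyTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=2)


def read_truth(path) -> StudyTruth:
    with open(path) as fh:
        data = json.load(fh)
    unknown = set(data) - set(StudyTruth.FIELDS)
    if unknown:
        raise ValueError(f"unknown truth fields: {sorted(unknown)}")
    missing = set(StudyTruth.FIELDS) - set(data)
    if missing:
        raise ValueError(f"missing truth fields: {sorted(missing)}")
    return StudyTruth(**data)


# ---------------------------------------------------------------------------
# Background demography
# ---------------------------------------------------------------------------

def _study_demography(cfg: StudyConfig) -> msprime.Demography:
    dem = msprime.Demography()
    mainland = [p for p in cfg.populations if region_of(p) == "mainland"]
    island = [p for p in cfg.populations if region_of(p) == "island"]
    for p in mainland:
        dem.add_population(name=p, initial_size=cfg.ne_mainland)
    for p in island:
        dem.add_population(name=p, initial_size=cfg.ne_island)

    # within-region island-model gene flow among leaf populations
    for group, ne in ((mainland, cfg.ne_mainland), (island, cfg.ne_island)):
        if len(group) > 1:
            m = cfg.m_within_scaled / (4.0 * ne) / (len(group) - 1)
            for a in group:
                for b in group:
                    if a != b:
                        dem.set_migration_rate(a, b, m)

    anc_names = []
    for group, ne, name in (
        (mainland, cfg.ne_mainland, "mainland_anc"),
        (island, cfg.ne_island, "island_anc"),
    ):
        if group:
            dem.add_population(name=name, initial_size=ne)
            dem.add_population_split(
                time=cfg.t_pop_split, derived=group, ancestral=name
            )
            anc_names.append(name)
    if len(anc_names) == 2:
        # ancient migration between region ancestors, active before isolation
        m_anc_main = cfg.m_ancient_scaled / (4.0 * cfg.ne_mainland)
        m_anc_isl = cfg.m_ancient_scaled / (4.0 * cfg.ne_island)
        dem.add_migration_rate_change(
            time=cfg.t_region_isolation, rate=m_anc_main,
            source="mainland_anc", dest="island_anc",
        )
        dem.add_migration_rate_change(
            time=cfg.t_region_isolation, rate=m_anc_isl,
            source="island_anc", dest="mainland_anc",
        )
        dem.add_population(name="anc", initial_size=cfg.ne_ancestral)
        dem.add_population_split(
            time=cfg.t_region_split, derived=anc_names, ancestral="anc"
        )
    dem.sort_events()
    return dem


def _simulate_background(
    cfg: StudyConfig, rng: np.random.Generator, keep_haplotypes: bool = False
):
    """Simulate all RAD loci and tile them onto synthetic chromosomes.

    Returns (variants DataFrame, dosage matrix, haplotype record).  The
    haplotype record (None unless requested) is a list of per-locus 0/1
    haplotype matrices (2 per diploid, sample-ordered) for ABC use.
    """
    dem = _study_demography(cfg)
    samples = {p: cfg.samples_per_population for p in cfg.populations}
    n_loci = cfg.n_chromosomes * cfg.loci_per_chromosome
    seed_anc = int(rng.integers(1, 2**31 - 1))
    seeds_mut = rng.integers(1, 2**31 - 1, size=n_loci)
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=cfg.locus_length_bp,
        recombination_rate=0.0,
        ploidy=2,
        num_replicates=n_loci,
        random_seed=seed_anc,
    )
    chrom_names = [f"chr{i+1}" for i in range(cfg.n_chromosomes)]
    rows = []
    dosage_cols = []
    haplotypes = [] if keep_haplotypes else None
    n_samples = cfg.samples_per_population * len(cfg.populations)
    for k, ts in enumerate(reps):
        ts = msprime.sim_mutations(
            ts, rate=cfg.mu, random_seed=int(seeds_mut[k]),
            discrete_genome=False, model=msprime.BinaryMutationModel(),
        )
        chrom = chrom_names[k // cfg.loci_per_chromosome]
        locus_idx = k % cfg.loci_per_chromosome
        locus_start = locus_idx * cfg.locus_spacing_bp + 1
        if ts.num_sites == 0:
            if haplotypes is not None:
                haplotypes.append(np.zeros((2 * n_samples, 0), dtype=np.int8))
            continue
        gm = ts.genotype_matrix()  # sites x haplotypes
        if haplotypes is not None:
            haplotypes.append(gm.T.astype(np.int8))
        dos = gm[:, 0::2] + gm[:, 1::2]  # diploid dosage, samples in order
        pos = np.floor(ts.sites_position).astype(int)
        # de-duplicate integer positions within the locus
        seen = set()
        for s in range(ts.num_sites):
            p = int(pos[s])
            while p in seen:
                p += 1
            if p >= cfg.locus_length_bp:
                continue
            seen.add(p)
            rows.append((chrom, locus_start + p))
            dosage_cols.append(dos[s])
    variants = pd.DataFrame(rows, columns=["chrom", "pos"])
    dosages = np.array(dosage_cols, dtype=float).T
    assert dosages.shape[0] == n_samples
    return variants, dosages, haplotypes


def _sample_table(cfg: StudyConfig) -> pd.DataFrame:
    rows = []
    # plausible coordinates: mainland ~43.7N/3.8E, island ~42.5N/8.9E
    base = {"mainland": (43.7, 3.8, 200.0), "island": (42.5, 8.9, 300.0)}
    # fixed, mutually decorrelated per-population offsets
    jitter = [(0.11, -0.07, 35), (-0.04, 0.21, -60), (0.18, 0.02, 110),
              (-0.13, -0.16, 15), (0.02, 0.09, -25), (0.07, -0.22, 80),
              (-0.19, 0.13, -45), (0.15, 0.18, 5), (-0.08, -0.03, 130),
              (0.05, 0.25, -90)]
    for pi, pop in enumerate(cfg.populations):
        reg = region_of(pop)
        lat0, lon0, alt0 = base[reg]
        dlat, dlon, dalt = jitter[pi % len(jitter)]
        for s in range(cfg.samples_per_population):
            rows.append(
                {
                    "sample_id": f"{pop}_{s:03d}",
                    "population": pop,
                    "region": reg,
                    "habitat": habitat_of(pop),
                    "latitude": round(lat0 + dlat, 4),
                    "longitude": round(lon0 + dlon, 4),
                    "altitude": alt0 + dalt,
                }
            )
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


# ---------------------------------------------------------------------------
# Plants
# ---------------------------------------------------------------------------

def _plant_outliers(
    variants: pd.DataFrame,
    dosages: np.ndarray,
    samples: pd.DataFrame,
    cfg: StudyConfig,
    rng: np.random.Generator,
    forbidden: np.ndarray,
) -> list:
    """Shift `n_outlier_loci` whole RAD loci between habitats.

    Every intermediate-frequency SNP of a chosen locus gets a between-
    habitat allele-frequency shift of `outlier_delta` (deciduous up,
    evergreen down) — a RAD tag under divergent selection carries the shift
    at all its SNPs, which is what window-based scans are built to see.
    """
    p_all = np.nanmean(dosages, axis=0) / 2.0
    eligible = ~forbidden & (p_all > 0.25) & (p_all < 0.75)
    locus_of = (
        variants["chrom"].astype(str)
        + ":"
        + ((variants["pos"] - 1) // cfg.locus_spacing_bp).astype(str)
    ).to_numpy()
    candidates = sorted(
        {
            lid
            for lid in locus_of[eligible]
            if (eligible & (locus_of == lid)).sum() >= 2
        }
    )
    if len(candidates) < cfg.n_outlier_loci:
        raise ValueError("not enough eligible loci for outlier plants")
    chosen = rng.choice(len(candidates), size=cfg.n_outlier_loci, replace=False)
    decid = (samples["habitat"] == "deciduous").to_numpy()
    truth = []
    for ci in sorted(chosen):
        lid = candidates[ci]
        for j in np.flatnonzero(eligible & (locus_of == lid)):
            p = p_all[j]
            p_d = np.clip(p + cfg.outlier_delta / 2, 0.0, 1.0)
            p_e = np.clip(p - cfg.outlier_delta / 2, 0.0, 1.0)
            draw_p = np.where(decid, p_d, p_e)
            dosages[:, j] = rng.binomial(2, draw_p).astype(float)
            truth.append(
                {
                    "chrom": str(variants.iloc[j]["chrom"]),
                    "pos": int(variants.iloc[j]["pos"]),
                    "delta": cfg.outlier_delta,
                }
            )
    return truth


def _simulate_arrangement_pools(cfg: StudyConfig, rng: np.random.Generator):
    """Two deeply split haplotype pools for the inversion region.

    The split time is chosen so the expected net divergence between
    arrangements equals `inversion_da_target` at the study mutation rate
    (Da ~ 2 mu T when ancestral and derived sizes match).
    Returns (positions within region, pool0 haplotypes, pool1 haplotypes).
    """
    t_split = cfg.inversion_da_target / (2.0 * cfg.mu)
    dem = msprime.Demography()
    dem.add_population(name="std", initial_size=cfg.inversion_ne)
    dem.add_population(name="inv", initial_size=cfg.inversion_ne)
    dem.add_population(name="anc", initial_size=cfg.inversion_ne)
    dem.add_population_split(time=t_split, derived=["std", "inv"], ancestral="anc")
    span = cfg.inversion_end - cfg.inversion_start + 1
    locus_starts = np.arange(
        cfg.inversion_start - 1, cfg.inversion_end - cfg.locus_length_bp,
        cfg.locus_spacing_bp,
    )
    n_loci = len(locus_starts)
    n_hap = cfg.inversion_pool_size
    seed_anc = int(rng.integers(1, 2**31 - 1))
    seeds_mut = rng.integers(1, 2**31 - 1, size=n_loci)
    reps = msprime.sim_ancestry(
        samples={"std": n_hap // 2, "inv": n_hap // 2},
        demography=dem,
        sequence_length=cfg.locus_length_bp,
        recombination_rate=0.0,
        ploidy=2,
        num_replicates=n_loci,
        random_seed=seed_anc,
    )
    positions, std_cols, inv_cols = [], [], []
    for k, ts in enumerate(reps):
        ts = msprime.sim_mutations(
            ts, rate=cfg.mu, random_seed=int(seeds_mut[k]),
            discrete_genome=False, model=msprime.BinaryMutationModel(),
        )
        if ts.num_sites == 0:
            continue
        gm = ts.genotype_matrix()  # sites x (2*n_hap) haploid genomes
        pos = np.floor(ts.sites_position).astype(int)
        seen = set()
        for s in range(ts.num_sites):
            p = int(pos[s])
            while p in seen:
                p += 1
            if p >= cfg.locus_length_bp:
                continue
            seen.add(p)
            positions.append(int(locus_starts[k]) + 1 + p)
            std_cols.append(gm[s, : n_hap])
            inv_cols.append(gm[s, n_hap :])
    order = np.argsort(positions)
    positions = np.array(positions)[order]
    std_pool = np.array(std_cols).T[:, order]   # haplotypes x sites
    inv_pool = np.array(inv_cols).T[:, order]
    return positions, std_pool, inv_pool, t_split, n_loci * cfg.locus_length_bp


def _plant_inversion(
    variants: pd.DataFrame,
    dosages: np.ndarray,
    samples: pd.DataFrame,
    cfg: StudyConfig,
    rng: np.random.Generator,
):
    """Replace the inversion region with arrangement-pool genotypes.

    Each chromosome copy of each sample draws an arrangement (Bernoulli at
    the population's planted frequency, i.e. Hardy-Weinberg karyotypes) and
    then one whole-region haplotype from that arrangement's pool: zero
    recombination within the region, maximal arrangement LD.
    """
    positions, std_pool, inv_pool, t_split, surveyed = _simulate_arrangement_pools(
        cfg, rng
    )
    region_mask = (
        (variants["chrom"] == cfg.inversion_chrom)
        & (variants["pos"] >= cfg.inversion_start)
        & (variants["pos"] <= cfg.inversion_end)
    ).to_numpy()
    keep = ~region_mask
    variants_out = variants.loc[keep].reset_index(drop=True)
    dosages_out = dosages[:, keep]

    n = len(samples)
    freqs = np.array(
        [
            cfg.inversion_freq_mainland
            if samples.iloc[i]["region"] == "mainland"
            else cfg.inversion_freq_island
            for i in range(n)
        ]
    )
    copies = rng.random((n, 2)) < freqs[:, None]   # True = inverted copy
    hap_idx = rng.integers(0, std_pool.shape[0], size=(n, 2))
    geno = np.zeros((n, len(positions)))
    for i in range(n):
        for c in range(2):
            pool = inv_pool if copies[i, c] else std_pool
            geno[i] += pool[hap_idx[i, c]]
    karyo = {}
    for i in range(n):
        k = int(copies[i].sum())
        karyo[samples.iloc[i]["sample_id"]] = ("STD/STD", "INV/STD", "INV/INV")[k]

    inv_variants = pd.DataFrame({"chrom": cfg.inversion_chrom, "pos": positions})
    variants_all = pd.concat([variants_out, inv_variants], ignore_index=True)
    dosages_all = np.concatenate([dosages_out, geno], axis=1)
    order = np.lexsort((variants_all["pos"], variants_all["chrom"]))
    variants_all = variants_all.iloc[order].reset_index(drop=True)
    dosages_all = dosages_all[:, order]
    frequencies = {
        p: (
            cfg.inversion_freq_mainland
            if region_of(p) == "mainland"
            else cfg.inversion_freq_island
        )
        for p in cfg.populations
    }
    return variants_all, dosages_all, karyo, frequencies, t_split, surveyed


# ---------------------------------------------------------------------------
# Top level
# ---------------------------------------------------------------------------

def generate_study(
    cfg: StudyConfig | None = None, seed: int = 0, keep_haplotypes: bool = False
):
    """Generate the synthetic study in memory: genotype matrix plus truth.

    With keep_haplotypes=True a third value is returned: the neutral
    background as per-locus haplotype matrices (pre-plant), for ABC analyses
    that need phased loci (the real study used a separate haplotype VCF for
    the same purpose).  Use :func:`pair_dataset` to carve out a
    two-population dataset from it.
    """
    cfg = cfg or StudyConfig()
    rng = np.random.default_rng(seed)
    samples = _sample_table(cfg)
    variants, dosages, haplotypes = _simulate_background(cfg, rng, keep_haplotypes)

    if cfg.inversion:
        span_ok = (
            cfg.inversion_chrom in {f"chr{i+1}" for i in range(cfg.n_chromosomes)}
            and cfg.inversion_end
            <= cfg.loci_per_chromosome * cfg.locus_spacing_bp
        )
        if not span_ok:
            raise ValueError("inversion region outside the simulated chromosomes")
        (
            variants, dosages, karyo, inv_freqs, t_split, surveyed
        ) = _plant_inversion(variants, dosages, samples, cfg, rng)
    else:
        karyo, inv_freqs, t_split, surveyed = {}, {}, 0.0, 0

    forbidden = (
        (
            (variants["chrom"] == cfg.inversion_chrom)
            & (variants["pos"] >= cfg.inversion_start)
            & (variants["pos"] <= cfg.inversion_end)
        ).to_numpy()
        if cfg.inversion
        else np.zeros(len(variants), bool)
    )
    outliers = (
        _plant_outliers(variants, dosages, samples, cfg, rng, forbidden)
        if cfg.n_outlier_loci > 0
        else []
    )

    # missingness and read depth
    if cfg.missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.missing_rate
        dosages = np.where(miss, np.nan, dosages)
    depth = rng.gamma(shape=25.0, scale=2.0, size=len(variants))
    variants = variants.assign(
        ref="A", alt="T", mean_depth=np.round(np.clip(depth, 11, 99), 1)
    )
    g = GenotypeMatrix(dosages, variants, samples)
    g.check_sorted()
    cfg_dict = asdict(cfg)
    cfg_dict["populations"] = list(cfg_dict["populations"])
    truth = StudyTruth(
        seed=seed,
        config=cfg_dict,
        outlier_snps=outliers,
        inversion_region=(
            [cfg.inversion_chrom, cfg.inversion_start, cfg.inversion_end]
            if cfg.inversion
            else []
        ),
        inversion_t_split=float(t_split),
        inversion_frequencies=inv_freqs,
        karyotypes=karyo,
        surveyed_bp_inversion=int(surveyed),
    )
    if keep_haplotypes:
        return g, truth, haplotypes
    return g, truth


def pair_dataset(
    haplotypes: list,
    samples: pd.DataFrame,
    cfg: StudyConfig,
    pop1,
    pop2,
    max_diploids: int | None = None,
    loci_subset=None,
):
    """Carve a two-population HaplotypeDataset out of a study's background
    haplotype record.  `pop1`/`pop2` may be population codes or regions
    ('mainland'/'island'); `max_diploids` subsamples each side (first
    individuals, deterministic)."""
    from .demography import HaplotypeDataset, Locus

    def hap_idx(sel):
        d = np.flatnonzero(sel)
        if max_diploids is not None:
            d = d[:max_diploids]
        return np.sort(np.concatenate([2 * d, 2 * d + 1]))

    def side(label):
        if label in ("mainland", "island"):
            return (samples["region"] == label).to_numpy()
        return (samples["population"] == label).to_numpy()

    i1, i2 = hap_idx(side(pop1)), hap_idx(side(pop2))
    pops = np.concatenate([np.zeros(len(i1), np.int8), np.ones(len(i2), np.int8)])
    take = np.concatenate([i1, i2])
    loci = []
    use = loci_subset if loci_subset is not None else range(len(haplotypes))
    for k in use:
        h = haplotypes[k][take]
        # drop sites not segregating in the carved sample
        freq = h.mean(axis=0)
        seg = (freq > 0) & (freq < 1)
        h = h[:, seg]
        loci.append(Locus(np.arange(h.shape[1], dtype=float), h, pops))
    return HaplotypeDataset(loci, cfg.locus_length_bp)


def make_study(out_dir, cfg: StudyConfig | None = None, seed: int = 0):
    """Generate a study and write VCF + metadata TSV + truth JSON files.

    Returns (vcf_path, metadata_path, truth_path, truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    g, truth = generate_study(cfg, seed)
    vcf_path = out_dir / "study.vcf"
    meta_path = out_dir / "samples.tsv"
    truth_path = out_dir / "truth.json"
    write_vcf(g, vcf_path)
    write_metadata(g.samples, meta_path)
    write_truth(truth, truth_path)
    return vcf_path, meta_path, truth_path, truth


PRESETS = {
    "full-study": lambda: StudyConfig(),
    "pair": lambda: StudyConfig(
        populations=("B6D", "B6E"),
        n_chromosomes=2,
        loci_per_chromosome=150,
        inversion=False,
        n_outlier_loci=3,
    ),
    "island-mainland": lambda: StudyConfig(
        populations=("A1D", "B4D"),
        n_chromosomes=2,
        loci_per_chromosome=150,
        inversion=False,
        n_outlier_loci=0,
    ),
    "inversion": lambda: StudyConfig(
        populations=("A1D", "A2D", "A2E"),
        samples_per_population=38,
        n_chromosomes=3,
        loci_per_chromosome=250,
        n_outlier_loci=0,
        inversion=True,
    ),
}
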