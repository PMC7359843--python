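"""Two-population divergence models and coalescent simulation of RAD-like loci.

Six base scenarios are supported: panmixia (PAN), the two-deme equilibrium
island model (EQ), strict isolation (SI), isolation with continuous
migration (IM), ancient migration (AM: gene flow from the split until T_am,
then isolation), and secondary contact (SC: isolation after the split, gene
flow since T_sc).  Each scenario with gene flow has four variants crossing
genomic heterogeneity in effective size (Nhetero) and in migration rate
(Mhetero), modelled as independent per-locus Beta-distributed scaling
factors rescaled to mean one; PAN and SI have the two N variants only,
giving 20 model variants in total.

Migration is parameterised as M = 4*N0*m, where M12 scales migrants into
population 1 from population 2 (m12 the per-generation fraction of
population 1 made of such migrants).  Loci are short (RAD-like, default
85 bp), free of intra-locus recombination, independent, and mutated under
infinite sites at rate mu per bp per generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import msprime
import numpy as np

BASES = ("PAN", "EQ", "SI", "IM", "AM", "SC")
MIGRATION_BASES = ("EQ", "IM", "AM", "SC")

SUMMARY_STAT_NAMES = (
    "pi1_mean", "pi1_sd", "pi2_mean", "pi2_sd",
    "theta1_mean", "theta1_sd", "theta2_mean", "theta2_sd",
    "dxy_mean", "dxy_sd", "da_mean", "da_sd",
    "fst_mean", "fst_sd",
    "sx1_mean", "sx1_sd", "sx2_mean", "sx2_sd",
    "ss_mean", "ss_sd", "sf_mean", "sf_sd",
    "cor_pi1_pi2",
)


@dataclass(frozen=True)
class DemographicModel:
    base: str
    n_hetero: bool = False
    m_hetero: bool = False

    def __post_init__(self):
        if self.base not in BASES:
            raise ValueError(f"unknown base model {self.base!r}")
        if self.m_hetero and self.base not in MIGRATION_BASES:
            raise ValueError(f"{self.base} has no migration to make heterogeneous")

    @property
    def name(self) -> str:
        tags = []
        tags.append("Nhetero" if self.n_hetero else "Nhomo")
        if self.base in MIGRATION_BASES:
            tags.append("Mhetero" if self.m_hetero else "Mhomo")
        return f"{self.base}_{''.join(tags)}"


def enumerate_models() -> list[DemographicModel]:
    """All 20 scenario variants: 4 per migration model, 2 for PAN and SI."""
    models = []
    for base in BASES:
        for nh in (False, True):
            if base in MIGRATION_BASES:
                for mh in (False, True):
                    models.append(DemographicModel(base, nh, mh))
            else:
                models.append(DemographicModel(base, nh))
    return models


@dataclass
class DemographicParams:
    """Parameter vector for one divergence scenario.

    Sizes are diploid effective sizes; times are generations before present;
    M12/M21 are 4*N0*m scaled migration rates; (a_N, b_N) and (a_M, b_M) are
    Beta hyper-parameters for per-locus heterogeneity.
    """

    N_anc: float = 1e4
    N_pop1: float = 1e4
    N_pop2: float = 1e4
    T_split: float = 1e4
    T_am: float = 0.0
    T_sc: float = 0.0
    M12: float = 0.0
    M21: float = 0.0
    a_N: float = 1.0
    b_N: float = 1.0
    a_M: float = 1.0
    b_M: float = 1.0
    mu: float = 1e-8
    locus_length: int = 85
    generation_time: float = 2.3

    def validate(self, model: DemographicModel) -> None:
        for nm in ("N_anc", "N_pop1", "N_pop2"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        if model.base == "AM" and not (0 < self.T_am < self.T_split):
            raise ValueError("AM requires 0 < T_am < T_split")
        if model.base == "SC" and not (0 < self.T_sc < self.T_split):
            raise ValueError("SC requires 0 < T_sc < T_split")
        if self.M12 < 0 or self.M21 < 0:
            raise ValueError("scaled migration must be non-negative")
        if model.base == "EQ" and self.M12 + self.M21 <= 0:
            raise ValueError("EQ needs positive migration for lineages to coalesce")
        for nm in ("a_N", "b_N", "a_M", "b_M"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")


DEFAULT_PRIORS = {
    "N_anc": ("loguniform", 1e2, 1e6),
    "N_pop1": ("loguniform", 1e2, 1e6),
    "N_pop2": ("loguniform", 1e2, 1e6),
    "T_split": ("loguniform", 1e3, 3e6),
    "T_am_frac": ("uniform", 0.0, 1.0),
    "T_sc_frac": ("uniform", 0.0, 1.0),
    "M12": ("uniform", 0.0, 40.0),
    "M21": ("uniform", 0.0, 40.0),
    "a_N": ("loguniform", 0.1, 10.0),
    "b_N": ("loguniform", 0.1, 10.0),
    "a_M": ("loguniform", 0.1, 10.0),
    "b_M": ("loguniform", 0.1, 10.0),
}

WIDE_MIGRATION_PRIORS = dict(
    DEFAULT_PRIORS, M12=("uniform", 0.0, 200.0), M21=("uniform", 0.0, 200.0)
)


def _draw(spec, rng: np.random.Generator) -> float:
    kind, lo, hi = spec
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValueError(f"invalid prior bounds {spec}")
    if kind == "uniform":
        return float(rng.uniform(lo, hi))
    if kind == "loguniform":
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    raise ValueError(f"unknown prior kind {kind!r}")


def sample_priors(
    model: DemographicModel, priors: dict | None = None, rng=None
) -> DemographicParams:
    """Draw one parameter vector from the priors, respecting model
    constraints (no split under EQ/PAN, no migration under PAN/SI, ordered
    epoch times under AM/SC)."""
    rng = np.random.default_rng(rng)
    pr = dict(DEFAULT_PRIORS, **(priors or {}))
    p = DemographicParams(
        N_anc=_draw(pr["N_anc"], rng),
        N_pop1=_draw(pr["N_pop1"], rng),
        N_pop2=_draw(pr["N_pop2"], rng),
    )
    if model.base == "PAN":
        p.N_pop2 = p.N_pop1
        p.T_split = 0.0
    elif model.base == "EQ":
        p.T_split = 0.0
    else:
        p.T_split = _draw(pr["T_split"], rng)
    if model.base in MIGRATION_BASES:
        p.M12 = _draw(pr["M12"], rng)
        p.M21 = _draw(pr["M21"], rng)
    if model.base == "AM":
        p.T_am = p.T_split * np.clip(_draw(pr["T_am_frac"], rng), 1e-6, 1 - 1e-6)
    if model.base == "SC":
        p.T_sc = p.T_split * np.clip(_draw(pr["T_sc_frac"], rng), 1e-6, 1 - 1e-6)
    if model.n_hetero:
        p.a_N = _draw(pr["a_N"], rng)
        p.b_N = _draw(pr["b_N"], rng)
    if model.m_hetero:
        p.a_M = _draw(pr["a_M"], rng)
        p.b_M = _draw(pr["b_M"], rng)
    return p


@dataclass
class Locus:
    """One independent locus: site positions (bp, within [0, L)) and a 0/1
    haplotype matrix (n_haplotypes x n_sites) with per-haplotype population
    labels (0 or 1)."""

    positions: np.ndarray
    haplotypes: np.ndarray
    pops: np.ndarray


@dataclass
class HaplotypeDataset:
    loci: list
    locus_length: int


def _build_demography(
    model: DemographicModel, p: DemographicParams, ne_scale: float = 1.0, m_scale: float = 1.0
) -> msprime.Demography:
    dem = msprime.Demography()
    if model.base == "PAN":
        dem.add_population(name="pop1", initial_size=p.N_pop1 * ne_scale)
        return dem
    dem.add_population(name="pop1", initial_size=p.N_pop1 * ne_scale)
    dem.add_population(name="pop2", initial_size=p.N_pop2 * ne_scale)
    m12 = m_scale * p.M12 / (4.0 * p.N_pop1)
    m21 = m_scale * p.M21 / (4.0 * p.N_pop2)
    if model.base != "EQ":
        dem.add_population(name="anc", initial_size=p.N_anc * ne_scale)
        dem.add_population_split(time=p.T_split, derived=["pop1", "pop2"], ancestral="anc")
    if model.base == "EQ":
        dem.set_migration_rate("pop1", "pop2", m12)
        dem.set_migration_rate("pop2", "pop1", m21)
    elif model.base == "IM":
        dem.set_migration_rate("pop1", "pop2", m12)
        dem.set_migration_rate("pop2", "pop1", m21)
    elif model.base == "AM":
        dem.add_migration_rate_change(time=p.T_am, rate=m12, source="pop1", dest="pop2")
        dem.add_migration_rate_change(time=p.T_am, rate=m21, source="pop2", dest="pop1")
    elif model.base == "SC":
        dem.set_migration_rate("pop1", "pop2", m12)
        dem.set_migration_rate("pop2", "pop1", m21)
        dem.add_migration_rate_change(time=p.T_sc, rate=0.0, source="pop1", dest="pop2")
        dem.add_migration_rate_change(time=p.T_sc, rate=0.0, source="pop2", dest="pop1")
    dem.sort_events()
    return dem


def _ts_to_locus(ts, n1: int, model_is_pan: bool) -> Locus:
    gm = ts.genotype_matrix().T.astype(np.int8)  # haplotypes x sites
    pos = ts.sites_position.copy()
    n_hap = gm.shape[0]
    pops = np.zeros(n_hap, dtype=np.int8)
    pops[2 * n1:] = 1
    return Locus(pos, gm, pops)


def simulate_dataset(
    model: DemographicModel,
    params: DemographicParams,
    n_loci: int = 1000,
    sample_config: tuple[int, int] = (20, 20),
    rng=None,
) -> HaplotypeDataset:
    """Simulate independent RAD-like loci under the structured coalescent.

    sample_config gives diploids per population; under PAN both labelled
    populations are drawn from the single deme.  Heterogeneous variants
    multiply per-locus Ne (resp. m) by an independent Beta(a, b) draw divided
    by its mean a/(a+b), so the genome-wide average stays at the nominal
    parameter; near-zero migration draws emulate barrier loci.
    """
    params.validate(model)
    rng = np.random.default_rng(rng)
    n1, n2 = sample_config
    if model.base == "PAN":
        samples = {"pop1": n1 + n2}
    else:
        samples = {"pop1": n1, "pop2": n2}
    L = params.locus_length
    loci: list[Locus] = []

    def run_one(ne_scale, m_scale, seed_pair):
        dem = _build_demography(model, params, ne_scale, m_scale)
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=dem,
            sequence_length=L,
            recombination_rate=0.0,
            ploidy=2,
            random_seed=seed_pair[0],
        )
        ts = msprime.sim_mutations(
            ts, rate=params.mu, random_seed=seed_pair[1], discrete_genome=False,
            model=msprime.BinaryMutationModel(),
        )
        return _ts_to_locus(ts, n1, model.base == "PAN")

    hetero = model.n_hetero or model.m_hetero
    seeds = rng.integers(1, 2**31 - 1, size=(n_loci, 2))
    if not hetero:
        # one msprime replicate stream for speed
        dem = _build_demography(model, params)
        reps = msprime.sim_ancestry(
            samples=samples,
            demography=dem,
            sequence_length=L,
            recombination_rate=0.0,
            ploidy=2,
            num_replicates=n_loci,
            random_seed=int(seeds[0, 0]),
        )
        for k, ts in enumerate(reps):
            ts = msprime.sim_mutations(
                ts, rate=params.mu, random_seed=int(seeds[k, 1]),
                discrete_genome=False, model=msprime.BinaryMutationModel(),
            )
            loci.append(_ts_to_locus(ts, n1, model.base == "PAN"))
    else:
        for k in range(n_loci):
            ne_scale = 1.0
            m_scale = 1.0
            if model.n_hetero:
                mean_n = params.a_N / (params.a_N + params.b_N)
                ne_scale = max(rng.beta(params.a_N, params.b_N) / mean_n, 1e-3)
            if model.m_hetero:
                mean_m = params.a_M / (params.a_M + params.b_M)
                m_scale = rng.beta(params.a_M, params.b_M) / mean_m
            loci.append(run_one(ne_scale, m_scale, seeds[k]))
    return HaplotypeDataset(loci, L)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def _locus_stats(locus: Locus, L: int) -> np.ndarray:
    """Per-locus statistics: pi1, pi2, theta1, theta2, dxy, da, fst,
    sx1, sx2, ss, sf."""
    h = locus.haplotypes
    in1 = locus.pops == 0
    in2 = locus.pops == 1
    n1, n2 = int(in1.sum()), int(in2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("summaries need at least two haplotypes per population")
    if h.shape[1] == 0:
        return np.zeros(11)
    p1 = h[in1].mean(axis=0)
    p2 = h[in2].mean(axis=0)
    pi1 = float(np.sum(2 * p1 * (1 - p1)) * n1 / (n1 - 1)) / L
    pi2 = float(np.sum(2 * p2 * (1 - p2)) * n2 / (n2 - 1)) / L
    a1 = np.sum(1.0 / np.arange(1, n1))
    a2 = np.sum(1.0 / np.arange(1, n2))
    seg1 = int(np.sum((p1 > 0) & (p1 < 1)))
    seg2 = int(np.sum((p2 > 0) & (p2 < 1)))
    theta1 = seg1 / a1 / L
    theta2 = seg2 / a2 / L
    dxy = float(np.sum(p1 * (1 - p2) + p2 * (1 - p1))) / L
    da = dxy - (pi1 + pi2) / 2.0
    n = n1 + n2
    pt = h.mean(axis=0)
    pi_tot = float(np.sum(2 * pt * (1 - pt)) * n / (n - 1)) / L
    fst = 1.0 - ((pi1 + pi2) / 2.0) / pi_tot if pi_tot > 0 else 0.0
    poly1 = (p1 > 0) & (p1 < 1)
    poly2 = (p2 > 0) & (p2 < 1)
    sx1 = int(np.sum(poly1 & ~poly2))
    sx2 = int(np.sum(poly2 & ~poly1))
    ss = int(np.sum(poly1 & poly2))
    sf = int(np.sum(~poly1 & ~poly2 & (p1 != p2)))
    return np.array([pi1, pi2, theta1, theta2, dxy, da, fst, sx1, sx2, ss, sf])


def summarize(dataset: HaplotypeDataset) -> np.ndarray:
    """ABC summary-statistic vector: mean and SD across loci of pi, Watterson
    theta, dxy, net divergence Da, per-locus FST and the Wakeley-Hey site
    classes (sx1, sx2, ss, sf), plus the across-locus Pearson correlation of
    pi1 with pi2.  Order follows SUMMARY_STAT_NAMES."""
    if not dataset.loci:
        raise ValueError("empty dataset")
    per = np.array([_locus_stats(lc, dataset.locus_length) for lc in dataset.loci])
    means = per.mean(axis=0)
    sds = per.std(axis=0)
    # interleave as (pi1_mean, pi1_sd, pi2_mean, ...), matching names
    order = [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
    vec = []
    for k in order:
        vec.extend([means[k], sds[k]])
    s1, s2 = per[:, 0], per[:, 1]
    if s1.std() > 0 and s2.std() > 0:
        cor = float(np.corrcoef(s1, s2)[0, 1])
    else:
        cor = 0.0
    vec.append(cor)
    return np.array(vec)


def simulate_summary_table(
    models: list[DemographicModel],
    n_sims_per_model: int,
    n_loci: int = 1000,
    sample_config: tuple[int, int] = (20, 20),
    priors: dict | None = None,
    rng=None,
    fixed_params: dict | None = None,
):
    """Build a simulation reference table: one row per simulated dataset with
    model name, the drawn parameters and the summary-stat vector.

    Returns (model_names list, params list of dicts, stats array).
    """
    import pandas as pd

    rng = np.random.default_rng(rng)
    names, param_rows, stats = [], [], []
    for model in models:
        for _ in range(n_sims_per_model):
            p = sample_priors(model, priors, rng)
            for k, v in (fixed_params or {}).items():
                setattr(p, k, v)
            ds = simulate_dataset(model, p, n_loci, sample_config, rng)
            names.append(model.name)
            param_rows.append(asdict(p))
            stats.append(summarize(ds))
    stats = np.array(stats)
    table = pd.DataFrame(param_rows)
    table.insert(0, "model", names)
    for i, nm in enumerate(SUMMARY_STAT_NAMES):
        table[nm] = stats[:, i]
    return table
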