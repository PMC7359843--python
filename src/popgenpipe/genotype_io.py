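"""Genotype input/output and the post-genotyping filter chain.

The central container is :class:`GenotypeMatrix`: a samples x variants diploid
dosage matrix (ALT-allele counts, NaN for missing calls) with variant and
sample metadata tables attached.  VCF parsing goes through cyvcf2; writing
emits plain VCF v4.2 text.  Population codes follow the study convention:
a leading "A" marks mainland, "B" the island, and a trailing "D"/"E" marks
deciduous versus evergreen forest habitat.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING = np.nan

METADATA_COLUMNS = [
    "sample_id",
    "population",
    "region",
    "habitat",
    "latitude",
    "longitude",
    "altitude",
]


def region_of(population: str) -> str:
    """Region implied by a population code ('A...' mainland, 'B...' island)."""
    if population.startswith("A"):
        return "mainland"
    if population.startswith("B"):
        return "island"
    raise ValueError(f"population code {population!r} has no A/B region prefix")


def habitat_of(population: str) -> str:
    """Habitat implied by a population code (trailing 'D' or 'E')."""
    if population.endswith("D"):
        return "deciduous"
    if population.endswith("E"):
        return "evergreen"
    raise ValueError(f"population code {population!r} has no D/E habitat suffix")


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with variant and sample metadata.

    dosages : float array (n_samples, n_variants), entries in {0, 1, 2, NaN}
    variants : DataFrame with columns chrom, pos (1-based), ref, alt, mean_depth
    samples : DataFrame with METADATA_COLUMNS
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[:, idx], self.variants.iloc[idx], self.samples
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[idx, :], self.variants, self.samples.iloc[idx]
        )

    def population_indices(self) -> dict:
        """Map population code -> integer sample indices."""
        out = {}
        for pop, grp in self.samples.groupby("population", sort=True):
            out[pop] = grp.index.to_numpy()
        return out

    def check_sorted(self) -> None:
        v = self.variants
        for _, grp in v.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("variant positions not strictly increasing within chromosome")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    return meta[METADATA_COLUMNS]


def read_vcf(path, metadata_path) -> GenotypeMatrix:
    """Read a diploid biallelic VCF plus a sample-metadata TSV.

    Dosage is the ALT-allele count of the GT field; ./. maps to NaN.
    Non-biallelic records are skipped with a warning.  Every VCF sample must
    appear in the metadata (hard error otherwise); metadata rows for samples
    absent from the VCF are ignored.
    """
    meta = read_metadata(metadata_path)
    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    known = set(meta["sample_id"])
    unknown = [s for s in vcf_samples if s not in known]
    if unknown:
        raise ValueError(f"VCF samples absent from metadata: {unknown[:5]}")

    n = len(vcf_samples)
    chroms, poss, refs, alts, depths = [], [], [], [], []
    cols = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        cols.append(dos)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        dp = rec.INFO.get("DP")
        depths.append(float(dp) / n if dp is not None else np.nan)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic records")

    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "mean_depth": depths}
    )
    dosages = (
        np.array(cols).T if cols else np.zeros((n, 0))
    )
    meta_indexed = meta.set_index("sample_id").loc[vcf_samples].reset_index()
    return GenotypeMatrix(dosages, variants, meta_indexed)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write the matrix as uncompressed VCF v4.2 (unphased GT + INFO DP)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, grp in g.variants.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples["sample_id"])
            + "\n"
        )
        code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        n = g.n_samples
        for j in range(g.n_variants):
            v = g.variants.iloc[j]
            md = v["mean_depth"]
            dp = int(round(md * n)) if np.isfinite(md) else 50 * n
            gts = [
                code.get(g.dosages[i, j], "./.") for i in range(n)
            ]
            fh.write(
                f"{v['chrom']}\t{int(v['pos'])}\t.\t{v['ref']}\t{v['alt']}\t.\tPASS\t"
                f"DP={dp}\tGT\t" + "\t".join(gts) + "\n"
            )


def write_metadata(samples: pd.DataFrame, path) -> None:
    samples[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filter chain
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Thresholds of the post-genotyping filter chain, in application order."""

    min_mean_depth: float | None = 10.0
    max_mean_depth: float | None = 100.0
    min_variant_call_rate: float | None = 0.80
    max_region_het: float | None = 0.65
    min_sample_call_rate: float | None = 0.85
    max_relatedness: float | None = 0.35
    max_per_population: int | None = 60
    drop_monomorphic: bool = True

    @classmethod
    def disabled(cls) -> "FilterConfig":
        return cls(None, None, None, None, None, None, None, False)


@dataclass
class FilterReport:
    """Per-rule removal counts, in the order the rules ran."""

    steps: list = field(default_factory=list)  # (rule, kind, n_removed)

    def add(self, rule: str, kind: str, n_removed: int) -> None:
        if n_removed:
            self.steps.append({"rule": rule, "kind": kind, "removed": int(n_removed)})

    def removed(self, kind: str) -> int:
        return sum(s["removed"] for s in self.steps if s["kind"] == kind)

    def to_json(self, path=None) -> str:
        text = json.dumps({"steps": self.steps}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class AllFilteredError(RuntimeError):
    pass


def _check_nonempty(g: GenotypeMatrix, step: str) -> None:
    if g.n_variants == 0 or g.n_samples == 0:
        raise AllFilteredError(f"no data left after filter step: {step}")


def apply_filters(
    g: GenotypeMatrix, cfg: FilterConfig | None = None, seed: int = 0
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the filter chain and return the filtered matrix plus a report.

    Order: mean-depth window, variant call rate, per-region heterozygosity
    excess, sample call rate, relatedness pruning, per-population cap
    (random, seeded), monomorphic removal.  The chain is repeated until no
    further removals occur (sample removal can push variants below the
    call-rate or polymorphism thresholds), so filtering is idempotent.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport()
    for _ in range(10):
        shape = (g.n_samples, g.n_variants)
        g, report = _apply_filters_once(g, cfg, seed, report)
        if (g.n_samples, g.n_variants) == shape:
            break
    return g, report


def _apply_filters_once(
    g: GenotypeMatrix, cfg: FilterConfig, seed: int, report: FilterReport
) -> tuple[GenotypeMatrix, FilterReport]:
    rng = np.random.default_rng(seed)

    if cfg.min_mean_depth is not None or cfg.max_mean_depth is not None:
        d = g.variants["mean_depth"].to_numpy()
        keep = np.ones(g.n_variants, bool)
        if cfg.min_mean_depth is not None:
            keep &= ~(d < cfg.min_mean_depth)
        if cfg.max_mean_depth is not None:
            keep &= ~(d > cfg.max_mean_depth)
        report.add("mean_depth", "variants", (~keep).sum())
        g = g.take_variants(np.flatnonzero(keep))
        _check_nonempty(g, "mean_depth")

    if cfg.min_variant_call_rate is not None:
        rate = 1.0 - np.mean(np.isnan(g.dosages), axis=0)
        keep = rate >= cfg.min_variant_call_rate
        report.add("variant_call_rate", "variants", (~keep).sum())
        g = g.take_variants(np.flatnonzero(keep))
        _check_nonempty(g, "variant_call_rate")

    if cfg.max_region_het is not None:
        drop = np.zeros(g.n_variants, bool)
        for region in g.samples["region"].unique():
            sel = (g.samples["region"] == region).to_numpy()
            sub = g.dosages[sel]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ho = np.nanmean(sub == 1, axis=0)
            drop |= np.nan_to_num(ho) >= cfg.max_region_het
        report.add("region_het_excess", "variants", drop.sum())
        g = g.take_variants(np.flatnonzero(~drop))
        _check_nonempty(g, "region_het_excess")

    if cfg.min_sample_call_rate is not None:
        rate = 1.0 - np.mean(np.isnan(g.dosages), axis=1)
        keep = rate >= cfg.min_sample_call_rate
        report.add("sample_call_rate", "samples", (~keep).sum())
        g = g.take_samples(np.flatnonzero(keep))
        _check_nonempty(g, "sample_call_rate")

    if cfg.max_relatedness is not None:
        from .popgen_stats import relatedness_matrix

        grm = relatedness_matrix(g)
        n = g.n_samples
        miss = np.sum(np.isnan(g.dosages), axis=1)
        ids = g.samples["sample_id"].to_numpy()
        iu, ju = np.triu_indices(n, k=1)
        rel = grm[iu, ju]
        order = np.argsort(-rel)
        removed: set[int] = set()
        for k in order:
            if rel[k] < cfg.max_relatedness:
                break
            i, j = int(iu[k]), int(ju[k])
            if i in removed or j in removed:
                continue
            # drop the member with more missing calls; tie -> lexicographic id
            if miss[i] != miss[j]:
                removed.add(i if miss[i] > miss[j] else j)
            else:
                removed.add(i if ids[i] > ids[j] else j)
        report.add("relatedness", "samples", len(removed))
        keep = np.array([i for i in range(n) if i not in removed])
        g = g.take_samples(keep)
        _check_nonempty(g, "relatedness")

    if cfg.max_per_population is not None:
        keep_idx = []
        for pop, idx in g.population_indices().items():
            if len(idx) > cfg.max_per_population:
                chosen = rng.choice(idx, size=cfg.max_per_population, replace=False)
                keep_idx.extend(sorted(chosen))
            else:
                keep_idx.extend(idx)
        keep_idx = np.sort(np.array(keep_idx))
        report.add("population_cap", "samples", g.n_samples - len(keep_idx))
        g = g.take_samples(keep_idx)
        _check_nonempty(g, "population_cap")

    if cfg.drop_monomorphic:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(g.dosages, axis=0)
        poly = np.zeros(g.n_variants, bool)
        for j in range(g.n_variants):
            col = g.dosages[:, j]
            col = col[~np.isnan(col)]
            poly[j] = col.size > 0 and not np.all(col == col[0])
        report.add("monomorphic", "variants", (~poly).sum())
        g = g.take_variants(np.flatnonzero(poly))
        _check_nonempty(g, "monomorphic")

    return g, report


def ld_prune(g: GenotypeMatrix, window: int = 50, step: int = 5, r2_max: float = 0.5):
    """Greedy windowed LD pruning of variants (plink indep-style).

    Slides a `window`-SNP window by `step` SNPs per chromosome and drops one
    member of each pair with dosage-correlation r^2 above `r2_max`.
    Returns indices of retained variants.
    """
    keep = np.ones(g.n_variants, bool)
    chroms = g.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            win = idx[start : start + window]
            win = win[keep[win]]
            if len(win) > 1:
                sub = g.dosages[:, win]
                col_mean = np.nanmean(sub, axis=0)
                filled = np.where(np.isnan(sub), col_mean, sub)
                sd = filled.std(axis=0)
                ok = sd > 0
                if ok.sum() > 1:
                    r = np.corrcoef(filled[:, ok].T)
                    r2 = r**2
                    live = np.ones(ok.sum(), bool)
                    for a in range(len(live)):
                        if not live[a]:
                            continue
                        hits = np.flatnonzero(r2[a] > r2_max)
                        for b in hits:
                            if b > a and live[b]:
                                live[b] = False
                    keep[win[ok]] &= live
            start += step
    return np.flatnonzero(keep)
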