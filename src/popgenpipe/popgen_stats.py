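"""Diversity and differentiation statistics on diploid dosage matrices.

Implements the Weir & Cockerham (1984) variance-component FST estimator
(per SNP, genome-wide ratio-of-sums, pairwise with locus bootstrap, and
windowed), observed heterozygosity and MAF spectra, a VanRaden genomic
relationship matrix, composite LD r^2 with decay curves and an LD-based
recent-Ne estimator, runs of homozygosity, a Hardy-Weinberg chi-square
test, and the FST-versus-recombination-rate analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def wc_fst_components(dosages: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-SNP WC84 variance components for >=2 groups of diploids.

    Parameters
    ----------
    dosages : (n_samples, n_variants) float array with NaN missing.
    groups : list of integer index arrays, one per population.

    Returns
    -------
    (n_variants, 3) array of components (a, b, c); rows are NaN where fewer
    than two groups have two or more genotyped diploids.

    The ratio estimate at a SNP is a / (a + b + c); multi-SNP estimates
    should sum components first (ratio of sums).
    """
    if len(groups) < 2:
        raise ValueError("WC84 FST requires at least two groups")
    r = len(groups)
    n_var = dosages.shape[1]
    # per-group sample sizes, allele freqs, het proportions
    n_i = np.empty((r, n_var))
    p_i = np.empty((r, n_var))
    h_i = np.empty((r, n_var))
    for k, idx in enumerate(groups):
        sub = dosages[idx]
        called = ~np.isnan(sub)
        n_i[k] = called.sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p_i[k] = np.nansum(sub, axis=0) / (2.0 * n_i[k])
            h_i[k] = np.nansum(sub == 1, axis=0) / n_i[k]

    valid = (n_i >= 2).sum(axis=0) >= 2
    # restrict each SNP to groups with n>=2; for simplicity require all
    # groups informative when r==2, else mask group-wise via weights
    use = n_i >= 2
    n_i = np.where(use, n_i, 0.0)
    p_i = np.where(use, p_i, 0.0)
    h_i = np.where(use, h_i, 0.0)
    r_eff = use.sum(axis=0).astype(float)

    n_sum = n_i.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_bar = n_sum / r_eff
        n_c = (n_sum - (n_i**2).sum(axis=0) / n_sum) / (r_eff - 1.0)
        p_bar = (n_i * p_i).sum(axis=0) / n_sum
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r_eff - 1.0) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_sum

        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1 - p_bar) - ((r_eff - 1.0) / r_eff) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar)
            - ((r_eff - 1.0) / r_eff) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0

    comp = np.stack([a, b, c], axis=1)
    comp[~valid | (r_eff < 2)] = np.nan
    return comp


def wc_fst_per_snp(g: GenotypeMatrix, grouping: dict | None = None) -> pd.DataFrame:
    """Per-SNP WC84 FST. `grouping` maps group label -> sample indices
    (defaults to population labels). Returns chrom, pos, a, denom, fst."""
    if grouping is None:
        grouping = g.population_indices()
    comp = wc_fst_components(g.dosages, list(grouping.values()))
    denom = comp.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = comp[:, 0] / denom
    return pd.DataFrame(
        {
            "chrom": g.variants["chrom"],
            "pos": g.variants["pos"],
            "a": comp[:, 0],
            "denom": denom,
            "fst": fst,
        }
    )


def ratio_of_sums(a: np.ndarray, denom: np.ndarray) -> float:
    """Genome-wide WC84 FST: sum of numerators over sum of denominators."""
    ok = np.isfinite(a) & np.isfinite(denom)
    d = denom[ok].sum()
    return float(a[ok].sum() / d) if d > 0 else np.nan


@dataclass
class PairwiseFstResult:
    pop1: str
    pop2: str
    fst_all: float
    fst_autosome: float
    fst_z: float
    p_value: float
    fst_z_over_autosome: float


def pairwise_fst(
    g: GenotypeMatrix,
    n_boot: int = 1000,
    chrom_classes: dict | None = None,
    seed: int = 0,
) -> list[PairwiseFstResult]:
    """All pairwise population FSTs with a locus bootstrap p-value for
    FST > 0, split by chromosome class (autosome / Z) when a class map is
    given."""
    rng = np.random.default_rng(seed)
    pops = g.population_indices()
    names = list(pops)
    chroms = g.variants["chrom"].to_numpy()
    if chrom_classes:
        cls = np.array([chrom_classes.get(c, "autosome") for c in chroms])
    else:
        cls = np.full(len(chroms), "autosome")

    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            comp = wc_fst_components(g.dosages, [pops[names[i]], pops[names[j]]])
            a, denom = comp[:, 0], comp.sum(axis=1)
            fst_all = ratio_of_sums(a, denom)
            fst_auto = (
                ratio_of_sums(a[cls == "autosome"], denom[cls == "autosome"])
                if np.any(cls == "autosome")
                else np.nan
            )
            fst_z = (
                ratio_of_sums(a[cls == "Z"], denom[cls == "Z"])
                if np.any(cls == "Z")
                else np.nan
            )
            ok = np.isfinite(a) & np.isfinite(denom)
            av, dv = a[ok], denom[ok]
            boots = np.empty(n_boot)
            for b in range(n_boot):
                pick = rng.integers(0, len(av), len(av))
                s = dv[pick].sum()
                boots[b] = av[pick].sum() / s if s > 0 else np.nan
            p = float(np.mean(boots <= 0))
            ratio = fst_z / fst_auto if np.isfinite(fst_z) and fst_auto else np.nan
            out.append(
                PairwiseFstResult(names[i], names[j], fst_all, fst_auto, fst_z, p, ratio)
            )
    return out


def window_fst(
    per_snp: pd.DataFrame,
    mode: str = "kb",
    window_bp: int = 200_000,
    step_bp: int = 200_000,
    block_snps: int = 50,
    step_snps: int = 5,
    outlier_quantile: float = 0.99,
) -> pd.DataFrame:
    """Windowed ratio-of-sums FST from per-SNP WC components.

    mode "kb": fixed-width windows (default 200 kb); mode "snp": blocks of
    `block_snps` SNPs moving by `step_snps`.  Windows with zero informative
    SNPs are omitted.  The top (1 - outlier_quantile) fraction of windows is
    flagged as outliers.  Coordinates are reported 1-based inclusive.
    """
    rows = []
    for chrom, grp in per_snp.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError("per-SNP table not sorted by position")
        a = grp["a"].to_numpy()
        d = grp["denom"].to_numpy()
        ok = np.isfinite(a) & np.isfinite(d)
        if mode == "kb":
            last = pos.max()
            start = 1
            while start <= last:
                end = start + window_bp - 1
                sel = ok & (pos >= start) & (pos <= end)
                if sel.sum() > 0 and d[sel].sum() > 0:
                    rows.append(
                        (chrom, start, end, int(sel.sum()), a[sel].sum() / d[sel].sum())
                    )
                start += step_bp
        elif mode == "snp":
            idx = np.flatnonzero(ok)
            if len(idx) == 0:
                continue
            start_i = 0
            emitted_any = False
            while start_i < len(idx):
                block = idx[start_i : start_i + block_snps]
                if len(block) < block_snps and emitted_any:
                    break  # trailing partial block already covered
                if d[block].sum() > 0:
                    rows.append(
                        (
                            chrom,
                            int(pos[block[0]]),
                            int(pos[block[-1]]),
                            len(block),
                            a[block].sum() / d[block].sum(),
                        )
                    )
                    emitted_any = True
                start_i += step_snps
        else:
            raise ValueError(f"unknown window mode: {mode}")
    win = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "fst"])
    if len(win):
        thr = win["fst"].quantile(outlier_quantile)
        win["outlier"] = win["fst"] > thr
    else:
        win["outlier"] = pd.Series(dtype=bool)
    return win


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def observed_het(g: GenotypeMatrix, by_population: bool = True) -> pd.Series:
    """Mean fraction of heterozygous calls among non-missing genotypes."""
    groups = g.population_indices() if by_population else {"all": np.arange(g.n_samples)}
    out = {}
    for name, idx in groups.items():
        sub = g.dosages[idx]
        called = ~np.isnan(sub)
        out[name] = float(np.sum(sub == 1) / called.sum()) if called.sum() else np.nan
    return pd.Series(out, name="Ho")


def maf_spectrum(
    g: GenotypeMatrix, by_population: bool = True, bins: int = 10
) -> dict:
    """Per-group minor-allele-frequency histograms plus polymorphic counts
    (MAF > 0.05)."""
    groups = g.population_indices() if by_population else {"all": np.arange(g.n_samples)}
    edges = np.linspace(0, 0.5, bins + 1)
    out = {}
    for name, idx in groups.items():
        sub = g.dosages[idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(sub, axis=0) / 2.0
        maf = np.minimum(p, 1 - p)
        maf = maf[np.isfinite(maf)]
        hist, _ = np.histogram(maf, bins=edges)
        out[name] = {
            "bin_edges": edges,
            "counts": hist,
            "n_polymorphic_maf05": int(np.sum(maf > 0.05)),
        }
    return out


def relatedness_matrix(g: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix.

    Dosages are centered by 2p and the cross-product scaled by sum 2p(1-p);
    self-relatedness is ~1+F, unrelated pairs ~0.  Missing entries are
    mean-imputed; monomorphic SNPs are excluded.
    """
    X = g.dosages
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(X, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    Xp = X[:, poly]
    p = p[poly]
    centered = np.where(np.isnan(Xp), 0.0, Xp - 2 * p)
    denom = np.sum(2 * p * (1 - p))
    return centered @ centered.T / denom


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(g: GenotypeMatrix, max_dist_bp: int = 500_000) -> pd.DataFrame:
    """Composite (dosage-correlation) r^2 for all SNP pairs within
    `max_dist_bp` on the same chromosome.  Monomorphic members are skipped."""
    rows_d, rows_r = [], []
    chroms = g.variants["chrom"].to_numpy()
    positions = g.variants["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        sub = g.dosages[:, idx]
        col_mean = np.nanmean(sub, axis=0)
        filled = np.where(np.isnan(sub), col_mean, sub)
        sd = filled.std(axis=0)
        for a in range(len(idx)):
            if sd[a] == 0:
                continue
            hi = np.searchsorted(pos, pos[a] + max_dist_bp, side="right")
            for b in range(a + 1, hi):
                if sd[b] == 0:
                    continue
                r = np.corrcoef(filled[:, a], filled[:, b])[0, 1]
                rows_d.append(pos[b] - pos[a])
                rows_r.append(r * r)
    return pd.DataFrame({"dist": rows_d, "r2": rows_r})


def ld_decay_curve(
    pairs: pd.DataFrame, bin_bp: int = 10_000, smooth: int = 0
) -> pd.DataFrame:
    """Mean r^2 per distance bin, optionally smoothed by a moving average."""
    if len(pairs) == 0:
        return pd.DataFrame(columns=["dist", "r2", "n"])
    b = (pairs["dist"] // bin_bp).astype(int)
    agg = pairs.groupby(b)["r2"].agg(["mean", "size"])
    curve = pd.DataFrame(
        {
            "dist": (agg.index.to_numpy() + 0.5) * bin_bp,
            "r2": agg["mean"].to_numpy(),
            "n": agg["size"].to_numpy(),
        }
    )
    if smooth > 1:
        curve["r2"] = (
            curve["r2"].rolling(smooth, center=True, min_periods=1).mean()
        )
    return curve


def ne_from_ld(
    curve: pd.DataFrame,
    n_samples: int,
    alpha: float = 2.0,
    cm_per_mb: float = 1.0,
) -> pd.DataFrame:
    """LD-based recent effective size, one estimate per distance bin.

    Under drift-recombination equilibrium E[r^2] ~ 1/(alpha + 4 Ne c) plus a
    1/(2n) sampling term; inverting the sample-size-corrected r^2 in each
    distance bin gives Ne at time ~ 1/(2c) generations.  Distances are mapped
    to Morgans at `cm_per_mb` (default 1 cM/Mb).
    """
    rows = []
    for _, row in curve.iterrows():
        c = row["dist"] * cm_per_mb / 1e6 / 100.0  # bp -> Morgans
        if c <= 0:
            continue
        r2_adj = row["r2"] - 1.0 / (2.0 * n_samples)
        if r2_adj <= 0:
            warnings.warn(f"bin at {row['dist']:.0f} bp skipped: adjusted r2 <= 0")
            continue
        ne = (1.0 / (4.0 * c)) * (1.0 / r2_adj - alpha)
        rows.append({"c_morgan": c, "t_gen": 1.0 / (2.0 * c), "ne": ne})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Runs of homozygosity
# ---------------------------------------------------------------------------

def roh_scan(
    g: GenotypeMatrix,
    min_len_bp: int = 500_000,
    max_snp: int = 100,
    max_het: int = 0,
) -> pd.DataFrame:
    """Per-sample runs of homozygosity.

    A run is a maximal stretch of non-missing genotypes with at most
    `max_het` heterozygous calls, segmented into chunks of at most `max_snp`
    SNPs; chunks spanning >= `min_len_bp` are emitted.
    Returns sample_id, chrom, start, end, n_snps, length.
    """
    rows = []
    chroms = g.variants["chrom"].to_numpy()
    positions = g.variants["pos"].to_numpy()
    ids = g.samples["sample_id"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        sub = g.dosages[:, idx]
        for s in range(g.n_samples):
            row = sub[s]
            runs = []
            start_i = None
            het_count = 0
            for k in range(len(idx)):
                v = row[k]
                if np.isnan(v):
                    continue
                if v == 1:
                    het_count += 1
                    if start_i is not None and het_count > max_het:
                        runs.append((start_i, k - 1))
                        start_i = None
                        het_count = 0
                    continue
                if start_i is None:
                    start_i = k
                    het_count = 0
            if start_i is not None:
                runs.append((start_i, len(idx) - 1))
            for a, b in runs:
                # segment at max_snp SNPs
                k = a
                while k <= b:
                    k2 = min(k + max_snp - 1, b)
                    length = int(pos[k2] - pos[k] + 1)
                    if length >= min_len_bp and k2 > k:
                        rows.append(
                            (ids[s], chrom, int(pos[k]), int(pos[k2]), k2 - k + 1, length)
                        )
                    k = k2 + 1
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end", "n_snps", "length"]
    )


def roh_summary(segments: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-sample ROH count and mean length, joined with sample metadata."""
    agg = (
        segments.groupby("sample_id")["length"].agg(["size", "mean", "sum"])
        if len(segments)
        else pd.DataFrame(columns=["size", "mean", "sum"])
    )
    agg.columns = ["n_roh", "mean_length", "total_length"]
    out = samples.set_index("sample_id").join(agg)
    out[["n_roh", "total_length"]] = out[["n_roh", "total_length"]].fillna(0)
    return out.reset_index()


def roh_group_test(segments: pd.DataFrame, groups: dict) -> dict:
    """Wilcoxon rank-sum comparison of ROH lengths between two sample groups.

    groups : mapping group name -> iterable of sample_ids (exactly two).
    """
    (g1, ids1), (g2, ids2) = list(groups.items())
    x = segments.loc[segments["sample_id"].isin(set(ids1)), "length"]
    y = segments.loc[segments["sample_id"].isin(set(ids2)), "length"]
    stat, p = stats.ranksums(x, y)
    return {
        "group1": g1,
        "group2": g2,
        "mean1": float(x.mean()) if len(x) else np.nan,
        "mean2": float(y.mean()) if len(y) else np.nan,
        "statistic": float(stat),
        "p_value": float(p),
    }


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def hwe_chisq(n_AA: int, n_Aa: int, n_aa: int) -> dict:
    """Pearson chi-square test of Hardy-Weinberg proportions (1 df).

    Returns the A-allele frequency, the chi-square statistic and p-value.
    Fixed samples (p-hat in {0, 1}) return chi2=0, p=1.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or (n_AA + n_Aa + n_aa) <= 0:
        raise ValueError("genotype counts must be non-negative with positive total")
    n = n_AA + n_Aa + n_aa
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    if p == 0 or p == 1:
        return {"p_allele": p, "chi2": 0.0, "df": 1, "p_value": 1.0}
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return {
        "p_allele": p,
        "chi2": chi2,
        "df": 1,
        "p_value": float(stats.chi2.sf(chi2, 1)),
    }


# ---------------------------------------------------------------------------
# FST versus recombination
# ---------------------------------------------------------------------------

def assign_rho(per_snp: pd.DataFrame, track: pd.DataFrame) -> pd.DataFrame:
    """Attach the recombination rate of the containing track interval to each
    SNP; SNPs outside the track are dropped.  Track columns: chrom, start,
    end (bp, half-open), rho."""
    out = []
    for chrom, grp in per_snp.groupby("chrom", sort=False):
        t = track[track["chrom"] == chrom].sort_values("start")
        if len(t) == 0:
            continue
        starts = t["start"].to_numpy()
        ends = t["end"].to_numpy()
        rhos = t["rho"].to_numpy()
        pos = grp["pos"].to_numpy()
        k = np.searchsorted(starts, pos, side="right") - 1
        inside = (k >= 0) & (pos < ends[np.clip(k, 0, len(ends) - 1)])
        sub = grp.loc[inside].copy()
        sub["rho"] = rhos[k[inside]]
        out.append(sub)
    if not out:
        return per_snp.iloc[0:0].assign(rho=np.nan)
    return pd.concat(out, ignore_index=True)


def fst_vs_recombination(
    per_snp_with_rho: pd.DataFrame,
    outlier_mask: np.ndarray | None = None,
    n_bins: int = 10,
) -> dict:
    """Linear model of per-SNP FST on recombination rate, a LOESS-smoothed
    curve, and a chi-square enrichment test of outliers across rho deciles.
    """
    df = per_snp_with_rho.copy()
    if outlier_mask is not None:
        if len(outlier_mask) != len(df):
            raise ValueError("outlier mask must align with the per-SNP table")
        df["_outlier"] = np.asarray(outlier_mask, dtype=bool)
    df = df.dropna(subset=["fst", "rho"])
    if df["rho"].nunique() > 1:
        slope, intercept, r, p_slope, se = stats.linregress(df["rho"], df["fst"])
    else:
        slope = intercept = p_slope = np.nan
    from statsmodels.nonparametric.smoothers_lowess import lowess

    smoothed = lowess(df["fst"], df["rho"], frac=0.5, return_sorted=True)
    result = {
        "slope": float(slope),
        "intercept": float(intercept),
        "p_slope": float(p_slope),
        "loess": pd.DataFrame(smoothed, columns=["rho", "fst_smooth"]),
    }
    if outlier_mask is not None:
        out = df["_outlier"].to_numpy()
        rho = df["rho"].to_numpy()
        qs = np.quantile(rho, np.linspace(0, 1, n_bins + 1))
        qs = np.unique(qs)
        if len(qs) - 1 < 2:
            result["enrichment"] = None
        else:
            bins = np.clip(np.searchsorted(qs, rho, side="right") - 1, 0, len(qs) - 2)
            n_out = out.sum()
            obs = np.bincount(bins[out], minlength=len(qs) - 1)
            tot = np.bincount(bins, minlength=len(qs) - 1)
            exp = n_out * tot / tot.sum()
            keep = exp > 0
            chi2 = float(np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep]))
            dof = int(keep.sum() - 1)
            tt = stats.ttest_ind(rho[out], rho[~out], equal_var=False)
            result["enrichment"] = {
                "chi2": chi2,
                "df": dof,
                "p_value": float(stats.chi2.sf(chi2, dof)),
                "mean_rho_outliers": float(rho[out].mean()),
                "mean_rho_background": float(rho[~out].mean()),
                "t_p_value": float(tt.pvalue),
            }
    return result
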