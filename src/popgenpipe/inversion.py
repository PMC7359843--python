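"""Detection and characterisation of polymorphic chromosomal inversions.

A segregating inversion suppresses recombination between arrangements, so a
window PCA inside it separates samples into three clusters (the two
arrangement homozygotes and heterozygotes in between), and local-PCA blocks
inside it are outliers in an MDS embedding of between-block differences.
Karyotypes are assigned from the region PCA, arrangements are contrasted
with FST/pi/dxy, and the arrangement divergence Da dates the inversion as
T = Da / (2 mu) generations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .genotype_io import GenotypeMatrix
from .popgen_stats import hwe_chisq, ratio_of_sums, wc_fst_components

KARYOTYPES = ("INV/INV", "INV/STD", "STD/STD")


def _imputed_centered(dosages: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(dosages, axis=0)
    col_mean = np.nan_to_num(col_mean)
    X = np.where(np.isnan(dosages), col_mean, dosages)
    return X - X.mean(axis=0)


def _pc1(dosages: np.ndarray, return_var_frac: bool = False):
    X = _imputed_centered(dosages)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = u[:, 0] * s[0]
    if return_var_frac:
        tot = float((s**2).sum())
        return scores, float(s[0] ** 2) / tot if tot > 0 else 0.0
    return scores


def _cluster_1d(x: np.ndarray, kmax: int = 3, floor_frac: float = 0.02, min_size: int = 2):
    """Optimal 1-D clustering for each k <= kmax by dynamic programming.

    Optimal clusters of sorted data are contiguous, so the exact optimum of a
    per-cluster Gaussian likelihood (mean and variance per cluster, variance
    floored at floor_frac of the data range, multinomial mixing weights) is
    found in O(kmax n^2) — immune to the local optima that trap Lloyd's
    algorithm, and able to isolate small extreme clusters that plain
    within-cluster SSE would sacrifice to split a large diffuse bulk.

    Returns {k: (bic, labels, centers)}.
    """
    n = len(x)
    order = np.argsort(x)
    xs = x[order]
    span = xs[-1] - xs[0]
    floor = max((floor_frac * span) ** 2, 1e-12)
    c1 = np.concatenate([[0.0], np.cumsum(xs)])
    c2 = np.concatenate([[0.0], np.cumsum(xs**2)])
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    m = jj - ii + 1
    with np.errstate(invalid="ignore", divide="ignore"):
        rss = (c2[jj + 1] - c2[ii]) - (c1[jj + 1] - c1[ii]) ** 2 / m
    m_safe = np.maximum(m, 1)
    sigma2 = np.maximum(rss / m_safe, floor)
    # negative log-likelihood of segment xs[i..j] under its own Gaussian,
    # including the multinomial mixing-weight term
    cost = 0.5 * m * (np.log(2 * np.pi * sigma2) + rss / (sigma2 * m_safe))
    cost -= m * np.log(m_safe / n)
    cost[(m < min_size)] = np.inf

    D = np.full((kmax + 1, n), np.inf)
    back = np.zeros((kmax + 1, n), dtype=int)
    D[1] = cost[0]
    for kk in range(2, kmax + 1):
        prev = np.concatenate([[np.inf], D[kk - 1, :-1]])
        cand = prev[:, None] + cost
        back[kk] = np.argmin(cand, axis=0)
        D[kk] = cand[back[kk], np.arange(n)]

    out = {}
    for kk in range(1, kmax + 1):
        if not np.isfinite(D[kk, n - 1]):
            continue
        bounds = []
        j = n - 1
        for q in range(kk, 1, -1):
            i = back[q, j]
            bounds.append(i)
            j = i - 1
        lab_sorted = np.zeros(n, dtype=int)
        for b in sorted(bounds):
            lab_sorted[b:] += 1
        lab = np.empty(n, dtype=int)
        lab[order] = lab_sorted
        centers = np.array([x[lab == c].mean() for c in range(kk)])
        bic = 2 * D[kk, n - 1] + (3 * kk - 1) * np.log(n)
        out[kk] = (bic, lab, centers)
    return out


def cluster_pc1(x: np.ndarray, rng=None, min_size: int = 2) -> dict:
    """Choose k in {1,2,3} by BIC for exact 1-D clustering of PC1 scores;
    flag the window trimodal when k=3 wins with the middle centroid near
    the midpoint of the outer two (within 25% of their half-span).

    min_size=1 admits singleton clusters — appropriate when clustering a
    region already flagged by an independent detector (a lone inverted
    homozygote is real evidence there), not for genome-wide scans."""
    fits = _cluster_1d(np.asarray(x, float), kmax=3, min_size=min_size)
    best = None
    for k, (bic, lab, centers) in fits.items():
        if best is None or bic < best["bic"]:
            best = {"bic": bic, "k": k, "labels": lab, "centers": centers}
    trimodal = False
    if best["k"] == 3:
        c = np.sort(best["centers"])
        mid = (c[0] + c[2]) / 2.0
        half = (c[2] - c[0]) / 2.0
        if half > 0 and abs(c[1] - mid) <= 0.25 * half:
            trimodal = True
    best["trimodal"] = trimodal
    return best


def sliding_pca(
    g: GenotypeMatrix,
    window_bp: int = 1_000_000,
    step_bp: int = 100_000,
    min_snps: int = 20,
    var_frac_factor: float = 2.0,
    rng=None,
) -> pd.DataFrame:
    """Windowed PCA scan: per window PC1 scores clustered in 1-D, with the
    trimodal (putative-inversion) flag.  Windows with fewer than `min_snps`
    SNPs are skipped.

    A window PC1 dominated by a couple of chance-LD SNPs also clusters into
    three dosage groups, so the trimodal flag additionally requires PC1 to
    explain more than `var_frac_factor` times the genome-wide median window
    fraction — inside an inversion the arrangement axis dominates the window
    variance, a few loose SNPs do not.
    """
    rng = np.random.default_rng(rng)
    rows = []
    chroms = g.variants["chrom"].to_numpy()
    positions = g.variants["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        last = pos.max()
        start = 1
        while start <= last:
            end = start + window_bp - 1
            sel = idx[(pos >= start) & (pos <= end)]
            if len(sel) >= min_snps:
                pc1, var_frac = _pc1(g.dosages[:, sel], return_var_frac=True)
                res = cluster_pc1(pc1, rng)
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "n_snps": len(sel),
                        "k": res["k"],
                        "trimodal": res["trimodal"],
                        "pc1_var_frac": var_frac,
                        "pc1": pc1,
                    }
                )
            start += step_bp
    scan = pd.DataFrame(rows)
    if len(scan):
        thr = var_frac_factor * scan["pc1_var_frac"].median()
        scan["trimodal"] = scan["trimodal"] & (scan["pc1_var_frac"] > thr)
    return scan


def local_pca_mds(
    g: GenotypeMatrix, block_snps: int = 100, k: int = 2, mad_factor: float = 3.0
) -> pd.DataFrame:
    """Local-PCA scan: non-overlapping blocks of `block_snps` SNPs (split at
    chromosome boundaries), pairwise block distances between normalised
    rank-k approximations of the sample covariance, embedded by classical
    MDS; outlier blocks deviate from the MDS1 median by more than
    mad_factor * 1.4826 * MAD."""
    blocks = []
    chroms = g.variants["chrom"].to_numpy()
    positions = g.variants["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for s in range(0, len(idx) - block_snps + 1, block_snps):
            sel = idx[s : s + block_snps]
            blocks.append((chrom, int(positions[sel[0]]), int(positions[sel[-1]]), sel))
    if len(blocks) < 10:
        raise ValueError(f"need at least 10 blocks, got {len(blocks)}")

    mats = []
    for chrom, start, end, sel in blocks:
        X = _imputed_centered(g.dosages[:, sel])
        C = X @ X.T / max(X.shape[1] - 1, 1)
        w, v = np.linalg.eigh(C)
        order = np.argsort(w)[::-1][:k]
        Ck = (v[:, order] * w[order]) @ v[:, order].T
        norm = np.linalg.norm(Ck)
        mats.append(Ck / norm if norm > 0 else Ck)
    B = len(mats)
    D = np.zeros((B, B))
    for i in range(B):
        for j in range(i + 1, B):
            D[i, j] = D[j, i] = np.linalg.norm(mats[i] - mats[j])

    # classical MDS to 2 coordinates
    J = np.eye(B) - np.ones((B, B)) / B
    Bmat = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(Bmat)
    order = np.argsort(w)[::-1][:2]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0))

    def robust_z(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        return (v - med) / (1.4826 * mad) if mad > 0 else np.zeros_like(v)

    z1, z2 = robust_z(coords[:, 0]), robust_z(coords[:, 1])
    out = (np.abs(z1) > mad_factor) | (np.abs(z2) > mad_factor)
    # the axis carrying the stronger deviation, for sign bookkeeping
    axis = np.where(np.abs(z1) >= np.abs(z2), 1, 2)
    return pd.DataFrame(
        {
            "chrom": [b[0] for b in blocks],
            "start": [b[1] for b in blocks],
            "end": [b[2] for b in blocks],
            "mds1": coords[:, 0],
            "mds2": coords[:, 1],
            "z1": z1,
            "z2": z2,
            "outlier": out,
            "outlier_axis": axis,
        }
    )


def detect_inversions(
    g: GenotypeMatrix,
    block_snps: int = 100,
    min_blocks: int = 3,
    rng=None,
) -> list:
    """Candidate inversion regions from the local-PCA scan.

    Outlier blocks are merged into a region when they are consecutive on the
    same chromosome (gap of at most one block allowed), deviate on the same
    MDS axis with the same sign, and number at least `min_blocks` — isolated
    outlier blocks are discarded as noise.  Each region is then confirmed by
    three-cluster karyotype assignment; regions whose samples do not separate
    into three PC1 clusters stay candidates (assigned=False).

    Returns a list of dicts: region, n_blocks, call (KaryotypeCall).
    """
    blocks = local_pca_mds(g, block_snps=block_snps)
    calls = []
    for chrom, grp in blocks.groupby("chrom", sort=False):
        grp = grp.reset_index(drop=True)
        runs = []
        current = None
        gap = 0
        for i, row in grp.iterrows():
            if row["outlier"]:
                sig = (row["outlier_axis"], np.sign(row[f"mds{int(row['outlier_axis'])}"]
                                                    - np.median(grp[f"mds{int(row['outlier_axis'])}"])))
                if current is not None and sig == current["sig"]:
                    current["rows"].append(i)
                    gap = 0
                else:
                    if current is not None:
                        runs.append(current)
                    current = {"sig": sig, "rows": [i]}
                    gap = 0
            else:
                if current is not None:
                    gap += 1
                    if gap > 1:
                        runs.append(current)
                        current = None
        if current is not None:
            runs.append(current)
        for run in runs:
            if len(run["rows"]) < min_blocks:
                continue
            rows = grp.iloc[run["rows"]]
            region = (chrom, int(rows["start"].min()), int(rows["end"].max()))
            call = assign_karyotypes(g, region, rng=rng)
            if call.assigned:
                refined = refine_region(g, region, call.karyotypes)
                if refined != region:
                    refined_call = assign_karyotypes(g, refined, rng=rng)
                    if refined_call.assigned:  # keep block call otherwise
                        call, region = refined_call, refined
            calls.append({"region": region, "n_blocks": len(rows), "call": call})
    return calls


def refine_region(
    g: GenotypeMatrix, region, karyotypes: pd.Series, smooth_snps: int = 25
) -> tuple:
    """Refine inversion boundaries to SNP resolution.

    Block-level detection can misplace boundaries by up to a block when the
    boundary block mixes inversion and background SNPs.  Given a provisional
    karyotype assignment, the per-SNP correlation between genotype dosage and
    arrangement dosage (0/1/2 inverted copies) is smoothed along the
    chromosome; the region becomes the longest stretch of elevated
    correlation (above the midpoint of the inside/outside medians, gaps up
    to smooth_snps SNPs bridged) that overlaps the provisional region.
    """
    chrom, start, end = region
    kar = karyotypes.to_numpy()
    kdos = np.select(
        [kar == "STD/STD", kar == "INV/STD", kar == "INV/INV"], [0.0, 1.0, 2.0], np.nan
    )
    if np.isnan(kdos).any() or np.nanstd(kdos) == 0:
        return region
    on_chrom = np.flatnonzero((g.variants["chrom"] == chrom).to_numpy())
    pos = g.variants["pos"].to_numpy()[on_chrom]
    X = g.dosages[:, on_chrom]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(X, axis=0)
    Xc = np.where(np.isnan(X), col_mean, X) - col_mean
    kc = kdos - kdos.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(Xc.T @ kc) / np.sqrt((Xc**2).sum(axis=0) * (kc**2).sum())
    corr = np.nan_to_num(corr)
    sm = np.convolve(corr, np.ones(smooth_snps) / smooth_snps, mode="same")
    inside = (pos >= start) & (pos <= end)
    if inside.sum() < smooth_snps or (~inside).sum() < smooth_snps:
        return region
    thr = (np.median(sm[inside]) + np.median(sm[~inside])) / 2.0
    high = sm > thr
    runs = []
    i = 0
    while i < len(high):
        if high[i]:
            j = i
            while j + 1 < len(high) and high[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    if not runs:
        return region
    merged = [runs[0]]
    for a, b in runs[1:]:
        if a - merged[-1][1] <= smooth_snps:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    best = None
    for a, b in merged:
        if pos[b] >= start and pos[a] <= end:
            if best is None or (b - a) > (best[1] - best[0]):
                best = (a, b)
    if best is None:
        return region
    return (chrom, int(pos[best[0]]), int(pos[best[1]]))


# ---------------------------------------------------------------------------
# Karyotypes and arrangement statistics
# ---------------------------------------------------------------------------

def _region_mask(variants: pd.DataFrame, region) -> np.ndarray:
    chrom, start, end = region
    return (
        (variants["chrom"] == chrom)
        & (variants["pos"] >= start)
        & (variants["pos"] <= end)
    ).to_numpy()


@dataclass
class KaryotypeCall:
    region: tuple
    karyotypes: pd.Series        # sample_id -> karyotype string
    counts: dict                 # karyotype -> count
    inv_frequency: float
    per_population_frequency: dict
    hwe: dict
    assigned: bool


def assign_karyotypes(g: GenotypeMatrix, region, rng=None) -> KaryotypeCall:
    """Assign arrangement karyotypes from the region PCA.

    PC1 scores are clustered at k=3; the middle cluster is called
    heterozygous and the minor homozygote cluster carries the inverted
    arrangement (minor-frequency polarity).  If three clusters are not
    separable (BIC prefers fewer), samples are left unassigned and the call
    is demoted to a candidate.
    """
    rng = np.random.default_rng(rng)
    mask = _region_mask(g.variants, region)
    if mask.sum() < 3:
        raise ValueError("region contains too few SNPs")
    pc1 = _pc1(g.dosages[:, mask])
    res = cluster_pc1(pc1, rng, min_size=1)
    ids = g.samples["sample_id"]

    def unassigned():
        kar = pd.Series(["unassigned"] * len(ids), index=ids)
        return KaryotypeCall(region, kar, {}, np.nan, {}, {}, assigned=False)

    if res["k"] != 3:
        return unassigned()
    lab, centers = res["labels"], res["centers"]
    order = np.argsort(centers)           # low, mid, high PC1
    c = centers[order]
    # heterozygote check 1: middle centroid near the midpoint of the outer two
    half = (c[2] - c[0]) / 2.0
    if half <= 0 or abs(c[1] - (c[0] + c[2]) / 2.0) > 0.25 * half:
        return unassigned()
    # heterozygote check 2: the middle cluster is the most heterozygous
    sub = g.dosages[:, mask]
    with np.errstate(invalid="ignore"):
        het_frac = np.nanmean(sub == 1, axis=1)
    het_by_cluster = [np.nanmean(het_frac[lab == cl]) for cl in order]
    if not (het_by_cluster[1] > het_by_cluster[0] and het_by_cluster[1] > het_by_cluster[2]):
        return unassigned()
    counts_by_cluster = np.array([(lab == c).sum() for c in order])
    het_cluster = order[1]
    # minor homozygote cluster = inverted arrangement
    if counts_by_cluster[0] <= counts_by_cluster[2]:
        inv_cluster, std_cluster = order[0], order[2]
    else:
        inv_cluster, std_cluster = order[2], order[0]
    mapping = {inv_cluster: "INV/INV", het_cluster: "INV/STD", std_cluster: "STD/STD"}
    kar = pd.Series([mapping[c] for c in lab], index=ids)
    counts = {k: int((kar == k).sum()) for k in KARYOTYPES}
    n = sum(counts.values())
    inv_freq = (2 * counts["INV/INV"] + counts["INV/STD"]) / (2 * n)
    per_pop = {}
    pops = g.samples["population"].to_numpy()
    for pop in pd.unique(pops):
        sel = pops == pop
        kp = kar.to_numpy()[sel]
        npop = sel.sum()
        per_pop[pop] = (2 * np.sum(kp == "INV/INV") + np.sum(kp == "INV/STD")) / (2 * npop)
    hwe = hwe_chisq(counts["INV/INV"], counts["INV/STD"], counts["STD/STD"])
    return KaryotypeCall(region, kar, counts, inv_freq, per_pop, hwe, assigned=True)


def _group_pi_per_site(dosages: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity (2n/(2n-1) * 2p(1-p)) from diploid
    dosages, NaN-aware."""
    called = ~np.isnan(dosages)
    n_allele = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dosages, axis=0) / n_allele
        pi = 2 * p * (1 - p) * n_allele / (n_allele - 1)
    return np.nan_to_num(pi)


def arrangement_stats(
    g: GenotypeMatrix,
    region,
    karyotypes: pd.Series,
    pi_window_bp: int = 10_000,
    surveyed_bp: int | None = None,
) -> dict:
    """FST/pi/dxy/Da contrasts between arrangement groups.

    FST (WC84, ratio of sums) between the two homozygote karyotype groups is
    averaged separately inside and outside the region.  pi per karyotype
    group is reported in `pi_window_bp` windows inside the region.  dxy
    between homozygote groups uses the unphased allele-frequency estimator
    p_x(1-p_y) + p_y(1-p_x) per surveyed bp (`surveyed_bp` defaults to the
    region span; pass the RAD-covered length for sparse data), and
    Da = dxy - (pi_inv + pi_std)/2 on the same scale.
    """
    kar = karyotypes.to_numpy()
    inv_idx = np.flatnonzero(kar == "INV/INV")
    std_idx = np.flatnonzero(kar == "STD/STD")
    het_idx = np.flatnonzero(kar == "INV/STD")
    if len(inv_idx) < 2 or len(std_idx) < 2:
        raise ValueError("need at least two samples in each homozygote group")
    mask = _region_mask(g.variants, region)
    comp = wc_fst_components(g.dosages, [inv_idx, std_idx])
    a, denom = comp[:, 0], comp.sum(axis=1)
    fst_in = ratio_of_sums(a[mask], denom[mask])
    fst_out = ratio_of_sums(a[~mask], denom[~mask])

    chrom, start, end = region
    span = end - start + 1
    surveyed = surveyed_bp if surveyed_bp is not None else span
    pos = g.variants["pos"].to_numpy()
    groups = {"INV/INV": inv_idx, "STD/STD": std_idx, "INV/STD": het_idx}
    pi_windows = []
    pi_region = {}
    site_pi = {}
    for name, idx in groups.items():
        if len(idx) < 2:
            continue
        site_pi[name] = _group_pi_per_site(g.dosages[idx][:, mask])
        pi_region[name] = float(site_pi[name].sum()) / surveyed
    rpos = pos[mask]
    for wstart in range(start, end + 1, pi_window_bp):
        wend = min(wstart + pi_window_bp - 1, end)
        insel = (rpos >= wstart) & (rpos <= wend)
        row = {"chrom": chrom, "start": wstart, "end": wend, "n_snps": int(insel.sum())}
        for name in site_pi:
            row[f"pi_{name}"] = float(site_pi[name][insel].sum()) / (wend - wstart + 1)
        pi_windows.append(row)

    din = g.dosages[:, mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_inv = np.nanmean(din[inv_idx], axis=0) / 2.0
        p_std = np.nanmean(din[std_idx], axis=0) / 2.0
    ok = np.isfinite(p_inv) & np.isfinite(p_std)
    dxy = float(np.sum(p_inv[ok] * (1 - p_std[ok]) + p_std[ok] * (1 - p_inv[ok]))) / surveyed
    da = dxy - (pi_region.get("INV/INV", 0.0) + pi_region.get("STD/STD", 0.0)) / 2.0
    return {
        "fst_in": fst_in,
        "fst_out": fst_out,
        "pi_region": pi_region,
        "pi_windows": pd.DataFrame(pi_windows),
        "dxy": dxy,
        "da": da,
        "surveyed_bp": surveyed,
    }


def date_inversion(
    da: float, mu: float = 1e-8, generation_time: float = 2.3
) -> tuple[float, float]:
    """Inversion age from net arrangement divergence: T = Da / (2 mu)
    generations, converted to years at `generation_time`."""
    if da < 0:
        raise ValueError("net divergence is negative: arrangements not differentiated")
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    t_gen = da / (2.0 * mu)
    return t_gen, t_gen * generation_time


# ---------------------------------------------------------------------------
# UPGMA tree
# ---------------------------------------------------------------------------

def upgma_tree(distance_matrix: np.ndarray, labels: list[str]) -> str:
    """UPGMA (average-linkage) agglomeration of a symmetric distance matrix;
    returns an ultrametric newick string with branch lengths."""
    D = np.asarray(distance_matrix, float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("need a symmetric matrix with zero diagonal")
    if len(labels) != D.shape[0]:
        raise ValueError("label count does not match matrix size")
    if D.shape[0] == 1:
        return f"{labels[0]}:0;"
    Z = linkage(squareform(D, checks=False), method="average")
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    newick = {i: labels[i] for i in range(n)}
    for k, (i, j, dist, _) in enumerate(Z):
        i, j = int(i), int(j)
        h = dist / 2.0
        bi = h - heights[i]
        bj = h - heights[j]
        node = n + k
        # canonical child order: shorter branch (older subtree) first
        kids = sorted(
            [(bi, newick[i]), (bj, newick[j])], key=lambda t: (t[0], t[1])
        )
        newick[node] = (
            f"({kids[0][1]}:{kids[0][0]:.10g},{kids[1][1]}:{kids[1][0]:.10g})"
        )
        heights[node] = h
    return newick[n + len(Z) - 1] + ";"
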