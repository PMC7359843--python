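"""Diversity/differentiation statistics against brute-force oracles and
closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from popgenpipe import popgen_stats as ps
from popgenpipe.genotype_io import GenotypeMatrix

from .oracles import (
    counts_to_dosages,
    hwe_chi2_scalar,
    random_genotype_table,
    wc84_components_scalar,
)


def _matrix_from_dosages(dosages, populations=None, spacing=1000, chrom="chr1"):
    n, p = dosages.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, p + 1) * spacing,
            "ref": "A",
            "alt": "T",
            "mean_depth": 50.0,
        }
    )
    populations = populations if populations is not None else ["A1D"] * n
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i:03d}" for i in range(n)],
            "population": populations,
            "region": ["mainland" if p0.startswith("A") else "island" for p0 in populations],
            "habitat": ["deciduous" if p0.endswith("D") else "evergreen" for p0 in populations],
            "latitude": 43.7,
            "longitude": 3.8,
            "altitude": 200.0,
        }
    )
    return GenotypeMatrix(np.asarray(dosages, float), variants, samples)


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def test_wc_fst_fixed_difference_is_one():
    dosages = np.array([[0.0]] * 10 + [[2.0]] * 10)
    comp = ps.wc_fst_components(dosages, [np.arange(10), np.arange(10, 20)])
    a, b, c = comp[0]
    assert a / (a + b + c) == pytest.approx(1.0)


def test_wc_fst_identical_populations_not_positive():
    col = np.array([0, 0, 1, 1, 2, 2] * 2, float)[:, None]
    comp = ps.wc_fst_components(col, [np.arange(6), np.arange(6, 12)])
    a, b, c = comp[0]
    assert a / (a + b + c) <= 0.0


def test_wc_fst_single_group_errors():
    with pytest.raises(ValueError):
        ps.wc_fst_components(np.zeros((4, 1)), [np.arange(4)])


def test_wc_fst_matches_scalar_oracle_on_random_tables():
    """100 random multi-population genotype tables agree with the
    independently coded WC84 component formulas to 1e-12."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        counts = random_genotype_table(rng)
        dosages, groups = counts_to_dosages(counts)
        comp = ps.wc_fst_components(dosages, groups)
        expected = wc84_components_scalar(counts)
        np.testing.assert_allclose(comp[0], expected, rtol=0, atol=1e-12)


def test_pairwise_fst_panmictic_labels_near_zero():
    """Arbitrarily splitting one panmictic sample gives FST ~ 0 and a
    non-significant bootstrap p."""
    rng = np.random.default_rng(8)
    p = rng.uniform(0.1, 0.9, size=1000)
    dosages = rng.binomial(2, p, size=(60, 1000)).astype(float)
    g = _matrix_from_dosages(dosages, ["A1D"] * 30 + ["A2D"] * 30)
    res = ps.pairwise_fst(g, n_boot=200, seed=0)[0]
    assert abs(res.fst_all) < 0.005
    assert res.p_value > 0.01


def test_pairwise_fst_chrom_class_missing_is_nan():
    rng = np.random.default_rng(9)
    dosages = rng.integers(0, 3, (20, 50)).astype(float)
    g = _matrix_from_dosages(dosages, ["A1D"] * 10 + ["B4D"] * 10)
    res = ps.pairwise_fst(g, n_boot=10, chrom_classes={"chr1": "autosome"}, seed=0)[0]
    assert np.isnan(res.fst_z)
    assert np.isfinite(res.fst_autosome)


def test_window_fst_partial_block_and_uniform_components():
    per = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, 11) * 100,
            "a": 0.2,
            "denom": 1.0,
            "fst": 0.2,
        }
    )
    win = ps.window_fst(per, mode="snp", block_snps=50, step_snps=5)
    assert len(win) == 1 and win["n_snps"].iloc[0] == 10
    assert win["fst"].iloc[0] == pytest.approx(0.2)
    win_kb = ps.window_fst(per, mode="kb", window_bp=500, step_bp=500)
    assert np.allclose(win_kb["fst"], 0.2)


def test_window_fst_ratio_within_member_range():
    rng = np.random.default_rng(10)
    per = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, 201) * 50,
            "a": rng.uniform(0.0, 0.5, 200),
            "denom": rng.uniform(0.5, 1.5, 200),
        }
    )
    per["fst"] = per["a"] / per["denom"]
    win = ps.window_fst(per, mode="snp", block_snps=50, step_snps=5)
    pos = per["pos"].to_numpy()
    for _, w in win.iterrows():
        sel = (pos >= w["start"]) & (pos <= w["end"])
        assert per["fst"][sel].min() - 1e-12 <= w["fst"] <= per["fst"][sel].max() + 1e-12


def test_window_fst_unsorted_errors():
    per = pd.DataFrame(
        {"chrom": "chr1", "pos": [300, 100, 200], "a": 0.1, "denom": 1.0, "fst": 0.1}
    )
    with pytest.raises(ValueError, match="sorted"):
        ps.window_fst(per, mode="snp")


def test_window_fst_flags_planted_high_segment_both_modes():
    """A 50-SNP high-FST segment lands in the top-1% windows in both
    windowing modes."""
    rng = np.random.default_rng(11)
    n = 2000
    a = rng.uniform(0.0, 0.02, n)
    denom = np.ones(n)
    a[1000:1050] = 0.6
    per = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, n + 1) * 200, "a": a, "denom": denom}
    )
    per["fst"] = per["a"] / per["denom"]
    for mode in ("snp", "kb"):
        win = ps.window_fst(per, mode=mode, window_bp=200_000)
        hits = win[win["outlier"]]
        seg = hits[(hits["start"] <= 1001 * 200) & (hits["end"] >= 1049 * 200)]
        assert len(seg) >= 1, mode


# ---------------------------------------------------------------------------
# Diversity, relatedness
# ---------------------------------------------------------------------------

def test_observed_het_and_maf():
    g = _matrix_from_dosages(np.array([[0.0], [1.0], [1.0], [2.0]]))
    assert ps.observed_het(g)["A1D"] == pytest.approx(0.5)
    spec = ps.maf_spectrum(g)["A1D"]
    edges, counts = spec["bin_edges"], spec["counts"]
    assert counts.sum() == 1
    assert edges[np.argmax(np.cumsum(counts) >= 1) + 1] >= 0.5


def test_observed_het_all_homozygous_zero():
    g = _matrix_from_dosages(np.array([[0.0, 2.0], [2.0, 0.0]]))
    assert ps.observed_het(g)["A1D"] == 0.0


def test_grm_duplicate_unrelated_and_parent_offspring():
    rng = np.random.default_rng(12)
    p = rng.uniform(0.2, 0.8, 2000)
    # founders drawn in linkage equilibrium; child gets one gamete per parent
    mother = rng.binomial(1, p) + rng.binomial(1, p)
    father = rng.binomial(1, p) + rng.binomial(1, p)
    gam_m = np.where(mother == 1, rng.integers(0, 2, len(p)), mother // 2)
    gam_f = np.where(father == 1, rng.integers(0, 2, len(p)), father // 2)
    child = gam_m + gam_f
    # a large unrelated panel keeps the allele-frequency centering unbiased
    others = rng.binomial(2, p, size=(100, len(p)))
    dosages = np.vstack([mother, father, child, mother, others]).astype(float)
    g = _matrix_from_dosages(dosages)
    grm = ps.relatedness_matrix(g)
    assert grm[0, 3] == pytest.approx(grm[0, 0], rel=1e-9)  # duplicate
    assert abs(grm[0, 2] - 0.5) < 0.08                      # parent-offspring
    assert abs(grm[0, 1]) < 0.08                            # unrelated
    assert abs(grm[4:, 4:][np.triu_indices(100, 1)]).max() < 0.15
    # centered construction: row means ~ 0, matrix PSD
    assert abs(grm.mean(axis=0)).max() < 0.05
    assert np.linalg.eigvalsh(grm).min() > -1e-8


# ---------------------------------------------------------------------------
# LD and Ne
# ---------------------------------------------------------------------------

def test_ld_r2_duplicated_snp_is_one_and_null_level():
    rng = np.random.default_rng(13)
    n = 100
    dosages = rng.binomial(2, 0.5, size=(n, 40)).astype(float)
    dosages[:, 1] = dosages[:, 0]
    g = _matrix_from_dosages(dosages)
    pairs = ps.ld_r2(g, max_dist_bp=50_000)
    first = pairs[(pairs["dist"] == 1000)].iloc[0]
    assert first["r2"] == pytest.approx(1.0)
    rest = pairs[pairs["r2"] < 0.9]["r2"]
    # E[r^2] ~ 1/n for independent SNPs
    assert abs(rest.mean() - 1.0 / n) < 3.0 / n


def test_ld_decay_curve_monotone_on_recombining_chromosome():
    import msprime

    ts = msprime.sim_ancestry(
        samples=50, population_size=10_000, sequence_length=1_000_000,
        recombination_rate=1e-8, random_seed=5,
    )
    ts = msprime.sim_mutations(ts, rate=2e-8, random_seed=6)
    gm = ts.genotype_matrix()
    biall = np.array([len(set(row)) == 2 for row in gm])
    gm = gm[biall]
    dos = (gm[:, 0::2] + gm[:, 1::2]).T.astype(float)
    pos = ts.sites_position[biall].astype(int)
    keep = np.concatenate([[True], np.diff(pos) > 0])
    g = _matrix_from_dosages(dos[:, keep][:, ::3], spacing=1)
    g.variants["pos"] = pos[keep][::3]
    pairs = ps.ld_r2(g, max_dist_bp=500_000)
    curve = ps.ld_decay_curve(pairs, bin_bp=100_000, smooth=3)
    assert curve["r2"].iloc[0] > curve["r2"].iloc[-1]
    diffs = np.diff(curve["r2"])
    assert (diffs <= 0.01).all()  # non-increasing within noise


def test_ne_from_ld_closed_form_inversion():
    """r2 constructed from the drift-recombination equilibrium inverts to
    the generating Ne."""
    n, alpha, N, c = 50, 2.0, 1000.0, 0.001
    r2 = 1.0 / (alpha + 4 * N * c) + 1.0 / (2 * n)
    curve = pd.DataFrame({"dist": [c * 1e8], "r2": [r2], "n": [100]})
    out = ps.ne_from_ld(curve, n_samples=n, alpha=alpha, cm_per_mb=1.0)
    assert out["ne"].iloc[0] == pytest.approx(N, rel=1e-9)
    assert out["t_gen"].iloc[0] == pytest.approx(1 / (2 * c))
    # alpha = 0 variant: exact recovery as well
    r2b = 1.0 / (4 * N * c) + 1.0 / (2 * n)
    curve_b = pd.DataFrame({"dist": [c * 1e8], "r2": [r2b], "n": [100]})
    out_b = ps.ne_from_ld(curve_b, n_samples=n, alpha=0.0)
    assert out_b["ne"].iloc[0] == pytest.approx(N, rel=1e-9)


def test_ne_from_ld_nonpositive_bin_skipped():
    curve = pd.DataFrame({"dist": [1e5], "r2": [0.001], "n": [10]})
    with pytest.warns(UserWarning, match="skipped"):
        out = ps.ne_from_ld(curve, n_samples=50)
    assert len(out) == 0


# ---------------------------------------------------------------------------
# ROH
# ---------------------------------------------------------------------------

def _roh_matrix(genos, spacing=15_000):
    return _matrix_from_dosages(np.array(genos, float), spacing=spacing)


def test_roh_basic_run_detected():
    """A homozygous 600 kb stretch of 40 SNPs is one ROH."""
    g = _roh_matrix([[0.0] * 40])
    segs = ps.roh_scan(g, min_len_bp=500_000, max_snp=100)
    assert len(segs) == 1
    assert segs["length"].iloc[0] >= 500_000
    assert segs["n_snps"].iloc[0] == 40


def test_roh_heterozygote_splits_run():
    row = [0.0] * 40
    row[20] = 1.0
    g = _roh_matrix([row])
    segs = ps.roh_scan(g, min_len_bp=500_000, max_snp=100)
    assert len(segs) == 0  # both halves < 500 kb at 15 kb spacing


def test_roh_inbred_vs_outbred_rank_sum():
    """Inbred genomes (long homozygous tracts) give longer ROH than outbred
    ones (Wilcoxon rank-sum p < 0.05)."""
    rng = np.random.default_rng(14)
    n_snp = 400
    genos = []
    for i in range(8):  # inbred: rare hets -> long runs
        row = np.zeros(n_snp)
        row[rng.random(n_snp) < 0.01] = 1.0
        genos.append(row)
    for i in range(8):  # outbred: frequent hets
        row = np.zeros(n_snp)
        row[rng.random(n_snp) < 0.25] = 1.0
        genos.append(row)
    g = _roh_matrix(genos)
    segs = ps.roh_scan(g, min_len_bp=300_000, max_snp=100)
    ids = g.samples["sample_id"].tolist()
    res = ps.roh_group_test(segs, {"inbred": ids[:8], "outbred": ids[8:]})
    assert res["mean1"] > res["mean2"]
    assert res["p_value"] < 0.05
    summ = ps.roh_summary(segs, g.samples)
    assert summ.loc[summ["sample_id"] == ids[0], "n_roh"].iloc[0] >= 1


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts,chi2,p_bound",
    [
        ((25, 50, 25), 0.0, None),      # exact HWE proportions
        ((50, 0, 50), 100.0, 1e-20),    # no heterozygotes: chi2 = n
    ],
)
def test_hwe_chisq_closed_forms(counts, chi2, p_bound):
    res = ps.hwe_chisq(*counts)
    assert res["chi2"] == pytest.approx(chi2, abs=1e-9)
    if p_bound is not None:
        assert res["p_value"] < p_bound


def test_hwe_chisq_fixed_sample_degenerate():
    res = ps.hwe_chisq(10, 0, 0)
    assert res["chi2"] == 0.0 and res["p_value"] == 1.0


def test_hwe_chisq_matches_independent_scalar_form():
    rng = np.random.default_rng(15)
    for _ in range(50):
        counts = rng.integers(0, 11, 3)
        if counts.sum() == 0:
            continue
        n_AA, n_Aa, n_aa = (int(x) for x in counts)
        p = (2 * n_AA + n_Aa) / (2 * counts.sum())
        if p in (0.0, 1.0):
            continue
        res = ps.hwe_chisq(n_AA, n_Aa, n_aa)
        assert res["chi2"] == pytest.approx(
            hwe_chi2_scalar(n_AA, n_Aa, n_aa), abs=1e-12
        )


# ---------------------------------------------------------------------------
# FST versus recombination
# ---------------------------------------------------------------------------

def _rho_setup(rng, n=2000, dependent=False):
    pos = np.arange(1, n + 1) * 100
    rho = rng.gamma(2.0, 0.002, n)
    fst = rng.beta(0.5, 10, n)
    if dependent:
        fst = fst - 20 * rho
    per = pd.DataFrame({"chrom": "chr1", "pos": pos, "fst": fst, "rho": rho})
    return per


def test_fst_recombination_null_slope_calibrated():
    rng = np.random.default_rng(16)
    hits = 0
    for _ in range(60):
        per = _rho_setup(rng, n=400)
        res = ps.fst_vs_recombination(per)
        hits += res["p_slope"] <= 0.05
    assert hits <= 9  # ~5% expected under the null


def test_fst_recombination_enrichment_detects_low_rho_plant():
    """Outliers planted only in the lowest-rho decile give chi-square
    p < 0.01."""
    rng = np.random.default_rng(17)
    per = _rho_setup(rng, n=2000)
    thr = np.quantile(per["rho"], 0.1)
    outlier = np.zeros(len(per), bool)
    low = np.flatnonzero(per["rho"] <= thr)
    outlier[rng.choice(low, 20, replace=False)] = True
    res = ps.fst_vs_recombination(per, outlier_mask=outlier)
    assert res["enrichment"]["p_value"] < 0.01
    assert res["enrichment"]["mean_rho_outliers"] < res["enrichment"]["mean_rho_background"]


def test_fst_recombination_constant_track_skips_enrichment():
    rng = np.random.default_rng(18)
    per = _rho_setup(rng, n=200)
    per["rho"] = 0.01
    outlier = np.zeros(len(per), bool)
    outlier[:5] = True
    res = ps.fst_vs_recombination(per, outlier_mask=outlier)
    assert res["enrichment"] is None


def test_assign_rho_drops_snps_outside_track():
    per = pd.DataFrame({"chrom": "chr1", "pos": [50, 150, 500], "fst": 0.1})
    track = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [0, 100], "end": [100, 200], "rho": [0.1, 0.2]}
    )
    out = ps.assign_rho(per, track)
    assert len(out) == 2
    assert list(out["rho"]) == [0.1, 0.2]
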