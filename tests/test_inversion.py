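"""Inversion detection, karyotyping, arrangement statistics, dating, UPGMA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from popgenpipe import inversion as inv
from popgenpipe.genotype_io import GenotypeMatrix


def _matrix(dosages, spacing=1000, chrom="chr1", populations=None):
    n, p = np.asarray(dosages).shape
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, p + 1) * spacing,
            "ref": "A",
            "alt": "T",
            "mean_depth": 50.0,
        }
    )
    pops = populations or ["A1D"] * n
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i:03d}" for i in range(n)],
            "population": pops,
            "region": ["mainland"] * n,
            "habitat": ["deciduous"] * n,
            "latitude": 43.7,
            "longitude": 3.8,
            "altitude": 200.0,
        }
    )
    return GenotypeMatrix(np.asarray(dosages, float), variants, samples)


# ---------------------------------------------------------------------------
# 1-D clustering
# ---------------------------------------------------------------------------

def test_pure_noise_prefers_one_cluster():
    rng = np.random.default_rng(0)
    res = inv.cluster_pc1(rng.normal(size=100), rng=0)
    assert res["k"] == 1
    assert not res["trimodal"]


def test_two_group_structure_not_flagged_trimodal():
    rng = np.random.default_rng(1)
    x = np.concatenate([rng.normal(-3, 0.5, 50), rng.normal(3, 0.5, 50)])
    res = inv.cluster_pc1(x, rng=0)
    assert res["k"] == 2
    assert not res["trimodal"]


def test_hwe_trimodal_structure_flagged():
    """Three karyotype clusters at ~14% arrangement frequency with the
    heterozygote centroid midway are flagged trimodal."""
    rng = np.random.default_rng(2)
    x = np.concatenate(
        [rng.normal(0, 0.3, 84), rng.normal(5, 0.3, 26), rng.normal(10, 0.3, 3)]
    )
    res = inv.cluster_pc1(x, rng=0)
    assert res["k"] == 3
    assert res["trimodal"]


def test_exact_clustering_finds_small_extreme_cluster():
    rng = np.random.default_rng(3)
    x = np.concatenate([rng.normal(0, 1, 110), [-15.0, -14.9], rng.normal(-7.4, 0.4, 8)])
    res = inv.cluster_pc1(x, rng=0)
    assert res["k"] == 3
    assert sorted(np.bincount(res["labels"])) == [2, 8, 110]


# ---------------------------------------------------------------------------
# Scans on the synthetic study
# ---------------------------------------------------------------------------

def test_sliding_pca_flags_planted_inversion_windows(inversion_study):
    """At the reported mainland sample size the window PCA shows the three
    karyotype clusters inside the planted region and nowhere else (mostly)."""
    g, truth = inversion_study["g"], inversion_study["truth"]
    chrom, start, end = truth.inversion_region
    scan = inv.sliding_pca(g, window_bp=1_000_000, step_bp=100_000, rng=0)
    inside = scan[
        (scan["chrom"] == chrom) & (scan["start"] >= start) & (scan["end"] <= end)
    ]
    assert inside["trimodal"].mean() > 0.5
    outside = scan[
        (scan["chrom"] != chrom) | (scan["end"] < start) | (scan["start"] > end)
    ]
    assert outside["trimodal"].mean() < 0.1


def test_local_pca_duplicated_blocks_coincide():
    rng = np.random.default_rng(4)
    block = rng.integers(0, 3, (30, 100)).astype(float)
    blocks = [block] * 12
    g = _matrix(np.concatenate(blocks, axis=1))
    out = inv.local_pca_mds(g, block_snps=100)
    assert len(out) == 12
    np.testing.assert_allclose(out["mds1"], out["mds1"].iloc[0], atol=1e-8)
    assert not out["outlier"].any()


def test_detect_inversion_region_and_karyotypes(study_bundle):
    """The planted inversion is recovered within one 100-SNP block with
    >=95% karyotype accuracy, and heterozygotes are the most diverse group
    inside the region."""
    g, truth = study_bundle["g"], study_bundle["truth"]
    chrom, start, end = truth.inversion_region
    calls = [c for c in inv.detect_inversions(g, rng=0) if c["call"].assigned]
    assert len(calls) == 1
    region = calls[0]["region"]
    assert region[0] == chrom
    # boundary within one block: block span inside the region
    blocks = inv.local_pca_mds(g, block_snps=100)
    spans = blocks[blocks["chrom"] == chrom]
    block_bp = np.median(spans["end"] - spans["start"])
    assert abs(region[1] - start) <= 1.5 * block_bp
    assert abs(region[2] - end) <= 1.5 * block_bp

    call = calls[0]["call"]
    true_k = pd.Series(truth.karyotypes)
    acc = (call.karyotypes.reindex(true_k.index) == true_k).mean()
    assert acc >= 0.95

    st_ = inv.arrangement_stats(
        g, tuple(truth.inversion_region), call.karyotypes,
        surveyed_bp=truth.surveyed_bp_inversion,
    )
    pi = st_["pi_region"]
    assert pi["INV/STD"] > pi["INV/INV"]
    assert pi["INV/STD"] > pi["STD/STD"]
    assert st_["fst_in"] > 5 * max(st_["fst_out"], 1e-6)
    # dating from net divergence recovers the arrangement split time
    age_gen, age_yr = inv.date_inversion(st_["da"], mu=truth.config["mu"])
    assert age_gen == pytest.approx(truth.inversion_t_split, rel=0.5)


def test_assign_karyotypes_unassigned_when_unimodal():
    rng = np.random.default_rng(5)
    g = _matrix(rng.binomial(2, 0.3, size=(40, 50)).astype(float))
    call = inv.assign_karyotypes(g, ("chr1", 1, 60_000), rng=0)
    assert not call.assigned
    assert (call.karyotypes == "unassigned").all()


def test_arrangement_stats_fixed_haplotypes_and_shuffled_null():
    rng = np.random.default_rng(6)
    n = 40
    # inside region (first 30 SNPs): homozygote groups fixed for opposite alleles
    kar = np.array(["INV/INV"] * 8 + ["STD/STD"] * 24 + ["INV/STD"] * 8)
    inside = np.where(kar == "INV/INV", 2.0, 0.0)[:, None] * np.ones(30)
    inside[kar == "INV/STD"] = 1.0
    outside = rng.binomial(2, 0.4, size=(n, 70)).astype(float)
    g = _matrix(np.concatenate([inside, outside], axis=1))
    region = ("chr1", 1, 30_500)
    ks = pd.Series(kar, index=g.samples["sample_id"])
    res = inv.arrangement_stats(g, region, ks)
    assert res["fst_in"] == pytest.approx(1.0)
    assert res["fst_out"] < 0.1
    # permuted labels: no differentiation anywhere
    perm = pd.Series(rng.permutation(kar), index=g.samples["sample_id"])
    null = inv.arrangement_stats(g, region, perm)
    assert abs(null["fst_in"]) < 0.25
    assert abs(null["fst_out"]) < 0.1


# ---------------------------------------------------------------------------
# Dating
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "da,mu,gens,years",
    [
        (0.0044, 1e-8, 220_000, 506_000),
        (0.0020, 1e-8, 100_000, 230_000),
        (0.0, 1e-8, 0.0, 0.0),
    ],
)
def test_date_inversion_values(da, mu, gens, years):
    g_, y_ = inv.date_inversion(da, mu=mu)
    assert g_ == pytest.approx(gens)
    assert y_ == pytest.approx(years)


def test_date_inversion_negative_da_errors():
    with pytest.raises(ValueError, match="negative"):
        inv.date_inversion(-0.001)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    da=st.floats(1e-6, 0.1), mu=st.floats(1e-9, 1e-6), scale=st.floats(0.1, 10.0)
)
def test_date_inversion_linearity(da, mu, scale):
    """Age is linear in Da and in 1/mu."""
    t, _ = inv.date_inversion(da, mu=mu)
    t_scaled, _ = inv.date_inversion(da * scale, mu=mu)
    assert t_scaled == pytest.approx(t * scale, rel=1e-9)
    t_mu, _ = inv.date_inversion(da, mu=mu * scale)
    assert t_mu == pytest.approx(t / scale, rel=1e-9)


def test_region_span_consistent_with_reported_size():
    """The canonical mainland inversion coordinates span ~2.8 Mb."""
    span_mb = (14_661_550 - 11_838_789 + 1) / 1e6
    assert span_mb == pytest.approx(2.82, abs=0.01)
    assert round(span_mb, 1) == 2.8


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def test_upgma_three_taxa_hand_computed():
    D = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float)
    nwk = inv.upgma_tree(D, ["A", "B", "C"])
    assert nwk == "((A:1,B:1):3,C:4);"


def test_upgma_two_taxa():
    nwk = inv.upgma_tree(np.array([[0, 4], [4, 0]], float), ["A", "B"])
    assert nwk == "(A:2,B:2);"


def test_upgma_ultrametric_root_depths_equal():
    rng = np.random.default_rng(7)
    import io

    from Bio import Phylo

    n = 8
    M = rng.uniform(1, 5, (n, n))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0)
    labels = [f"t{i}" for i in range(n)]
    nwk = inv.upgma_tree(D, labels)
    tree = Phylo.read(io.StringIO(nwk), "newick")
    depths = tree.depths()
    leaf_depths = [d for cl, d in depths.items() if cl.is_terminal()]
    assert max(leaf_depths) - min(leaf_depths) < 1e-9


def test_upgma_rejects_nan():
    D = np.array([[0, np.nan], [np.nan, 0]])
    with pytest.raises(ValueError, match="NaN"):
        inv.upgma_tree(D, ["A", "B"])
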