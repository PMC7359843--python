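"""Divergence-model enumeration, priors, coalescent simulation, and ABC
summary statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from popgenpipe import demography as dm

from .oracles import pi_pairwise_scalar, watterson_theta_scalar


def _stat(vec, name):
    return vec[dm.SUMMARY_STAT_NAMES.index(name)]


# ---------------------------------------------------------------------------
# Model enumeration and priors
# ---------------------------------------------------------------------------

def test_twenty_model_variants():
    models = dm.enumerate_models()
    assert len(models) == 20
    pan = [m for m in models if m.base == "PAN"]
    assert {(m.n_hetero, m.m_hetero) for m in pan} == {(False, False), (True, False)}
    eq = [m for m in models if m.base == "EQ"]
    assert len(eq) == 4
    names = {m.name for m in models}
    assert len(names) == 20


def test_m_hetero_invalid_for_isolation_models():
    with pytest.raises(ValueError):
        dm.DemographicModel("SI", m_hetero=True)
    with pytest.raises(ValueError):
        dm.DemographicModel("PAN", m_hetero=True)


def test_si_draws_have_no_migration():
    rng = np.random.default_rng(0)
    p = dm.sample_priors(dm.DemographicModel("SI"), rng=rng)
    assert p.M12 == 0.0 and p.M21 == 0.0


def test_am_epoch_ordering_always_holds():
    rng = np.random.default_rng(1)
    for _ in range(200):
        p = dm.sample_priors(dm.DemographicModel("AM"), rng=rng)
        assert 0 < p.T_am < p.T_split
        p2 = dm.sample_priors(dm.DemographicModel("SC"), rng=rng)
        assert 0 < p2.T_sc < p2.T_split


def test_eq_migration_prior_marginal_is_uniform():
    rng = np.random.default_rng(2)
    draws = np.array(
        [dm.sample_priors(dm.DemographicModel("EQ"), rng=rng).M12 for _ in range(10_000)]
    )
    ks = sps.kstest(draws, sps.uniform(0, 40).cdf)
    assert ks.pvalue > 0.01


def test_param_validation_errors():
    m = dm.DemographicModel("AM")
    p = dm.DemographicParams(T_split=1000, T_am=2000, M12=1)
    with pytest.raises(ValueError, match="T_am"):
        p.validate(m)
    with pytest.raises(ValueError, match="coalesce"):
        dm.DemographicParams(M12=0, M21=0).validate(dm.DemographicModel("EQ"))


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def test_summarize_hand_example_fixed_differences():
    """pop1 all-0, pop2 all-1 over 10 sites, L=100: dxy=0.1, pi=0, Da=0.1,
    sf=10."""
    h = np.vstack([np.zeros((4, 10), np.int8), np.ones((4, 10), np.int8)])
    locus = dm.Locus(np.arange(10.0), h, np.array([0, 0, 0, 0, 1, 1, 1, 1], np.int8))
    ds = dm.HaplotypeDataset([locus], 100)
    vec = dm.summarize(ds)
    assert _stat(vec, "pi1_mean") == 0.0
    assert _stat(vec, "pi2_mean") == 0.0
    assert _stat(vec, "dxy_mean") == pytest.approx(0.1)
    assert _stat(vec, "da_mean") == pytest.approx(0.1)
    assert _stat(vec, "sf_mean") == 10.0
    assert _stat(vec, "ss_mean") == 0.0


def test_summarize_identical_population_haplotypes():
    rng = np.random.default_rng(3)
    h1 = rng.integers(0, 2, (6, 8)).astype(np.int8)
    h = np.vstack([h1, h1])
    locus = dm.Locus(np.arange(8.0), h, np.repeat([0, 1], 6).astype(np.int8))
    vec = dm.summarize(dm.HaplotypeDataset([locus], 100))
    assert _stat(vec, "sf_mean") == 0.0
    # dxy equals total pi up to the finite-sample correction factor
    n = 12
    assert _stat(vec, "dxy_mean") == pytest.approx(
        _stat(vec, "pi1_mean") * (6 - 1) / 6, rel=1e-9
    )
    assert abs(_stat(vec, "da_mean")) < _stat(vec, "pi1_mean") / 5


def test_pi_theta_match_pairwise_oracle():
    rng = np.random.default_rng(4)
    h = rng.integers(0, 2, (20, 15)).astype(np.int8)
    pops = np.repeat([0, 1], 10).astype(np.int8)
    L = 85
    vec = dm.summarize(dm.HaplotypeDataset([dm.Locus(np.arange(15.0), h, pops)], L))
    assert _stat(vec, "pi1_mean") == pytest.approx(
        pi_pairwise_scalar(h[:10], L), abs=1e-12
    )
    assert _stat(vec, "theta2_mean") == pytest.approx(
        watterson_theta_scalar(h[10:], L), abs=1e-12
    )


def test_summarize_rejects_single_haplotype_population():
    h = np.zeros((3, 4), np.int8)
    locus = dm.Locus(np.arange(4.0), h, np.array([0, 0, 1], np.int8))
    with pytest.raises(ValueError, match="two haplotypes"):
        dm.summarize(dm.HaplotypeDataset([locus], 85))


# ---------------------------------------------------------------------------
# Coalescent simulation
# ---------------------------------------------------------------------------

def test_pan_pseudo_populations_undifferentiated():
    m = dm.DemographicModel("PAN")
    p = dm.DemographicParams(N_pop1=10_000, N_pop2=10_000, mu=2e-7)
    ds = dm.simulate_dataset(m, p, n_loci=500, sample_config=(10, 10), rng=5)
    vec = dm.summarize(ds)
    assert abs(_stat(vec, "fst_mean")) < 0.02
    # E[Da] = 0 under panmixia, within 3 SE
    das = np.array([dm._locus_stats(lc, 85)[5] for lc in ds.loci])
    se = das.std() / np.sqrt(len(das))
    assert abs(das.mean()) < 3 * se


def test_si_deep_split_fixes_differences_and_loses_shared_polymorphism():
    m = dm.DemographicModel("SI")
    p = dm.DemographicParams(
        N_anc=2_000, N_pop1=2_000, N_pop2=2_000, T_split=100_000, mu=2e-7
    )
    ds = dm.simulate_dataset(m, p, n_loci=300, sample_config=(8, 8), rng=6)
    vec = dm.summarize(ds)
    assert _stat(vec, "sf_mean") > 0.5
    assert _stat(vec, "ss_mean") < 0.05 * _stat(vec, "sf_mean")


def test_neutral_diversity_unbiased():
    """Watterson theta and pi both ~ 4*N*mu under neutral panmixia."""
    m = dm.DemographicModel("PAN")
    N, mu = 10_000, 2e-7
    p = dm.DemographicParams(N_pop1=N, N_pop2=N, mu=mu)
    ds = dm.simulate_dataset(m, p, n_loci=2_000, sample_config=(10, 10), rng=7)
    per = np.array([dm._locus_stats(lc, 85) for lc in ds.loci])
    expected = 4 * N * mu
    for col in (0, 2):  # pi1, theta1
        vals = per[:, col]
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - expected) < 3 * se


def test_eq_fst_strictly_decreasing_in_migration():
    m = dm.DemographicModel("EQ")
    fsts = []
    for i, M in enumerate((0.4, 4.0, 40.0)):
        p = dm.DemographicParams(N_pop1=10_000, N_pop2=10_000, M12=M, M21=M, mu=2e-7)
        ds = dm.simulate_dataset(m, p, n_loci=400, sample_config=(10, 10), rng=100 + i)
        fsts.append(_stat(dm.summarize(ds), "fst_mean"))
    assert fsts[0] > fsts[1] > fsts[2]


def test_nonviable_params_error_before_simulation():
    m = dm.DemographicModel("AM")
    p = dm.DemographicParams(T_split=1_000, T_am=5_000, M12=1.0)
    with pytest.raises(ValueError):
        dm.simulate_dataset(m, p, n_loci=1, rng=0)


def test_degenerate_heterogeneity_matches_homogeneous_model():
    """Beta(a, a) with large a has vanishing variance: the Nhetero variant
    reproduces the homogeneous model's FST-mean distribution (KS p > 0.01
    over replicate datasets)."""
    rng = np.random.default_rng(8)
    base = dict(N_pop1=5_000, N_pop2=5_000, M12=4.0, M21=4.0, mu=2e-7)
    homo = dm.DemographicModel("EQ")
    het = dm.DemographicModel("EQ", n_hetero=True, m_hetero=True)
    f_homo, f_het = [], []
    for _ in range(60):
        p = dm.DemographicParams(**base)
        ds = dm.simulate_dataset(homo, p, n_loci=40, sample_config=(6, 6), rng=rng)
        f_homo.append(_stat(dm.summarize(ds), "fst_mean"))
        p2 = dm.DemographicParams(**base, a_N=500.0, b_N=500.0, a_M=500.0, b_M=500.0)
        ds2 = dm.simulate_dataset(het, p2, n_loci=40, sample_config=(6, 6), rng=rng)
        f_het.append(_stat(dm.summarize(ds2), "fst_mean"))
    ks = sps.ks_2samp(f_homo, f_het)
    assert ks.pvalue > 0.01


def test_simulation_table_layout(abc_table):
    assert set(abc_table["model"].str.split("_").str[0]) == {"PAN", "EQ", "SI", "AM"}
    for nm in dm.SUMMARY_STAT_NAMES:
        assert nm in abc_table.columns
        assert np.isfinite(abc_table[nm]).all()
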