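"""Shared fixtures: one synthetic study and one ABC reference table per
session, both deterministic.  Problem sizes are desk-scale (see
docs/methods.md)."""

import numpy as np
import pytest

from popgenpipe import demography as dm
from popgenpipe import synthetic_data as sd

STUDY_SEED = 1
ABC_TABLE_SEED = 202
ABC_MODELS = ("PAN", "EQ", "SI", "AM")
ABC_SIMS_PER_MODEL = 500
ABC_N_LOCI = 100
ABC_SAMPLE_CONFIG = (10, 10)


@pytest.fixture(scope="session")
def study_bundle():
    """Default synthetic study: genotypes, truth, background haplotypes."""
    cfg = sd.StudyConfig()
    g, truth, haps = sd.generate_study(cfg, seed=STUDY_SEED, keep_haplotypes=True)
    return {"g": g, "truth": truth, "haps": haps, "cfg": cfg}


@pytest.fixture(scope="session")
def inversion_study():
    """Mainland-only study at the reported karyotyping sample size
    (3 populations x 38 = 114 birds, arrangement frequency 0.14)."""
    cfg = sd.PRESETS["inversion"]()
    g, truth = sd.generate_study(cfg, seed=4)
    return {"g": g, "truth": truth, "cfg": cfg}


@pytest.fixture(scope="session")
def abc_table():
    """Reference simulation table over PAN/EQ/SI/AM (homogeneous variants)."""
    rng = np.random.default_rng(ABC_TABLE_SEED)
    models = [dm.DemographicModel(b) for b in ABC_MODELS]
    return dm.simulate_summary_table(
        models,
        n_sims_per_model=ABC_SIMS_PER_MODEL,
        n_loci=ABC_N_LOCI,
        sample_config=ABC_SAMPLE_CONFIG,
        rng=rng,
    )
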