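"""Diversity and differentiation across the filtered study: observed
heterozygosity and MAF spectra per population, pairwise Weir-Cockerham FST
with locus bootstraps, LD decay with an LD-based recent-Ne estimate, and a
runs-of-homozygosity comparison between regions.  Tables go to
results/diversity/.
"""

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from popgenpipe import popgen_stats as ps
from popgenpipe.genotype_io import read_vcf

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    g = read_vcf(ROOT / "filtered" / "filtered.vcf", ROOT / "filtered" / "filtered_samples.tsv")
    out = ROOT / "diversity"
    out.mkdir(parents=True, exist_ok=True)

    ho = ps.observed_het(g)
    ho.to_csv(out / "observed_het.tsv", sep="\t", header=["Ho"])
    main_ho = ho[[p for p in ho.index if p.startswith("A")]].mean()
    isl_ho = ho[[p for p in ho.index if p.startswith("B")]].mean()
    print(f"Ho mainland {main_ho:.4f} vs island {isl_ho:.4f} "
          f"({'higher on mainland' if main_ho > isl_ho else 'higher on island'})")

    spectra = ps.maf_spectrum(g)
    rows = []
    for pop, spec in spectra.items():
        rows.append({"population": pop, "n_polymorphic_maf05": spec["n_polymorphic_maf05"]})
    pd.DataFrame(rows).to_csv(out / "polymorphic_counts.tsv", sep="\t", index=False)

    pw = ps.pairwise_fst(g, n_boot=200, seed=SEED)
    pw_df = pd.DataFrame([asdict(r) for r in pw])
    pw_df.to_csv(out / "pairwise_fst.tsv", sep="\t", index=False)
    between = pw_df[
        pw_df.apply(lambda r: r["pop1"][0] != r["pop2"][0], axis=1)
    ]["fst_all"]
    within = pw_df[
        pw_df.apply(lambda r: r["pop1"][0] == r["pop2"][0], axis=1)
    ]["fst_all"]
    print(f"pairwise FST: between-region mean {between.mean():.4f}, "
          f"within-region mean {within.mean():.4f}")
    print(f"all pairs significantly > 0: {(pw_df['p_value'] < 0.05).all()}")

    # LD decay on chr1 for one mainland population, and the Ne it implies
    pops = g.population_indices()
    sub = g.take_samples(pops["A1D"]).take_variants(
        np.flatnonzero((g.variants["chrom"] == "chr1").to_numpy())
    )
    pairs = ps.ld_r2(sub, max_dist_bp=300_000)
    curve = ps.ld_decay_curve(pairs, bin_bp=25_000, smooth=3)
    curve.to_csv(out / "ld_decay_A1D_chr1.tsv", sep="\t", index=False)
    ne = ps.ne_from_ld(curve, n_samples=len(pops["A1D"]))
    ne.to_csv(out / "ne_ld_A1D.tsv", sep="\t", index=False)
    if len(ne):
        print(f"LD-based Ne (A1D): median {ne['ne'].median():,.0f} across "
              f"{len(ne)} distance bins")

    # ROH by region (short windows: the desk-scale map is SNP-sparse)
    segs = ps.roh_scan(g, min_len_bp=200_000, max_snp=100)
    segs.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
    if len(segs):
        ids = g.samples
        groups = {
            "island": ids.loc[ids["region"] == "island", "sample_id"].tolist(),
            "mainland": ids.loc[ids["region"] == "mainland", "sample_id"].tolist(),
        }
        res = ps.roh_group_test(segs, groups)
        print(f"ROH mean length island {res['mean1']:.0f} vs mainland "
              f"{res['mean2']:.0f} bp (rank-sum p = {res['p_value']:.3g})")
    else:
        print("no ROH segments at these thresholds")


if __name__ == "__main__":
    main()
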