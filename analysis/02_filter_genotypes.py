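"""Apply the post-genotyping filter chain to the study VCF: mean-depth
window [10, 100], variant call rate >= 0.8, per-region heterozygosity
excess < 0.65, sample call rate >= 0.85, relatedness pruning at 0.35,
per-population cap of 60, monomorphic removal.  Writes the filtered VCF and
a per-rule removal report under results/filtered/.
"""

from pathlib import Path

from popgenpipe.genotype_io import (
    FilterConfig,
    apply_filters,
    read_vcf,
    write_metadata,
    write_vcf,
)

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    g = read_vcf(ROOT / "study" / "study.vcf", ROOT / "study" / "samples.tsv")
    out = ROOT / "filtered"
    out.mkdir(parents=True, exist_ok=True)
    filtered, report = apply_filters(g, FilterConfig(), seed=SEED)
    write_vcf(filtered, out / "filtered.vcf")
    write_metadata(filtered.samples, out / "filtered_samples.tsv")
    report.to_json(out / "filter_report.json")
    print(f"input : {g.n_samples} samples x {g.n_variants} variants")
    print(f"output: {filtered.n_samples} samples x {filtered.n_variants} variants")
    for step in report.steps:
        print(f"  removed {step['removed']:>5} {step['kind']:<8} ({step['rule']})")


if __name__ == "__main__":
    main()
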