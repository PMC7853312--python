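"""Per-population genetic diversity (pi, Watterson's theta, windowed
Tajima's D) from the raw, unfiltered genotype likelihoods.

Diversity uses all sites (variant and invariant) so per-site means are
interpretable; the SNP filters of script 02 would bias the spectrum."""

import pandas as pd

from common import RAW_VCF, RESULTS, SAMPLE_TABLE, ensure_dirs

from pikapop.diversity import population_diversity
from pikapop.io_core import read_sample_table, read_vcf_gl


def main() -> None:
    ensure_dirs()
    gl = read_vcf_gl(RAW_VCF)
    samples = read_sample_table(SAMPLE_TABLE)

    rows = []
    all_windows = []
    for pop, members in samples.groupby("population")["sample_id"]:
        sub = gl.subset_samples(list(members))
        summary, windows, _ = population_diversity(sub, population=pop)
        rows.append(vars(summary))
        windows.insert(0, "population", pop)
        all_windows.append(windows)
        print(f"{pop}: n={summary.n_individuals}  pi={summary.pi:.5f}  "
              f"thetaW={summary.theta_w:.5f}  mean D={summary.mean_tajima_d:.3f} "
              f"({summary.n_windows} windows)")

    pd.DataFrame(rows).to_csv(RESULTS / "diversity_summary.csv", index=False)
    pd.concat(all_windows, ignore_index=True).to_csv(
        RESULTS / "tajima_windows.csv", index=False)
    print(f"tables -> {RESULTS / 'diversity_summary.csv'}, "
          f"{RESULTS / 'tajima_windows.csv'}")


if __name__ == "__main__":
    main()
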