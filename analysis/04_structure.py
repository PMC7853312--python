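"""PCA of genotype dosages and Nei's standard genetic distance between
populations, from the filtered SNP panel."""

import numpy as np
import pandas as pd

from common import FILTERED_VCF, RESULTS, SAMPLE_TABLE, ensure_dirs

from pikapop.io_core import read_sample_table, read_vcf_gl
from pikapop.structure_stats import nei_distance, pop_allele_freqs, run_pca


def main() -> None:
    ensure_dirs()
    gl = read_vcf_gl(FILTERED_VCF)
    samples = read_sample_table(SAMPLE_TABLE)

    post = gl.normalized()
    dosage = post[:, :, 1] + 2 * post[:, :, 2]

    pca = run_pca(dosage)
    scores = pd.DataFrame(pca.scores[:, :4],
                          columns=[f"PC{c + 1}" for c in range(4)])
    scores.insert(0, "population", samples["population"])
    scores.insert(0, "sample_id", gl.sample_ids)
    scores.to_csv(RESULTS / "pca_scores.csv", index=False)
    pct = 100 * pca.proportion_variance[:4]
    print("variance explained: " + ", ".join(
        f"PC{c + 1} {v:.1f}%" for c, v in enumerate(pct)))

    freqs = pop_allele_freqs(dosage, samples)
    nei = nei_distance(freqs)
    nei.to_frame().to_csv(RESULTS / "nei_distance.csv")
    (RESULTS / "nei_distance.phy").write_text(nei.to_phylip())
    with np.printoptions(precision=4):
        print("Nei's D:")
        print(nei.to_frame().to_string())
    print(f"tables -> {RESULTS / 'pca_scores.csv'}, {RESULTS / 'nei_distance.csv'}")


if __name__ == "__main__":
    main()
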