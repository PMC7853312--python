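"""Gibbs admixture on the filtered SNP panel with DIC model choice over k."""

import pandas as pd

from common import DATASET_SEED, FILTERED_VCF, RESULTS, ensure_dirs

from pikapop.ancestry import McmcSettings, gibbs_admixture, select_k
from pikapop.io_core import read_vcf_gl


def main() -> None:
    ensure_dirs()
    gl = read_vcf_gl(FILTERED_VCF)
    settings = McmcSettings(n_steps=3000, burn_in=750, thin=5,
                            n_chains=1, seed=DATASET_SEED)
    fits = {}
    for k in (1, 2, 3, 4):
        fits[k] = gibbs_admixture(gl, k, settings)
        print(f"k={k}: DIC={fits[k].dic:.1f}  p_D={fits[k].p_d:.1f}")
    best, table = select_k(fits)
    table.to_csv(RESULTS / "ancestry_dic.csv", index=False)
    q = pd.DataFrame(fits[best].q, columns=[f"cluster_{c}" for c in range(best)])
    q.insert(0, "sample_id", gl.sample_ids)
    q.to_csv(RESULTS / "ancestry_q.csv", index=False)
    print(f"DIC selects k={best}")
    print(f"tables -> {RESULTS / 'ancestry_dic.csv'}, {RESULTS / 'ancestry_q.csv'}")


if __name__ == "__main__":
    main()
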