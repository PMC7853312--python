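"""Filter the raw VCF to the analysis SNP panel and report the attrition."""

from common import DATASET_SEED, FILTERED_VCF, RAW_VCF, RESULTS, ensure_dirs

from pikapop.io_core import read_vcf_gl, write_vcf_gl
from pikapop.variant_filter import FilterConfig, apply_filters


def main() -> None:
    ensure_dirs()
    gl = read_vcf_gl(RAW_VCF)
    config = FilterConfig(completeness_min=0.92, maf_min=0.05,
                          thin_block=1000, seed=DATASET_SEED)
    filtered, report = apply_filters(
        gl, config, n_multiallelic_skipped=gl.n_multiallelic_skipped
    )
    write_vcf_gl(filtered, FILTERED_VCF)
    table = report.to_frame()
    out = RESULTS / "filter_report.csv"
    table.to_csv(out, index=False)
    print(table.to_string(index=False))
    print(f"filtered VCF -> {FILTERED_VCF}")
    print(f"report -> {out}")


if __name__ == "__main__":
    main()
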