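"""Shared paths and the demo dataset configuration for the analysis scripts.

The scripts are meant to run in numeric order; each one reads what the
previous ones left in ``scratch/`` (bulky intermediates, not committed) and
writes small summary tables to ``results/``.
"""

from pathlib import Path

from pikapop.synthetic_data import SimulationParams

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

DATASET_SEED = 2021

# Three montane populations, moderate divergence, ddRAD-like sparse depth.
DATASET = SimulationParams(
    n_populations=3,
    samples_per_population=[15, 12, 13],
    fst_per_population=[0.25, 0.25, 0.35],
    n_variant_sites=1200,
    invariant_fraction=0.9,
    mean_depth=8,
    seed=DATASET_SEED,
)

RAW_VCF = SCRATCH / "demo_raw.vcf"
FILTERED_VCF = SCRATCH / "demo_filtered.vcf"
SAMPLE_TABLE = RESULTS / "demo_samples.csv"


def ensure_dirs() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
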