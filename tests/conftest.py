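import numpy as np
import pandas as pd
import pytest

from pikapop.synthetic_data import SimulationParams, simulate_metapopulation

DATA_DIR = __file__.rsplit("/", 1)[0] + "/data"


@pytest.fixture(scope="session")
def two_pop_dataset():
    """A well-separated two-population simulation with known truth."""
    params = SimulationParams(
        n_populations=2,
        samples_per_population=[20, 20],
        fst_per_population=[0.4, 0.4],
        n_variant_sites=300,
        invariant_fraction=0.0,
        mean_depth=20,
        seed=42,
    )
    return simulate_metapopulation(params)


@pytest.fixture()
def certain_gl():
    """Factory: a GenotypeLikelihoodSet with effectively certain genotypes."""
    from pikapop.io_core import GenotypeLikelihoodSet

    def make(genotypes, scaffold="s0", positions=None, depth=50, floor=1e-12):
        genotypes = np.asarray(genotypes, dtype=int)
        n, L = genotypes.shape
        lk = np.full((n, L, 3), floor)
        for g in range(3):
            lk[:, :, g][genotypes == g] = 1.0
        if positions is None:
            positions = np.arange(1, L + 1) * 10
        sites = pd.DataFrame(
            {"scaffold": scaffold, "pos": positions, "ref": "A", "alt": "G"}
        )
        depths = np.full((n, L), depth, dtype=int)
        return GenotypeLikelihoodSet(
            sample_ids=[f"i{j}" for j in range(n)],
            sites=sites,
            likelihoods=lk,
            depths=depths,
        )

    return make
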