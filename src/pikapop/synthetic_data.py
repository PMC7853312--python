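"""Synthetic genotype-likelihood datasets with known truth.

The generator emulates the statistical structure a likelihood-aware
reduced-representation (ddRADseq/GBS) analysis assumes:

* K source populations whose allele frequencies diverge from a shared
  ancestral frequency under the Balding–Nichols model (a Beta distribution
  parameterised by one Fst dial per population);
* individuals with Dirichlet-distributed admixture proportions (or pure
  ancestry in their home population when the concentration is zero);
* Hardy–Weinberg genotypes given each individual's admixed allele frequency;
* Poisson read depth per individual per site and a symmetric per-base error
  rate, giving binomial read counts and hence genotype likelihoods;
* invariant as well as variant sites scattered along named scaffolds (the
  invariant majority matters for per-site diversity denominators);
* geography and 19 bioclim-style climate variables whose temperature block
  tracks elevation (lapse rate) and whose precipitation/seasonality block
  follows a smooth spatial gradient.

Everything is deterministic given the seed; the VCF written from a simulated
dataset is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import (
    CLIMATE_VARIABLES,
    PRECIPITATION_VARIABLES,
    TEMPERATURE_VARIABLES,
    GenotypeLikelihoodSet,
)

__all__ = [
    "SimulationParams",
    "TruthRecord",
    "ClimateGeographyParams",
    "simulate_metapopulation",
    "simulate_climate_geography",
    "simulate_sfs_sites",
]


@dataclass
class SimulationParams:
    """Parameters of the metapopulation genotype-likelihood simulator."""

    n_populations: int = 2
    samples_per_population: list[int] = field(default_factory=lambda: [20, 20])
    n_scaffolds: int = 5
    scaffold_length: int = 1_000_000
    n_variant_sites: int = 500
    fst_per_population: list[float] = field(default_factory=lambda: [0.3, 0.3])
    admixture_alpha: float = 0.0
    mean_depth: float = 10.0
    error_rate: float = 0.001
    ancestral_freq_beta: tuple[float, float] = (0.8, 0.8)
    invariant_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("need at least one population")
        if len(self.samples_per_population) != self.n_populations:
            raise ValueError("samples_per_population length != n_populations")
        if sum(self.samples_per_population) <= 0:
            raise ValueError("zero total samples")
        if len(self.fst_per_population) != self.n_populations:
            raise ValueError("fst_per_population length != n_populations")
        if not all(0.0 < f < 1.0 for f in self.fst_per_population):
            raise ValueError("all Fst values must lie strictly in (0, 1)")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.admixture_alpha < 0:
            raise ValueError("admixture_alpha must be >= 0")
        if not (0.0 <= self.invariant_fraction < 1.0):
            raise ValueError("invariant_fraction must lie in [0, 1)")

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_population)

    @property
    def n_total_sites(self) -> int:
        if self.invariant_fraction == 0.0:
            return self.n_variant_sites
        return int(round(self.n_variant_sites / (1.0 - self.invariant_fraction)))


@dataclass
class TruthRecord:
    """Ground truth of a simulation run, for parameter-recovery tests."""

    true_q: np.ndarray  # N x K ancestry proportions, rows sum to 1
    true_p: np.ndarray  # K x L_total allele frequencies
    true_genotypes: np.ndarray  # N x L_total dosages in {0,1,2}
    variant_mask: np.ndarray  # length L_total; True at designed-variant sites


@dataclass
class ClimateGeographyParams:
    """Parameters of the synthetic geography/climate generator."""

    n_sites: int = 11
    elevation_range: tuple[float, float] = (1800.0, 3700.0)
    temp_lapse_rate: float = 6.5  # units lost per km of elevation
    precip_spatial_scale: float = 300.0  # km extent of the precipitation gradient
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValueError("n_sites must be >= 3 (climate PCA undefined below)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


_NUC = np.array(list("ACGT"))


def _place_sites(rng: np.random.Generator, n_scaffolds: int, scaffold_length: int,
                 n_sites: int) -> pd.DataFrame:
    """Scatter ``n_sites`` distinct positions uniformly over the scaffolds."""
    per = np.full(n_scaffolds, n_sites // n_scaffolds)
    per[: n_sites % n_scaffolds] += 1
    rows = []
    for s, m in enumerate(per):
        if m > scaffold_length:
            raise ValueError(
                f"scaffold of {scaffold_length} bp cannot host {m} distinct sites"
            )
        pos = np.sort(rng.choice(scaffold_length, size=m, replace=False)) + 1
        for p in pos:
            rows.append((f"scaffold_{s}", int(p)))
    df = pd.DataFrame(rows, columns=["scaffold", "pos"])
    ref = _NUC[rng.integers(0, 4, size=len(df))]
    alt_shift = rng.integers(1, 4, size=len(df))
    alt = _NUC[(np.searchsorted(_NUC, ref) + alt_shift) % 4]
    df["ref"] = ref
    df["alt"] = alt
    return df


def _reads_to_likelihoods(depth: np.ndarray, alt_reads: np.ndarray,
                          error_rate: float) -> np.ndarray:
    """Binomial read likelihoods for the three genotypes, max-normalised.

    Under genotype g the probability a read shows the alternate allele is
    eps, 1/2, 1-eps for g = 0, 1, 2.  The binomial coefficient is common to
    the three genotypes and cancels in the normalisation.
    """
    eps = max(error_rate, 1e-12)  # keep logs finite at error_rate = 0
    p_alt = np.array([eps, 0.5, 1.0 - eps])
    d = depth[..., None].astype(float)
    r = alt_reads[..., None].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = r * np.log(p_alt) + (d - r) * np.log1p(-p_alt)
    loglik = loglik - loglik.max(axis=-1, keepdims=True)
    lk = np.exp(loglik)
    lk[depth == 0] = 1.0
    return lk


def simulate_metapopulation(
    params: SimulationParams,
) -> tuple[GenotypeLikelihoodSet, pd.DataFrame, TruthRecord]:
    """Simulate a K-population metapopulation with genotype likelihoods.

    Returns the genotype-likelihood set over all sites (variant and
    invariant), a per-individual sample table with population labels and
    locality coordinates, and the :class:`TruthRecord`.
    """
    rng = np.random.default_rng(params.seed)
    K = params.n_populations
    N = params.n_samples
    L = params.n_total_sites

    sites = _place_sites(rng, params.n_scaffolds, params.scaffold_length, L)

    variant_mask = np.zeros(L, dtype=bool)
    variant_mask[rng.choice(L, size=params.n_variant_sites, replace=False)] = True

    # Balding–Nichols population frequencies around a truncated-Beta ancestral
    # frequency; invariant sites are fixed for the reference allele everywhere.
    a, b = params.ancestral_freq_beta
    anc = rng.beta(a, b, size=L)
    anc = np.clip(anc, 0.02, 0.98)
    p = np.zeros((K, L))
    for k, F in enumerate(params.fst_per_population):
        lam = (1.0 - F) / F
        p[k] = rng.beta(anc * lam, (1.0 - anc) * lam)
    p[:, ~variant_mask] = 0.0

    # Individual ancestries
    pop_of = np.repeat(np.arange(K), params.samples_per_population)
    if params.admixture_alpha == 0.0:
        q = np.zeros((N, K))
        q[np.arange(N), pop_of] = 1.0
    else:
        q = rng.dirichlet(np.full(K, params.admixture_alpha), size=N)

    w = q @ p  # N x L individual allele frequencies
    genotypes = rng.binomial(2, w)

    depth = rng.poisson(params.mean_depth, size=(N, L))
    eps = params.error_rate
    p_alt_read = np.array([eps, 0.5, 1.0 - eps])[genotypes]
    alt_reads = rng.binomial(depth, p_alt_read)
    likelihoods = _reads_to_likelihoods(depth, alt_reads, eps)

    gl = GenotypeLikelihoodSet(
        sample_ids=[f"ind_{i:04d}" for i in range(N)],
        sites=sites,
        likelihoods=likelihoods,
        depths=depth,
    )

    # Locality per population: a compact grid of plausible montane coordinates.
    lat0, lon0 = 39.0, -115.0
    pop_lat = lat0 + 0.6 * np.arange(K) + rng.normal(0, 0.05, K)
    pop_lon = lon0 - 0.4 * np.arange(K) + rng.normal(0, 0.05, K)
    pop_elev = rng.uniform(2000.0, 3500.0, K).round(0)
    samples = pd.DataFrame(
        {
            "sample_id": gl.sample_ids,
            "population": [f"pop_{k}" for k in pop_of],
            "latitude": pop_lat[pop_of],
            "longitude": pop_lon[pop_of],
            "elevation_m": pop_elev[pop_of],
        }
    )

    truth = TruthRecord(true_q=q, true_p=p, true_genotypes=genotypes,
                        variant_mask=variant_mask)
    return gl, samples, truth


def simulate_sfs_sites(
    n_individuals: int,
    allele_counts: np.ndarray,
    positions: np.ndarray | None = None,
    scaffold: str = "scaffold_0",
    mean_depth: float = 20.0,
    error_rate: float = 0.001,
    seed: int = 0,
) -> tuple[GenotypeLikelihoodSet, np.ndarray]:
    """Simulate one population's genotype likelihoods from fixed allele counts.

    ``allele_counts[l]`` is the number of alternate alleles among the
    ``n = 2 * n_individuals`` chromosomes at site l; the alleles are assigned
    to chromosomes uniformly at random (exact hypergeometric sampling) and
    chromosomes are paired into diploid genotypes.  Reads then follow the same
    Poisson-depth binomial-error model as the metapopulation simulator.

    Handy for spectrum-shape experiments: drawing counts with probability
    proportional to 1/j gives the neutral infinite-sites expectation, while
    excluding rare counts emulates a bottleneck-like spectrum.

    Returns the genotype-likelihood set and the true N x L genotype matrix.
    """
    rng = np.random.default_rng(seed)
    allele_counts = np.asarray(allele_counts, dtype=int)
    L = len(allele_counts)
    n_chrom = 2 * n_individuals
    if np.any((allele_counts < 0) | (allele_counts > n_chrom)):
        raise ValueError("allele counts out of range 0..2*n_individuals")
    if positions is None:
        positions = np.sort(rng.choice(10_000_000, size=L, replace=False)) + 1
    positions = np.asarray(positions)
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    allele_counts = allele_counts[order]

    genotypes = np.zeros((n_individuals, L), dtype=int)
    for l, j in enumerate(allele_counts):
        chroms = np.zeros(n_chrom, dtype=int)
        chroms[rng.choice(n_chrom, size=j, replace=False)] = 1
        genotypes[:, l] = chroms[0::2] + chroms[1::2]

    depth = rng.poisson(mean_depth, size=(n_individuals, L))
    eps = error_rate
    p_alt_read = np.array([eps, 0.5, 1.0 - eps])[genotypes]
    alt_reads = rng.binomial(depth, p_alt_read)
    likelihoods = _reads_to_likelihoods(depth, alt_reads, eps)

    ref = _NUC[rng.integers(0, 4, size=L)]
    alt = _NUC[(np.searchsorted(_NUC, ref) + rng.integers(1, 4, size=L)) % 4]
    sites = pd.DataFrame(
        {"scaffold": scaffold, "pos": positions, "ref": ref, "alt": alt}
    )
    gl = GenotypeLikelihoodSet(
        sample_ids=[f"ind_{i:04d}" for i in range(n_individuals)],
        sites=sites,
        likelihoods=likelihoods,
        depths=depth,
    )
    return gl, genotypes


def simulate_climate_geography(
    params: ClimateGeographyParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate sampling localities and their 19 bioclim-style variables.

    Temperature-family variables (bio1..bio11) decrease linearly with
    elevation at the lapse rate; precipitation/seasonality variables
    (bio12..bio19) follow a smooth gradient across the lat/lon plane.  With
    ``noise_sd = 0`` each temperature variable correlates exactly -1 with
    elevation.
    """
    rng = np.random.default_rng(params.seed)
    m = params.n_sites
    lat = 38.0 + rng.uniform(0.0, 3.0, m)
    lon = -119.0 + rng.uniform(0.0, 4.0, m)
    elev = rng.uniform(*params.elevation_range, m).round(0)

    samples = pd.DataFrame(
        {
            "sample_id": [f"site_{i:02d}" for i in range(m)],
            "population": [f"site_{i:02d}" for i in range(m)],
            "latitude": lat,
            "longitude": lon,
            "elevation_m": elev,
        }
    )

    # Smooth spatial gradient for the precipitation block: projection of the
    # locality onto a fixed direction, in km-ish units.
    km_lat = 111.195
    theta = rng.uniform(0, 2 * np.pi)
    grad = (
        (lat - lat.mean()) * km_lat * np.cos(theta)
        + (lon - lon.mean()) * km_lat * np.cos(np.radians(lat.mean())) * np.sin(theta)
    ) / params.precip_spatial_scale

    clim = {"population": samples["population"]}
    for idx, var in enumerate(TEMPERATURE_VARIABLES):
        base = 25.0 - 1.5 * idx
        sens = 1.0 + 0.1 * idx  # each variable its own lapse sensitivity
        clim[var] = (
            base
            - sens * params.temp_lapse_rate * elev / 1000.0
            + rng.normal(0, params.noise_sd, m)
        )
    for idx, var in enumerate(PRECIPITATION_VARIABLES):
        base = 400.0 + 50.0 * idx
        sens = 30.0 * (1.0 + 0.2 * idx)
        clim[var] = base + sens * grad + rng.normal(0, params.noise_sd, m)
    climate = pd.DataFrame(clim)[["population", *CLIMATE_VARIABLES]]
    return samples, climate
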