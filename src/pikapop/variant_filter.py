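"""Post-calling SNP filters for genotype-likelihood data.

The analysis-ready SNP panel is produced by three successive site filters,
mirroring the standard reduced-representation recipe:

1. completeness — keep a site when at least a fraction of individuals have at
   least one read there (ceil rounding: the count must meet or exceed the
   fraction of N);
2. minor allele frequency — estimated by maximum likelihood from the genotype
   likelihoods under Hardy–Weinberg (EM), sites with MAF strictly below the
   threshold are removed;
3. positional thinning — one SNP retained uniformly at random per fixed
   1000-bp block of each scaffold, to reduce linkage between retained loci.

Each stage's attrition is recorded in a :class:`FilterReport` whose counts
telescope (output of one stage is input of the next).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import GenotypeLikelihoodSet

__all__ = [
    "FilterConfig",
    "FilterReport",
    "required_complete_count",
    "completeness_filter",
    "estimate_allele_freq_em",
    "allele_freqs_em",
    "maf_filter",
    "thin_sites",
    "apply_filters",
]


@dataclass
class FilterConfig:
    completeness_min: float = 0.92
    maf_min: float = 0.05
    thin_block: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.completeness_min <= 1.0):
            raise ValueError("completeness_min must lie in (0, 1]")
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0, 0.5)")
        if self.thin_block < 1:
            raise ValueError("thin_block must be >= 1")


@dataclass
class FilterReport:
    """Per-stage site attrition; stage rows telescope."""

    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int) -> None:
        if self.stages and self.stages[-1]["sites_out"] != n_in:
            raise ValueError("stage counts do not telescope")
        self.stages.append(
            {"stage": stage, "sites_in": n_in, "sites_removed": n_in - n_out, "sites_out": n_out}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "sites_in", "sites_removed", "sites_out"])


def required_complete_count(threshold: float, n_samples: int) -> int:
    """Minimum number of covered individuals a site needs (ceil of the fraction)."""
    return math.ceil(threshold * n_samples)


def completeness_filter(gl: GenotypeLikelihoodSet, threshold: float = 0.92) -> GenotypeLikelihoodSet:
    """Keep sites where at least ``ceil(threshold * N)`` individuals have a read."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    need = required_complete_count(threshold, gl.n_samples)
    covered = (gl.depths >= 1).sum(axis=0)
    return gl.subset_sites(covered >= need)


def estimate_allele_freq_em(
    likelihoods: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[float, bool]:
    """Maximum-likelihood alternate-allele frequency at one site under HWE.

    ``likelihoods`` is N x 3 (hom-ref, het, hom-alt).  EM iterates
    ``f' = sum_i E[g_i | f] / 2N``.  Returns ``(f, informative)``; when every
    individual's likelihood triple is flat the site carries no information and
    ``(0.5, False)`` is returned.
    """
    lk = np.asarray(likelihoods, dtype=float)
    flat = np.allclose(lk, lk[:, :1])
    if flat:
        return 0.5, False
    f = 0.5
    n2 = 2.0 * lk.shape[0]
    for _ in range(max_iter):
        prior = np.array([(1 - f) ** 2, 2 * f * (1 - f), f * f])
        post = lk * prior
        post /= post.sum(axis=1, keepdims=True)
        f_new = float((post[:, 1] + 2.0 * post[:, 2]).sum() / n2)
        if abs(f_new - f) < tol:
            f = f_new
            break
        f = f_new
    return f, True


def allele_freqs_em(gl: GenotypeLikelihoodSet, **kwargs) -> np.ndarray:
    """EM allele frequency at every site (vectorised across sites).

    Same fixed point as :func:`estimate_allele_freq_em`, run in parallel over
    the L sites.  Flat (all-individuals uninformative) sites yield 0.5.
    """
    tol = kwargs.get("tol", 1e-8)
    max_iter = kwargs.get("max_iter", 200)
    lk = gl.likelihoods  # N x L x 3
    f = np.full(gl.n_sites, 0.5)
    active = ~np.all(
        np.isclose(lk, lk[:, :, :1]).all(axis=2), axis=0
    )  # sites with at least one informative individual
    n2 = 2.0 * gl.n_samples
    fa = f[active]
    sub = lk[:, active, :]
    for _ in range(max_iter):
        prior = np.stack([(1 - fa) ** 2, 2 * fa * (1 - fa), fa * fa], axis=-1)
        post = sub * prior[None, :, :]
        post /= post.sum(axis=2, keepdims=True)
        f_new = (post[:, :, 1] + 2.0 * post[:, :, 2]).sum(axis=0) / n2
        if np.max(np.abs(f_new - fa), initial=0.0) < tol:
            fa = f_new
            break
        fa = f_new
    f[active] = fa
    return f


def maf_filter(gl: GenotypeLikelihoodSet, maf_min: float = 0.05) -> GenotypeLikelihoodSet:
    """Remove sites whose minor allele frequency is strictly below ``maf_min``.

    The boundary is kept: the rule excludes frequencies *less than* the
    threshold.
    """
    f = allele_freqs_em(gl)
    maf = np.minimum(f, 1.0 - f)
    return gl.subset_sites(maf >= maf_min)


def thin_sites(gl: GenotypeLikelihoodSet, block_bp: int = 1000, seed: int = 0) -> GenotypeLikelihoodSet:
    """Retain one site uniformly at random per fixed ``block_bp`` genomic block.

    Scaffolds are partitioned into half-open blocks [0, B), [B, 2B), ... of
    ``block_bp`` bp (positions are 1-based, so position p falls in block
    ``(p - 1) // B``); every non-empty block contributes exactly one site.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    keep = np.zeros(gl.n_sites, dtype=bool)
    sites = gl.sites
    block = (sites["pos"].to_numpy() - 1) // block_bp
    key = pd.DataFrame({"scaffold": sites["scaffold"], "block": block})
    for _, idx in key.groupby(["scaffold", "block"], sort=False).indices.items():
        keep[rng.choice(idx)] = True
    return gl.subset_sites(keep)


def apply_filters(
    gl: GenotypeLikelihoodSet,
    config: FilterConfig,
    n_multiallelic_skipped: int = 0,
) -> tuple[GenotypeLikelihoodSet, FilterReport]:
    """Run completeness, MAF and thinning in order, recording attrition.

    ``n_multiallelic_skipped`` — records dropped at VCF ingestion for having
    more than one alternate allele — is folded into a leading "biallelic"
    stage so the report covers the whole panel-construction funnel.
    """
    report = FilterReport()
    n0 = gl.n_sites
    report.add("biallelic", n0 + n_multiallelic_skipped, n0)
    out = completeness_filter(gl, config.completeness_min)
    report.add("completeness", n0, out.n_sites)
    n1 = out.n_sites
    out = maf_filter(out, config.maf_min)
    report.add("maf", n1, out.n_sites)
    n2 = out.n_sites
    out = thin_sites(out, config.thin_block, config.seed)
    report.add("thinning", n2, out.n_sites)
    return out, report
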