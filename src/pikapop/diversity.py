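"""Genotype-likelihood diversity estimation per population.

The estimation chain follows the empirical-Bayes site-frequency-spectrum
approach used for low-coverage data:

1. **Site allele-frequency (SAF) likelihoods** — for each site,
   ``P(reads | j alternate alleles among the n = 2 * n_ind chromosomes)`` for
   j = 0..n, computed by a dynamic program that convolves per-individual
   genotype likelihoods with the hypergeometric probability of partitioning j
   alleles into diploid genotypes.
2. **Folded SFS** — maximum-likelihood minor-allele-count spectrum across
   sites, by EM over the folded SAF.
3. **Per-site expectations** — with the fitted spectrum as an empirical-Bayes
   prior, each site's posterior over allele counts yields its expected
   contribution to nucleotide diversity (pi, the mean pairwise difference
   weight j(n-j)/C(n,2)) and to Watterson's theta (probability the site
   segregates, divided by the harmonic number a1).
4. **Windowed Tajima's D** — contributions summed over non-overlapping
   genomic windows (50 kbp by default) and normalised by Tajima's variance
   approximation, with the implied segregating-site count ``S = a1 * S_theta``.

Diversity is estimated on all covered sites (variant and invariant); the
MAF-filtered SNP panel is *not* used here, because removing rare alleles
would bias the spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_core import GenotypeLikelihoodSet

logger = logging.getLogger("pikapop")

__all__ = [
    "compute_saf",
    "fold_saf",
    "estimate_folded_sfs",
    "per_site_thetas",
    "tajima_constants",
    "TajimaConstants",
    "windowed_tajima",
    "population_diversity",
]


def compute_saf(gl: GenotypeLikelihoodSet) -> np.ndarray:
    """Site allele-frequency likelihoods for one population.

    Returns an ``(L, n+1)`` array, ``n = 2 * n_ind``; entry (l, j) is
    proportional to P(reads at site l | j alternate alleles among the n
    chromosomes), max-normalised per site.

    The dynamic program processes individuals one at a time:
    ``Q_m(j) = sum_g GL_m(g) * C(2, g) * Q_{m-1}(j - g)`` with ``Q_0(0) = 1``;
    dividing ``Q_n(j)`` by ``C(n, j)`` (Vandermonde) gives the hypergeometric
    average over genotype configurations carrying j alleles in total.
    """
    n_ind, L = gl.n_samples, gl.n_sites
    if n_ind < 2:
        raise ValueError("SAF requires at least two individuals")
    n = 2 * n_ind
    lk = gl.likelihoods  # N x L x 3
    Q = np.zeros((L, n + 1))
    Q[:, 0] = 1.0
    coef = np.array([1.0, 2.0, 1.0])  # C(2, g)
    for m in range(n_ind):
        glm = lk[m] * coef  # L x 3
        upto = 2 * m  # current max allele count
        newQ = np.zeros_like(Q)
        newQ[:, : upto + 1] += glm[:, :1] * Q[:, : upto + 1]
        newQ[:, 1 : upto + 2] += glm[:, 1:2] * Q[:, : upto + 1]
        newQ[:, 2 : upto + 3] += glm[:, 2:3] * Q[:, : upto + 1]
        Q = newQ
        Q /= Q.max(axis=1, keepdims=True)  # guard against underflow
    j = np.arange(n + 1)
    log_binom = gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)
    saf = Q * np.exp(-log_binom)
    saf /= saf.max(axis=1, keepdims=True)
    return saf


def fold_saf(saf: np.ndarray) -> np.ndarray:
    """Fold SAF over the minor-allele count: class j pools counts j and n-j."""
    saf = np.asarray(saf, dtype=float)
    n = saf.shape[1] - 1
    half = n // 2
    folded = saf[:, : half + 1].copy()
    for j in range(half + 1):
        if n - j != j:
            folded[:, j] += saf[:, n - j]
    return folded


def estimate_folded_sfs(
    saf: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> np.ndarray:
    """Maximum-likelihood folded SFS across sites by EM.

    ``saf`` is the unfolded ``(L, n+1)`` array from :func:`compute_saf`.
    Returns spectrum probabilities phi of length ``n//2 + 1`` maximising
    ``sum_sites log sum_j phi_j * SAF_fold(site, j)``.
    """
    saf = np.asarray(saf, dtype=float)
    if saf.shape[0] == 0:
        raise ValueError("no sites")
    if saf.shape[0] < 100:
        logger.warning("estimate_folded_sfs: only %d sites; spectrum will be noisy", saf.shape[0])
    folded = fold_saf(saf)
    L, m = folded.shape
    phi = np.full(m, 1.0 / m)
    for _ in range(max_iter):
        w = folded * phi
        w /= w.sum(axis=1, keepdims=True)
        phi_new = w.mean(axis=0)
        if np.max(np.abs(phi_new - phi)) < tol:
            phi = phi_new
            break
        phi = phi_new
    return phi


def per_site_thetas(
    saf: np.ndarray,
    sfs_prior: np.ndarray,
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Posterior expected per-site contributions to pi and Watterson's theta.

    The posterior over folded allele-count classes at each site is
    ``post(j) propto phi_j * SAF_fold(j)``.  The pi weight ``j(n-j)/C(n,2)``
    is symmetric under folding, so it applies directly to the folded
    posterior; the theta_W contribution is the posterior probability the site
    segregates divided by ``a1 = sum_{i<n} 1/i``.
    """
    saf = np.asarray(saf, dtype=float)
    n = saf.shape[1] - 1
    folded = fold_saf(saf)
    phi = np.asarray(sfs_prior, dtype=float)
    if phi.shape[0] != folded.shape[1]:
        raise ValueError(
            f"SFS prior length {phi.shape[0]} does not match folded SAF classes {folded.shape[1]}"
        )
    post = folded * phi
    post /= post.sum(axis=1, keepdims=True)
    j = np.arange(folded.shape[1])
    w_pi = j * (n - j) / (n * (n - 1) / 2.0)
    a1 = float(np.sum(1.0 / np.arange(1, n)))
    pi = post @ w_pi
    theta_w = (1.0 - post[:, 0]) / a1
    out = pd.DataFrame({"pi": pi, "theta_w": theta_w})
    if sites is not None:
        out.insert(0, "pos", sites["pos"].to_numpy())
        out.insert(0, "scaffold", sites["scaffold"].to_numpy())
    return out


class TajimaConstants(NamedTuple):
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """The classical normalising constants of Tajima's D for n chromosomes."""
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


def windowed_tajima(
    track: pd.DataFrame,
    n: int,
    window_bp: int = 50_000,
) -> tuple[pd.DataFrame, float]:
    """Tajima's D in non-overlapping genomic windows.

    ``track`` must carry scaffold, pos, pi and theta_w columns (from
    :func:`per_site_thetas`).  Per window, ``S_pi`` and ``S_theta`` are the
    summed contributions, the implied segregating-site count is
    ``S = a1 * S_theta`` and
    ``D = (S_pi - S_theta) / sqrt(e1*S + e2*S*(S-1))``.
    Windows with no expected segregating sites emit no value; a non-positive
    variance term skips the window with a log entry.  Returns the per-window
    table and the mean D over emitted windows.
    """
    const = tajima_constants(n)
    blocks = (track["pos"].to_numpy() - 1) // window_bp
    rows = []
    grouped = track.assign(_block=blocks).groupby(["scaffold", "_block"], sort=True)
    for (scaf, blk), grp in grouped:
        s_pi = float(grp["pi"].sum())
        s_th = float(grp["theta_w"].sum())
        S = const.a1 * s_th
        if S <= 0:
            continue
        var = const.e1 * S + const.e2 * S * (S - 1.0)
        if var <= 0:
            logger.info("windowed_tajima: non-positive variance in %s block %d; skipped", scaf, blk)
            continue
        d = (s_pi - s_th) / np.sqrt(var)
        rows.append(
            {
                "scaffold": scaf,
                "start": int(blk * window_bp),
                "end": int((blk + 1) * window_bp),
                "n_sites": len(grp),
                "s_pi": s_pi,
                "s_theta": s_th,
                "tajima_d": d,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["scaffold", "start", "end", "n_sites", "s_pi", "s_theta", "tajima_d"],
    )
    mean_d = float(table["tajima_d"].mean()) if len(table) else float("nan")
    return table, mean_d


@dataclass
class DiversitySummary:
    population: str
    n_individuals: int
    n_sites: int
    pi: float  # sites-weighted mean per-site nucleotide diversity
    theta_w: float  # sites-weighted mean per-site Watterson's theta
    mean_tajima_d: float
    n_windows: int


def population_diversity(
    gl: GenotypeLikelihoodSet,
    population: str = "pop",
    window_bp: int = 50_000,
) -> tuple[DiversitySummary, pd.DataFrame, np.ndarray]:
    """Full diversity chain for one population's genotype-likelihood data.

    Returns the summary, the per-window Tajima table and the folded SFS.
    Per-site means divide total contributions by the total number of sites
    with data (variant and invariant alike).
    """
    saf = compute_saf(gl)
    phi = estimate_folded_sfs(saf)
    track = per_site_thetas(saf, phi, sites=gl.sites)
    n = 2 * gl.n_samples
    windows, mean_d = windowed_tajima(track, n=n, window_bp=window_bp)
    summary = DiversitySummary(
        population=population,
        n_individuals=gl.n_samples,
        n_sites=gl.n_sites,
        pi=float(track["pi"].sum() / len(track)),
        theta_w=float(track["theta_w"].sum() / len(track)),
        mean_tajima_d=mean_d,
        n_windows=len(windows),
    )
    return summary, windows, phi
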