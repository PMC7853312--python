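"""Hierarchical Bayesian admixture from genotype likelihoods.

The model jointly infers individual ancestry coefficients ``q`` and cluster
allele frequencies ``p`` while carrying genotype uncertainty through the
analysis: genotypes are latent, informed by the genotype likelihoods, so
low-coverage individuals contribute what their reads support and no more.

Model (k clusters, N diploids, L biallelic sites):

* each of the two allele copies at (i, l) draws an ancestry
  ``z ~ Categorical(q_i)`` and then an allele ``~ Bernoulli(p_{z,l})``;
* priors ``q_i ~ Dirichlet(1, ..., 1)`` and ``p_{k,l} ~ Beta(1, 1)``;
* the read data enter through the genotype likelihoods ``GL_il(g)``.

Inference is Gibbs sampling: sample the genotype from GL times its
admixture-HWE prior, sample the two copies' ancestries, then conjugate
Beta/Dirichlet updates for ``p`` and ``q``.  The number of clusters is chosen
by the Deviance Information Criterion with genotypes marginalised out of the
deviance.  This is a deliberately lean re-implementation of the
entropy-style model: no free sequencing-error parameter and no
within-cluster inbreeding coefficient, which the downstream analyses (q,
genotype posteriors, DIC over k) do not require.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import GenotypeLikelihoodSet

logger = logging.getLogger("pikapop")

__all__ = [
    "McmcSettings",
    "AncestryFit",
    "init_ancestry",
    "gibbs_admixture",
    "deviance",
    "compute_dic",
    "select_k",
]


@dataclass
class McmcSettings:
    """MCMC chain settings; defaults are full production-length chains."""

    n_steps: int = 40_000
    burn_in: int = 10_000
    thin: int = 10
    n_chains: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_steps:
            raise ValueError("burn_in must be < n_steps")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


@dataclass
class AncestryFit:
    """Posterior summary of one admixture model."""

    k: int
    q: np.ndarray  # N x k posterior-mean ancestry coefficients
    p: np.ndarray  # k x L posterior-mean cluster allele frequencies
    genotype_posterior: np.ndarray  # N x L x 3
    dosage: np.ndarray  # N x L posterior-mean genotype
    dic: float
    p_d: float
    mean_deviance: float
    deviance_samples: np.ndarray = field(repr=False, default=None)


def _naive_dosage(gl: GenotypeLikelihoodSet) -> np.ndarray:
    """Posterior-mean genotype under a flat genotype prior."""
    post = gl.normalized()
    return post[:, :, 1] + 2.0 * post[:, :, 2]


def init_ancestry(gl: GenotypeLikelihoodSet, k: int, seed: int = 0) -> np.ndarray:
    """Initial ancestry coefficients from k-means + LDA on PC scores.

    Naive flat-prior dosages are projected onto their leading principal
    components; k-means labels the individuals; linear discriminant analysis
    on those labels yields per-individual class posterior probabilities, which
    are floored at 0.001 and renormalised.  For ``k = 1`` the trivial
    all-ones vector is returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = gl.n_samples
    if k > n:
        raise ValueError(f"k={k} exceeds the number of individuals ({n})")
    if k == 1:
        return np.ones((n, 1))

    from sklearn.cluster import KMeans
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    dosage = _naive_dosage(gl)
    centered = dosage - dosage.mean(axis=0)
    n_comp = max(2, min(10, n - 1, gl.n_sites))
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :n_comp] * s[:n_comp]

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(scores)
    q = np.full((n, k), 1.0 / k)
    if len(np.unique(labels)) == k:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lda = LinearDiscriminantAnalysis()
                lda.fit(scores, labels)
                proba = lda.predict_proba(scores)
            q = np.zeros((n, k))
            q[:, lda.classes_] = proba
        except Exception:  # collinear scores: fall back to hard labels
            q = np.zeros((n, k))
            q[np.arange(n), labels] = 1.0
    else:
        logger.warning("init_ancestry: k-means produced < k clusters; flat init")
        q = np.zeros((n, k))
        q[np.arange(n), labels] = 1.0
    q = np.maximum(q, 0.001)
    q /= q.sum(axis=1, keepdims=True)
    return q


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Sample along the last axis of an unnormalised probability array."""
    c = probs.cumsum(axis=-1)
    u = rng.random(probs.shape[:-1] + (1,)) * c[..., -1:]
    return (u > c).sum(axis=-1)


def deviance(gl: GenotypeLikelihoodSet, q: np.ndarray, p: np.ndarray) -> float:
    """-2 log L(data | q, p) with latent genotypes marginalised out."""
    w = q @ p  # N x L
    prior = np.stack([(1 - w) ** 2, 2 * w * (1 - w), w * w], axis=-1)
    lik = (gl.likelihoods * prior).sum(axis=2)
    if np.any(lik <= 0) or not np.all(np.isfinite(lik)):
        bad = np.argwhere((lik <= 0) | ~np.isfinite(lik))
        i, l = bad[0]
        raise ValueError(
            f"non-finite marginal likelihood at individual {gl.sample_ids[i]}, "
            f"site {gl.sites.at[int(l), 'scaffold']}:{gl.sites.at[int(l), 'pos']}"
        )
    return float(-2.0 * np.log(lik).sum())


def _run_chain(
    gl: GenotypeLikelihoodSet,
    k: int,
    settings: McmcSettings,
    q_init: np.ndarray,
    seed: int,
) -> dict:
    rng = np.random.default_rng(seed)
    N, L = gl.n_samples, gl.n_sites
    lk = gl.likelihoods

    q = q_init.copy()
    # initialise p from dosage-weighted per-cluster frequencies
    dosage = _naive_dosage(gl)
    denom = q.sum(axis=0)[:, None]
    p = np.clip((q.T @ dosage) / (2.0 * denom), 0.01, 0.99)

    n_retained = (settings.n_steps - settings.burn_in) // settings.thin
    dev_samples = np.empty(n_retained, dtype=float)
    q_acc = np.zeros_like(q)
    p_acc = np.zeros_like(p)
    gpost_acc = np.zeros((N, L, 3))
    r = 0

    for step in range(settings.n_steps):
        w = q @ p
        prior = np.stack([(1 - w) ** 2, 2 * w * (1 - w), w * w], axis=-1)
        gprobs = lk * prior  # N x L x 3
        g = _sample_categorical(rng, gprobs)

        # copy alleles: one alt copy for hets, two for hom-alt
        a1 = g >= 1
        a2 = g == 2

        # copy ancestries given alleles
        pT = p.T[None, :, :]  # 1 x L x k
        qE = q[:, None, :]  # N x 1 x k
        w1 = qE * np.where(a1[:, :, None], pT, 1.0 - pT)
        z1 = _sample_categorical(rng, w1)
        w2 = qE * np.where(a2[:, :, None], pT, 1.0 - pT)
        z2 = _sample_categorical(rng, w2)

        # conjugate updates
        alt_kl = np.empty((k, L))
        tot_kl = np.empty((k, L))
        m_ik = np.empty((N, k))
        for kk in range(k):
            m1 = z1 == kk
            m2 = z2 == kk
            alt_kl[kk] = (m1 & a1).sum(axis=0) + (m2 & a2).sum(axis=0)
            tot_kl[kk] = m1.sum(axis=0) + m2.sum(axis=0)
            m_ik[:, kk] = m1.sum(axis=1) + m2.sum(axis=1)
        p = rng.beta(1.0 + alt_kl, 1.0 + tot_kl - alt_kl)
        gam = rng.gamma(1.0 + m_ik)
        q = gam / gam.sum(axis=1, keepdims=True)

        if step >= settings.burn_in and (step - settings.burn_in) % settings.thin == 0:
            dev_samples[r] = deviance(gl, q, p)
            q_acc += q
            p_acc += p
            gpost = gprobs / gprobs.sum(axis=2, keepdims=True)
            gpost_acc += gpost
            r += 1

    return {
        "q": q_acc / r,
        "p": p_acc / r,
        "gpost": gpost_acc / r,
        "deviance": dev_samples[:r],
    }


def _align_clusters(p_ref: np.ndarray, p_other: np.ndarray) -> np.ndarray:
    """Greedy minimal-distance matching of cluster labels between two chains.

    Returns a permutation ``perm`` such that cluster ``perm[j]`` of the other
    chain corresponds to cluster ``j`` of the reference.
    """
    k = p_ref.shape[0]
    d = np.linalg.norm(p_ref[:, None, :] - p_other[None, :, :], axis=2)
    perm = np.full(k, -1)
    used = np.zeros(k, dtype=bool)
    for _ in range(k):
        masked = np.where(used[None, :] | (perm != -1)[:, None], np.inf, d)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        perm[i] = j
        used[j] = True
    return perm


def gibbs_admixture(
    gl: GenotypeLikelihoodSet,
    k: int,
    settings: McmcSettings | None = None,
    q_init: np.ndarray | None = None,
) -> AncestryFit:
    """Fit the k-cluster admixture model by Gibbs sampling.

    Runs ``settings.n_chains`` replicate chains from the k-means/LDA
    initialisation, resolves label switching across chains by greedily
    matching posterior-mean allele-frequency vectors, and averages the
    aligned chains.  DIC is computed from the pooled retained deviance
    samples and the deviance at the aligned posterior mean.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if settings is None:
        settings = McmcSettings()
    if q_init is None:
        q_init = init_ancestry(gl, k, seed=settings.seed)

    ss = np.random.SeedSequence(settings.seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(settings.n_chains)]
    chains = [
        _run_chain(gl, k, settings, q_init, seed) for seed in chain_seeds
    ]

    ref = chains[0]
    q_sum, p_sum = ref["q"].copy(), ref["p"].copy()
    for ch in chains[1:]:
        perm = _align_clusters(ref["p"], ch["p"])
        q_sum += ch["q"][:, perm]
        p_sum += ch["p"][perm, :]
    q_mean = q_sum / len(chains)
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    p_mean = p_sum / len(chains)
    gpost = np.mean([ch["gpost"] for ch in chains], axis=0)
    dosage = gpost[:, :, 1] + 2.0 * gpost[:, :, 2]

    dev_samples = np.concatenate([ch["deviance"] for ch in chains])
    dic, p_d, mean_dev = compute_dic(dev_samples, deviance(gl, q_mean, p_mean))
    return AncestryFit(
        k=k,
        q=q_mean,
        p=p_mean,
        genotype_posterior=gpost,
        dosage=dosage,
        dic=dic,
        p_d=p_d,
        mean_deviance=mean_dev,
        deviance_samples=dev_samples,
    )


def compute_dic(
    deviance_samples: np.ndarray, deviance_at_mean: float
) -> tuple[float, float, float]:
    """Deviance Information Criterion from retained deviance samples.

    ``DIC = mean(D) + p_D`` with ``p_D = mean(D) - D(posterior mean)``.
    Returns ``(dic, p_d, mean_deviance)``.  A negative ``p_D`` (poorly
    identified model) is reported with a warning, not an error.
    """
    deviance_samples = np.asarray(deviance_samples, dtype=float)
    if deviance_samples.size == 0:
        raise ValueError("no retained deviance samples")
    if deviance_samples.size < 30:
        logger.warning("compute_dic: only %d retained samples", deviance_samples.size)
    d_bar = float(deviance_samples.mean())
    p_d = d_bar - float(deviance_at_mean)
    if p_d < 0:
        logger.warning("compute_dic: negative p_D (%.3f)", p_d)
    return d_bar + p_d, p_d, d_bar


def select_k(fits: dict[int, AncestryFit]) -> tuple[int, pd.DataFrame]:
    """Choose the cluster count with minimal DIC (smallest k wins ties)."""
    if not fits:
        raise ValueError("no fits supplied")
    table = pd.DataFrame(
        [
            {"k": k, "dic": f.dic, "p_d": f.p_d, "mean_deviance": f.mean_deviance}
            for k, f in sorted(fits.items())
        ]
    )
    best_dic = table["dic"].min()
    winners = table.loc[table["dic"] == best_dic, "k"]
    if len(winners) > 1:
        logger.info("select_k: DIC tie among k=%s; returning smallest", list(winners))
    return int(winners.iloc[0]), table
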