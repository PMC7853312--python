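"""Summaries of spatial genetic structure: PCA and Nei's genetic distance.

PCA runs on the posterior-mean genotype dosages (N individuals x L sites),
columns centred but not scaled — the dosages share units, so scaling would
only up-weight rare variants.  Nei's (1972) standard genetic distance is
computed between populations from their allele-frequency vectors:

    D = -ln I,  I = J_xy / sqrt(J_x J_y)

with J_x, J_y the mean within-population gene identities and J_xy the mean
between-population identity over biallelic loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PcaResult", "NeiDMatrix", "run_pca", "pop_allele_freqs", "nei_distance"]


@dataclass
class PcaResult:
    scores: np.ndarray  # N x C
    proportion_variance: np.ndarray  # length C
    loadings: np.ndarray  # L x C


@dataclass
class NeiDMatrix:
    populations: list[str]
    D: np.ndarray  # symmetric, zero diagonal; np.inf where identity is zero

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.populations, columns=self.populations)

    def to_phylip(self) -> str:
        """PHYLIP-style square distance matrix (for external tree builders)."""
        lines = [f"{len(self.populations)}"]
        for name, row in zip(self.populations, self.D):
            label = name[:10].ljust(10)
            lines.append(label + "  " + "  ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def run_pca(dosage: np.ndarray, n_components: int | None = None) -> PcaResult:
    """PCA of a complete dosage matrix: centred, unscaled, covariance-based.

    Sign convention: within each component the loading of largest magnitude
    is made positive, so results are reproducible across linear-algebra
    backends.
    """
    X = np.asarray(dosage, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two individuals")
    n, L = X.shape
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    var = s**2 / (n - 1)
    total = var.sum()
    prop = var / total if total > 0 else np.zeros_like(var)
    if n_components is not None:
        u, s, vt, prop = u[:, :n_components], s[:n_components], vt[:n_components], prop[:n_components]
    return PcaResult(scores=u * s, proportion_variance=prop, loadings=vt.T)


def pop_allele_freqs(dosage: np.ndarray, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-population alternate-allele frequencies from mean dosage / 2.

    ``samples`` rows must correspond to dosage rows (sample order).  Returns a
    populations x L DataFrame indexed by population name.
    """
    dosage = np.asarray(dosage, dtype=float)
    if len(samples) != dosage.shape[0]:
        raise ValueError("sample table and dosage matrix disagree on N")
    pops = samples["population"].to_numpy()
    names = list(dict.fromkeys(pops))
    freqs = np.vstack([dosage[pops == name].mean(axis=0) / 2.0 for name in names])
    return pd.DataFrame(freqs, index=names)


def nei_distance(freqs: pd.DataFrame | np.ndarray,
                 populations: list[str] | None = None) -> NeiDMatrix:
    """Nei's standard genetic distance between all population pairs.

    For biallelic loci with alternate-allele frequencies x_l, y_l:
    ``J_x = mean(x^2 + (1-x)^2)``, ``J_xy = mean(x*y + (1-x)*(1-y))``,
    ``D = -ln(J_xy / sqrt(J_x * J_y))``.  Opposite fixation at every locus
    gives ``J_xy = 0`` and ``D = +inf``.
    """
    if isinstance(freqs, pd.DataFrame):
        populations = list(freqs.index)
        F = freqs.to_numpy(dtype=float)
    else:
        F = np.asarray(freqs, dtype=float)
        if populations is None:
            populations = [f"pop_{i}" for i in range(F.shape[0])]
    m = F.shape[0]
    if m < 2:
        raise ValueError("need at least two populations")
    if np.any((F < 0) | (F > 1)):
        raise ValueError("allele frequencies outside [0, 1]")
    J_within = (F**2 + (1 - F) ** 2).mean(axis=1)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            J_xy = float((F[i] * F[j] + (1 - F[i]) * (1 - F[j])).mean())
            if J_xy == 0.0:
                d = np.inf
            else:
                identity = J_xy / np.sqrt(J_within[i] * J_within[j])
                d = -np.log(min(identity, 1.0))
            D[i, j] = D[j, i] = d
    return NeiDMatrix(populations=populations, D=D)
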