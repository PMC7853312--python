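"""Landscape genetics: predictor distance matrices and MRM model comparison.

Four population-level predictors of genetic distance are built — great-circle
(haversine) geographic distance in km, absolute elevational difference in m,
and the absolute score differences on the first two components of a PCA over
19 bioclim-style climate variables ("Climate 1", temperature-dominated, and
"Climate 2", precipitation/seasonality-dominated in typical montane data).

Multiple regression on distance matrices (MRM) regresses the unfolded
strictly-lower triangle of the response matrix on those of the predictors by
OLS; significance comes from jointly permuting rows and columns of the
response matrix and recomputing R-squared.  A model scan fits every non-empty
predictor subset (15 models for 4 predictors) and reports the comparison
table sorted by R-squared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CLIMATE_VARIABLES
from .structure_stats import run_pca

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "DistanceSet",
    "MRMResult",
    "population_midpoints",
    "haversine_matrix",
    "elevation_matrix",
    "climate_pca",
    "climate_distance",
    "build_distance_set",
    "mrm",
    "model_scan",
]


@dataclass
class DistanceSet:
    populations: list[str]
    geographic: np.ndarray  # km
    elevational: np.ndarray  # m
    climate1: np.ndarray
    climate2: np.ndarray
    climate_pca_variance: np.ndarray

    def predictors(self) -> dict[str, np.ndarray]:
        return {
            "Elevation": self.elevational,
            "Geography": self.geographic,
            "Climate 1": self.climate1,
            "Climate 2": self.climate2,
        }


@dataclass
class MRMResult:
    predictors: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    r_squared: float
    p_value: float
    coefficient_p: dict[str, float]
    n_perm: int
    seed: int


def population_midpoints(samples: pd.DataFrame) -> pd.DataFrame:
    """One row per population: mean latitude/longitude/elevation of its samples."""
    agg = (
        samples.groupby("population", sort=False)[["latitude", "longitude", "elevation_m"]]
        .mean()
        .reset_index()
    )
    return agg


def haversine_matrix(localities: pd.DataFrame) -> np.ndarray:
    """Great-circle distance matrix (km) between locality midpoints.

    ``localities`` needs latitude/longitude columns in decimal degrees.
    Uses the haversine formula on a sphere of mean radius 6371 km.
    """
    lat = np.radians(localities["latitude"].to_numpy(dtype=float))
    lon = np.radians(localities["longitude"].to_numpy(dtype=float))
    if np.any(np.abs(localities["latitude"].to_numpy()) > 90):
        raise ValueError("latitude out of range")
    if np.any(np.abs(localities["longitude"].to_numpy()) > 180):
        raise ValueError("longitude out of range")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return d


def elevation_matrix(localities: pd.DataFrame) -> np.ndarray:
    """Absolute elevation difference (m) between localities."""
    e = localities["elevation_m"].to_numpy(dtype=float)
    return np.abs(e[:, None] - e[None, :])


def climate_pca(climate: pd.DataFrame, scale: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the 19 climate variables across localities.

    Variables are centred and, by default, scaled to unit variance (they mix
    units: degrees, millimetres, dimensionless seasonality indices).  Returns
    (scores, variance fractions).
    """
    if len(climate) < 3:
        raise ValueError("climate PCA needs at least 3 localities")
    X = climate[CLIMATE_VARIABLES].to_numpy(dtype=float)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if len(zero):
            names = [CLIMATE_VARIABLES[i] for i in zero]
            raise ValueError(f"constant climate variable(s) with scaling on: {names}")
        X = X / sd
    res = run_pca(X)
    return res.scores, res.proportion_variance


def climate_distance(scores: np.ndarray, component: int) -> np.ndarray:
    """Pairwise absolute difference on one climate PC (0-based index)."""
    s = np.asarray(scores, dtype=float)[:, component]
    return np.abs(s[:, None] - s[None, :])


def build_distance_set(
    samples: pd.DataFrame,
    climate: pd.DataFrame,
    scale_climate: bool = True,
) -> DistanceSet:
    """Assemble the four predictor matrices on a shared population ordering."""
    mids = population_midpoints(samples)
    pops = list(mids["population"])
    clim = climate.set_index("population").loc[pops].reset_index()
    scores, var = climate_pca(clim, scale=scale_climate)
    return DistanceSet(
        populations=pops,
        geographic=haversine_matrix(mids),
        elevational=elevation_matrix(mids),
        climate1=climate_distance(scores, 0),
        climate2=climate_distance(scores, 1),
        climate_pca_variance=var,
    )


def _lower_triangle(mat: np.ndarray) -> np.ndarray:
    m = np.asarray(mat, dtype=float)
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """OLS fit; returns (beta, r_squared, t_statistics). X includes intercept."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    dof = max(len(y) - X.shape[1], 1)
    sigma2 = ss_res / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), np.finfo(float).tiny))
    t = beta / se
    return beta, r2, t


def mrm(
    response: np.ndarray,
    predictors: dict[str, np.ndarray],
    n_perm: int = 999,
    seed: int = 0,
) -> MRMResult:
    """Multiple regression on distance matrices with permutation inference.

    The strictly-lower triangles are unfolded to vectors and regressed by OLS
    with an intercept.  The R-squared p-value comes from ``n_perm`` joint
    row/column permutations of the response matrix:
    ``p = (1 + #{perm R2 >= observed}) / (1 + n_perm)``; per-coefficient
    p-values are analogous on |t|.  Deterministic given the seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    names = list(predictors)
    mats = [np.asarray(predictors[name], dtype=float) for name in names]
    m = np.asarray(response, dtype=float)
    npop = m.shape[0]
    for name, mat in zip(names, mats):
        if mat.shape != (npop, npop):
            raise ValueError(f"predictor {name!r} shape mismatch")
    y = _lower_triangle(m)
    X = np.column_stack([np.ones(len(y))] + [_lower_triangle(mat) for mat in mats])
    try:
        beta, r2_obs, t_obs = _ols(y, X)
    except np.linalg.LinAlgError:
        corr = np.corrcoef(X[:, 1:].T) if X.shape[1] > 2 else None
        raise ValueError(
            f"rank-deficient predictor set {names}; pairwise predictor correlations:\n{corr}"
        )

    rng = np.random.default_rng(seed)
    count_r2 = 0
    count_t = np.zeros(X.shape[1], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(npop)
        y_p = _lower_triangle(m[np.ix_(perm, perm)])
        beta_p, r2_p, t_p = _ols(y_p, X)
        if r2_p >= r2_obs:
            count_r2 += 1
        count_t += np.abs(t_p) >= np.abs(t_obs)
    p_r2 = (1 + count_r2) / (1 + n_perm)
    p_t = (1 + count_t) / (1 + n_perm)
    coef = {"intercept": float(beta[0])}
    coef_p = {"intercept": float(p_t[0])}
    for idx, name in enumerate(names, start=1):
        coef[name] = float(beta[idx])
        coef_p[name] = float(p_t[idx])
    return MRMResult(
        predictors=names,
        coefficients=coef,
        r_squared=float(r2_obs),
        p_value=float(p_r2),
        coefficient_p=coef_p,
        n_perm=n_perm,
        seed=seed,
    )


def model_scan(
    response: np.ndarray,
    predictors: dict[str, np.ndarray],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit every non-empty predictor subset; table sorted by R-squared.

    Columns: model (predictor names joined by " + "), r_squared, p_value.
    """
    names = list(predictors)
    rows = []
    results = {}
    for mask in range(1, 2 ** len(names)):
        subset = [names[i] for i in range(len(names)) if mask >> i & 1]
        res = mrm(response, {s: predictors[s] for s in subset}, n_perm=n_perm, seed=seed)
        results[tuple(subset)] = res
        rows.append(
            {
                "model": " + ".join(subset),
                "n_predictors": len(subset),
                "r_squared": res.r_squared,
                "p_value": res.p_value,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["r_squared", "model"], ascending=[False, True], ignore_index=True
    )
    return table
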