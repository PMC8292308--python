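"""Pairwise distance matrices and the partial Mantel test.

Genetic distance is the linearized F_ST/(1 - F_ST); geographic distance
is the great-circle distance on a sphere of mean radius 6371.0088 km;
environmental distance is the Euclidean norm over 2-SD-standardized,
correlation-pruned bioclim variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .envwindows import standardize_2sd

__all__ = [
    "DistanceMatrix",
    "linearize_fst",
    "geodesic_distance",
    "env_distance",
    "partial_mantel",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape inconsistent with labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have zero diagonal")

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def linearize_fst(fst: pd.DataFrame) -> DistanceMatrix:
    """Elementwise F_ST / (1 - F_ST); requires all theta < 1."""
    v = fst.to_numpy(float).copy()
    np.fill_diagonal(v, 0.0)
    if (v >= 1).any():
        raise ValueError("theta >= 1 cannot be linearized")
    v = np.clip(v, 0.0, None)  # small negative thetas map to distance 0
    out = v / (1.0 - v)
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(list(fst.index), out, kind="genetic")


def geodesic_distance(sites: pd.DataFrame) -> DistanceMatrix:
    """Great-circle (haversine) distances in km; sites: site, lat, lon."""
    lat = np.radians(sites["lat"].to_numpy(float))
    lon = np.radians(sites["lon"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(list(sites["site"].astype(str)), d, kind="geographic")


def env_distance(
    bioclim: pd.DataFrame,
    variables: list[str] | None = None,
    standardize: bool = True,
) -> DistanceMatrix:
    """Euclidean distance over (2-SD standardized) bioclim variables."""
    variables = variables or [c for c in bioclim.columns if c != "site"]
    X = bioclim[variables].to_numpy(float)
    if standardize:
        X = np.column_stack([standardize_2sd(X[:, j]) for j in range(X.shape[1])])
    d = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(list(bioclim["site"].astype(str)), d, kind="environmental")


def _offdiag_residuals(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of M's condensed entries regressed on C's (with intercept)."""
    y = squareform(M, checks=False)
    x = squareform(C, checks=False)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    C: DistanceMatrix,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Partial Mantel test of A vs B controlling for C.

    r is the Pearson correlation of the off-diagonal residuals of A|C
    and B|C.  The null distribution permutes object labels of A (rows
    and columns jointly), re-residualizes, and recomputes r; p is the
    one-sided upper tail with the (exceedances + 1)/(n_perm + 1)
    convention.
    """
    if not (A.labels == B.labels == C.labels):
        raise ValueError("distance matrices must share labels (and order)")
    n = len(A.labels)
    if n < 4:
        raise ValueError("partial Mantel needs >= 4 objects")
    for M in (A, B, C):
        if np.ptp(M.condensed()) == 0:
            raise ValueError(f"constant {M.kind} distance matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rb = _offdiag_residuals(B.values, C.values)
    rb = (rb - rb.mean()) / rb.std()

    def _r(Amat: np.ndarray) -> float:
        ra = _offdiag_residuals(Amat, C.values)
        ra = (ra - ra.mean()) / ra.std()
        return float((ra * rb).mean())

    r_obs = _r(A.values)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if _r(A.values[np.ix_(p, p)]) >= r_obs - 1e-12:
            count += 1
    return {"r": r_obs, "p": (count + 1) / (n_perm + 1), "n": n, "n_perm": n_perm}
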