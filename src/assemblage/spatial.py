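"""Geographic distances and Moran's Eigenvector Maps (dbMEM-style).

MEM construction follows the classical recipe: threshold the pairwise
distance matrix at the largest edge of its minimum spanning tree, replace
every distance beyond the threshold (and the diagonal) by four times the
threshold, run a principal coordinates analysis of the truncated matrix, and
keep the axes with positive eigenvalues.  Because multiple samples can share
one location (several soil cores per site), the MST and the PCoA are computed
on unique locations and the eigenvector scores are broadcast back to the
samples; zero-length edges would otherwise drive the threshold to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .tables import SiteGeometry

__all__ = [
    "pairwise_distances",
    "mst_threshold",
    "truncate_distances",
    "pcoa_mems",
    "build_mems",
    "MEMSet",
]

EARTH_RADIUS_KM = 6371.0


def _haversine_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(
        dlam / 2.0
    ) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def pairwise_distances(geometry: SiteGeometry) -> pd.DataFrame:
    """Pairwise sample distances in km.

    Great-circle (haversine, R = 6371 km) for geographic coordinates,
    Euclidean for projected ones.
    """
    if geometry.n_samples < 2:
        raise ValueError("need at least 2 samples for pairwise distances")
    xy = geometry.coords.to_numpy()
    if geometry.crs == "geographic":
        d = _haversine_matrix(xy[:, 0], xy[:, 1])
    else:
        diff = xy[:, None, :] - xy[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    ids = geometry.sample_ids
    return pd.DataFrame(d, index=ids, columns=ids)


def mst_threshold(D: np.ndarray | pd.DataFrame) -> float:
    """Largest edge weight of a minimum spanning tree of the distance matrix.

    Expects a matrix of unique locations (no zero off-diagonal entries);
    duplicate rows should be collapsed by the caller (see :func:`build_mems`).
    """
    d = np.asarray(D, dtype=float)
    if d.shape[0] < 2:
        raise ValueError("need at least 2 unique locations for an MST threshold")
    mst = minimum_spanning_tree(d).toarray()
    return float(mst.max())


def truncate_distances(D: np.ndarray | pd.DataFrame, threshold: float) -> np.ndarray:
    """Replace distances beyond ``threshold`` and the diagonal by 4x threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    d = np.asarray(D, dtype=float).copy()
    d[d > threshold] = 4.0 * threshold
    np.fill_diagonal(d, 4.0 * threshold)
    return d


@dataclass
class MEMSet:
    """Positive-eigenvalue spatial eigenvectors with their eigenvalues."""

    eigenvectors: pd.DataFrame  # samples x MEM axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # descending, all positive
    threshold_km: float

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def scores(self, n_mems: int | None = None) -> pd.DataFrame:
        """The first ``n_mems`` eigenvectors (all if None)."""
        if n_mems is None:
            return self.eigenvectors
        if n_mems > self.n_axes:
            raise ValueError(
                f"requested {n_mems} MEMs but only {self.n_axes} positive axes exist"
            )
        return self.eigenvectors.iloc[:, :n_mems]


def pcoa_mems(D_star: np.ndarray, threshold_km: float = np.nan) -> MEMSet:
    """PCoA of a truncated distance matrix, keeping positive-eigenvalue axes.

    Gower double-centering of -0.5 * D*^2, symmetric eigendecomposition,
    axes with eigenvalue > 1e-10 x the largest retained, scores scaled by
    sqrt(eigenvalue).  Each eigenvector is oriented so its largest-magnitude
    entry is positive, making the output reproducible across LAPACK builds.
    """
    d = np.asarray(D_star, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("truncated distance matrix must be symmetric")
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-10 * max(eigval.max(), 0.0)
    keep = eigval > tol
    if not keep.any():
        raise ValueError("no positive eigenvalues: degenerate geometry")
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    for j in range(eigvec.shape[1]):
        col = eigvec[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            eigvec[:, j] = -col
    scores = eigvec * np.sqrt(eigval)
    frame = pd.DataFrame(
        scores, columns=[f"MEM{k + 1}" for k in range(scores.shape[1])]
    )
    return MEMSet(eigenvectors=frame, eigenvalues=eigval, threshold_km=threshold_km)


def build_mems(geometry: SiteGeometry) -> MEMSet:
    """Full MEM pipeline on a sample geometry with possible duplicate locations.

    Unique locations are identified, the MST threshold and PCoA are computed
    at the location level, and the scores are broadcast to every sample at
    each location.
    """
    coords = geometry.coords.to_numpy()
    _, uniq_idx, inverse = np.unique(
        coords.round(9), axis=0, return_index=True, return_inverse=True
    )
    uniq_geometry = SiteGeometry(
        coords=geometry.coords.iloc[np.sort(uniq_idx)], crs=geometry.crs
    )
    # np.unique sorts lexically; remap inverse to the original-order unique rows
    sorted_to_original = np.argsort(np.argsort(uniq_idx))
    inverse = sorted_to_original[inverse]

    d_uniq = pairwise_distances(uniq_geometry).to_numpy()
    threshold = mst_threshold(d_uniq)
    d_star = truncate_distances(d_uniq, threshold)
    mems = pcoa_mems(d_star, threshold_km=threshold)
    broadcast = mems.eigenvectors.to_numpy()[inverse]
    frame = pd.DataFrame(
        broadcast, index=geometry.sample_ids, columns=mems.eigenvectors.columns
    )
    return MEMSet(
        eigenvectors=frame, eigenvalues=mems.eigenvalues, threshold_km=threshold
    )
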