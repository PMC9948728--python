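"""Analytic rarefaction and the dissimilarity / transform kernels.

Rarefaction uses the binomial ("asymptotic") expectation

    E[S(n*)] = sum_i ( 1 - (1 - N_i / N)^n* )

over taxa with N_i > 0, where N is the sample's total read count and n* the
standard depth.  This is the with-replacement approximation to the
hypergeometric expectation; the two agree closely whenever n* is small
relative to N, and the resampling check in the test-suite quantifies the
residual discrepancy.  Extrapolation (n* > N) is refused.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import CommunityTable

__all__ = [
    "rarefied_richness",
    "rarefy_table",
    "sorensen",
    "bray_curtis",
    "hellinger",
    "dissimilarity_matrix",
    "pairwise_bray_curtis",
    "pairwise_sorensen",
]


def rarefied_richness(counts, n_star: int) -> float:
    """Expected taxon richness at a standard depth of ``n_star`` reads.

    Parameters
    ----------
    counts : array-like of int
        Per-taxon read counts for one sample (zeros allowed).
    n_star : int
        Standard read depth, 1 <= n_star <= sum(counts).  Requesting a depth
        beyond the observed total is extrapolation and raises.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot rarefy an all-zero sample")
    if n_star < 1:
        raise ValueError("n_star must be >= 1")
    if n_star > total:
        raise ValueError(
            f"n_star={n_star} exceeds the sample total {int(total)}: "
            "extrapolation is not supported"
        )
    present = counts[counts > 0]
    return float(np.sum(1.0 - (1.0 - present / total) ** n_star))


def rarefy_table(table: CommunityTable, n_star: int) -> pd.Series:
    """Rarefied richness for every sample of a community table.

    Enforces ``n_star`` <= the minimum retained sample depth so no sample
    extrapolates.
    """
    totals = table.totals()
    min_depth = int(totals.min())
    if n_star > min_depth:
        raise ValueError(
            f"rarefaction depth {n_star} exceeds the minimum sample depth "
            f"{min_depth}; filter shallower samples first or lower the depth"
        )
    values = [rarefied_richness(row, n_star) for row in table.counts.to_numpy()]
    return pd.Series(values, index=table.counts.index, name=f"richness_{n_star}")


def sorensen(pa_i, pa_j) -> float:
    """Sorensen dissimilarity 1 - 2|A&B| / (|A| + |B|) between two presence vectors."""
    a = np.asarray(pa_i).astype(bool)
    b = np.asarray(pa_j).astype(bool)
    na, nb = a.sum(), b.sum()
    if na == 0 and nb == 0:
        raise ValueError("Sorensen undefined for two empty communities")
    shared = np.logical_and(a, b).sum()
    return float(1.0 - 2.0 * shared / (na + nb))


def bray_curtis(x_i, x_j) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) on relative abundances."""
    x = np.asarray(x_i, dtype=float)
    y = np.asarray(x_j, dtype=float)
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("Bray-Curtis undefined for a zero-sum vector")
    return float(np.abs(x - y).sum() / (x + y).sum())


def hellinger(table: CommunityTable) -> pd.DataFrame:
    """Hellinger transform sqrt(count / row_sum); rows get unit Euclidean norm."""
    totals = table.totals().astype(float)
    if (totals <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"zero-total rows cannot be Hellinger transformed: {bad}")
    rel = table.counts.to_numpy() / totals[:, None]
    return pd.DataFrame(
        np.sqrt(rel), index=table.counts.index, columns=table.counts.columns
    )


def pairwise_bray_curtis(x: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis matrix for rows of ``x`` (relative abundances)."""
    x = np.asarray(x, dtype=float)
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = x.sum(axis=1)[:, None] + x.sum(axis=1)[None, :]
    return num / den


def pairwise_sorensen(presence: np.ndarray) -> np.ndarray:
    """Pairwise Sorensen matrix for rows of a boolean presence matrix."""
    p = np.asarray(presence).astype(float)
    shared = p @ p.T
    sizes = p.sum(axis=1)
    den = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore"):
        out = 1.0 - 2.0 * shared / den
    return out


def dissimilarity_matrix(table: CommunityTable, metric: str) -> pd.DataFrame:
    """Pairwise dissimilarity matrix for a community table.

    ``metric`` is ``"sorensen"`` (on presence/absence) or ``"bray_curtis"``
    (on row-normalised relative abundances).
    """
    if metric == "sorensen":
        values = pairwise_sorensen(table.presence().to_numpy())
    elif metric == "bray_curtis":
        values = pairwise_bray_curtis(table.relative_abundance().to_numpy())
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(values, 0.0)
    return pd.DataFrame(values, index=table.sample_ids, columns=table.sample_ids)
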