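"""Neutral null model and the stochastic/deterministic partition of beta-diversity.

The null model holds each sample's observed richness fixed, draws that many
taxa without replacement with probability proportional to the regional
occupancy weights w_f, and assigns relative abundances from a
Dirichlet(alpha) with alpha = w_a*/min(w_a*), where w_a* are the regional
abundance weights of the chosen taxa.  Averaging pairwise dissimilarities
over many such neutral communities yields the expected dissimilarity E(d),
against which each observed pairwise dissimilarity O is compared:

    O > E(d):  det_a = (O - E) / O        (deterministic similarity)
    O < E(d):  det_b = (E - O) / (1 - O)  (deterministic dissimilarity)
    stoch     = 1 - (the applicable det component)

Exactly one deterministic component is nonzero per pair; stoch + det_a +
det_b = 1 always.  Per-sample summaries are column means excluding the
diagonal; the alternative aggregation 0.5*(mean stoch_a + mean stoch_b) over
the pairs where each branch applied is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import dissimilarity_matrix
from .tables import CommunityTable

__all__ = [
    "RegionalWeights",
    "regional_weights",
    "neutral_draw",
    "expected_dissimilarity",
    "partition_stochasticity",
    "PartitionComponents",
    "StochasticityPartition",
    "StochasticityResults",
]


@dataclass
class RegionalWeights:
    """Neutral regional weights: occupancy-based (w_f) and abundance-based (w_a)."""

    w_f: pd.Series
    w_a: pd.Series

    def __post_init__(self) -> None:
        for name, w in (("w_f", self.w_f), ("w_a", self.w_a)):
            v = w.to_numpy()
            if (v < 0).any():
                raise ValueError(f"{name} has negative entries")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {v.sum()})")


def regional_weights(table: CommunityTable) -> RegionalWeights:
    """Occupancy-proportion weights w_f and total-read-share weights w_a.

    w_f: per taxon, the fraction of samples occupied, normalised to sum 1.
    w_a: per taxon, total reads across all samples, normalised to sum 1.
    """
    presence = table.presence().to_numpy()
    occ = presence.mean(axis=0)
    w_f = occ / occ.sum()
    totals = table.counts.to_numpy().sum(axis=0).astype(float)
    w_a = totals / totals.sum()
    idx = pd.Index(table.taxon_ids, name="taxon")
    return RegionalWeights(
        w_f=pd.Series(w_f, index=idx, name="w_f"),
        w_a=pd.Series(w_a, index=idx, name="w_a"),
    )


def dirichlet_alpha(weights: np.ndarray) -> np.ndarray:
    """Concentration vector alpha = w / min(w); the smallest entry is always 1."""
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("Dirichlet construction requires strictly positive weights")
    return w / w.min()


def neutral_draw(
    richness: int, weights: RegionalWeights, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One neutral community: taxa indices and their relative abundances.

    ``richness`` taxa are drawn without replacement with probability
    proportional to w_f; abundances come from Dirichlet(w_a*/min(w_a*)).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    w_f = weights.w_f.to_numpy()
    available = int((w_f > 0).sum())
    if not 1 <= richness <= available:
        raise ValueError(
            f"richness {richness} outside [1, {available}] (taxa with positive w_f)"
        )
    chosen = rng.choice(len(w_f), size=richness, replace=False, p=w_f)
    w_a_star = weights.w_a.to_numpy()[chosen]
    assert (w_a_star > 0).all(), "drawn taxon has zero regional reads"
    if richness == 1:
        return chosen, np.array([1.0])
    abundances = rng.dirichlet(dirichlet_alpha(w_a_star))
    return chosen, abundances


def _simulate_null_batch(
    richness: np.ndarray,
    w_f: np.ndarray,
    w_a: np.ndarray,
    n_sims: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised neutral communities for all samples and simulations.

    Returns boolean occurrence masks (n_sims, n_samples, n_taxa) and
    row-normalised abundances of the same shape.  Sampling without
    replacement proportional to w_f uses the Gumbel top-k construction,
    which is distributionally identical to sequential renormalised draws.
    """
    n = len(richness)
    t = len(w_f)
    logw = np.full(t, -np.inf)
    positive = w_f > 0
    logw[positive] = np.log(w_f[positive])
    keys = logw[None, None, :] + rng.gumbel(size=(n_sims, n, t))
    # rank taxa by key per (sim, sample); top richness_i are present
    order = np.argsort(-keys, axis=2)
    ranks = np.empty_like(order)
    idx = np.arange(t)[None, None, :]
    np.put_along_axis(ranks, order, np.broadcast_to(idx, order.shape), axis=2)
    mask = ranks < richness[None, :, None]

    wa_sel = np.where(mask, w_a[None, None, :], np.inf)
    alpha = np.where(mask, w_a[None, None, :] / wa_sel.min(axis=2, keepdims=True), 0.0)
    gam = rng.gamma(shape=np.where(mask, alpha, 1.0))
    gam = np.where(mask, gam, 0.0)
    # richness >= 1 guarantees a positive row sum almost surely
    abund = gam / gam.sum(axis=2, keepdims=True)
    return mask, abund


def expected_dissimilarity(
    table: CommunityTable,
    weights: RegionalWeights,
    n_sims: int,
    metric: str,
    seed: int | np.random.Generator,
    batch: int = 200,
) -> pd.DataFrame:
    """Expected pairwise dissimilarity E(d) under the neutral null model.

    Each simulation redraws every sample's community at its observed
    richness; E(d) is the elementwise mean of the pairwise dissimilarity
    matrices over ``n_sims`` simulations.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if metric not in ("sorensen", "bray_curtis"):
        raise ValueError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    richness = table.richness()
    w_f = weights.w_f.to_numpy()
    w_a = weights.w_a.to_numpy()
    n = table.n_samples

    acc = np.zeros((n, n))
    done = 0
    while done < n_sims:
        b = min(batch, n_sims - done)
        mask, abund = _simulate_null_batch(richness, w_f, w_a, b, rng)
        if metric == "sorensen":
            sizes = richness.astype(float)
            den = sizes[:, None] + sizes[None, :]
            for s in range(b):
                m = mask[s].astype(float)
                shared = m @ m.T
                acc += 1.0 - 2.0 * shared / den
        else:
            for s in range(b):
                x = abund[s]
                acc += 0.5 * np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
        done += b
    e = acc / n_sims
    np.fill_diagonal(e, 0.0)
    return pd.DataFrame(e, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class PartitionComponents:
    """Per-pair stochastic and deterministic components plus per-sample means."""

    stoch: pd.DataFrame
    det_a: pd.DataFrame
    det_b: pd.DataFrame
    expected: pd.DataFrame
    observed: pd.DataFrame
    metric: str

    def sample_means(self) -> pd.DataFrame:
        """Column means of each component, excluding the diagonal."""
        n = self.stoch.shape[0]
        if n < 2:
            raise ValueError("need >= 2 samples for per-sample means")
        out = {}
        offdiag = ~np.eye(n, dtype=bool)
        for name, frame in (
            ("stoch", self.stoch),
            ("det_a", self.det_a),
            ("det_b", self.det_b),
        ):
            v = frame.to_numpy()
            out[name] = np.array(
                [v[offdiag[:, j], j].mean() for j in range(n)]
            )
        return pd.DataFrame(out, index=self.stoch.index)

    def sample_means_branch_averaged(self) -> pd.Series:
        """Alternative per-sample aggregation 0.5*(mean stoch_a + mean stoch_b).

        Means are taken over the pairs where each branch applied; if a branch
        never applied for a sample, the other branch's mean is used alone.
        """
        o = self.observed.to_numpy()
        e = self.expected.to_numpy()
        stoch = self.stoch.to_numpy()
        n = o.shape[0]
        offdiag = ~np.eye(n, dtype=bool)
        values = np.empty(n)
        for j in range(n):
            col = offdiag[:, j]
            a_mask = col & (o[:, j] > e[:, j])
            b_mask = col & (o[:, j] < e[:, j])
            parts = []
            if a_mask.any():
                parts.append(stoch[a_mask, j].mean())
            if b_mask.any():
                parts.append(stoch[b_mask, j].mean())
            values[j] = np.mean(parts) if parts else 1.0
        return pd.Series(values, index=self.stoch.index, name="stoch_branch_avg")


def partition_stochasticity(
    observed: pd.DataFrame, expected: pd.DataFrame, metric: str = ""
) -> PartitionComponents:
    """Partition each pairwise dissimilarity into stoch / det_a / det_b."""
    o = observed.to_numpy(dtype=float)
    e = expected.to_numpy(dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed and expected matrices must have equal shape")
    if (o < -1e-12).any() or (o > 1 + 1e-12).any():
        raise ValueError("observed dissimilarities must lie in [0, 1]")

    det_a = np.zeros_like(o)
    det_b = np.zeros_like(o)
    above = o > e
    below = o < e
    det_a[above] = (o[above] - e[above]) / o[above]
    det_b[below] = (e[below] - o[below]) / (1.0 - o[below])
    stoch = 1.0 - det_a - det_b
    np.fill_diagonal(det_a, 0.0)
    np.fill_diagonal(det_b, 0.0)
    np.fill_diagonal(stoch, 1.0)

    ids = observed.index
    wrap = lambda v: pd.DataFrame(v, index=ids, columns=ids)  # noqa: E731
    return PartitionComponents(
        stoch=wrap(stoch),
        det_a=wrap(det_a),
        det_b=wrap(det_b),
        expected=expected.copy(),
        observed=observed.copy(),
        metric=metric,
    )


class StochasticityPartition:
    """Null-model partition of beta-diversity for a community table.

    Examples
    --------
    >>> model = StochasticityPartition(table, metric="sorensen")
    >>> res = model.fit(n_sims=1000, seed=42)
    >>> res.summary()  # per-sample stochastic/deterministic fractions
    """

    def __init__(self, table: CommunityTable, metric: str = "sorensen"):
        if metric not in ("sorensen", "bray_curtis"):
            raise ValueError(f"unknown metric {metric!r}")
        self.table = table
        self.metric = metric
        self.weights = regional_weights(table)

    def fit(self, n_sims: int = 1000, seed: int | None = None) -> "StochasticityResults":
        rng = np.random.default_rng(seed)
        observed = dissimilarity_matrix(self.table, self.metric)
        expected = expected_dissimilarity(
            self.table, self.weights, n_sims, self.metric, rng
        )
        components = partition_stochasticity(observed, expected, metric=self.metric)
        return StochasticityResults(
            model=self, components=components, n_sims=n_sims, seed=seed
        )


@dataclass
class StochasticityResults:
    model: StochasticityPartition
    components: PartitionComponents
    n_sims: int
    seed: int | None

    def summary(self) -> pd.DataFrame:
        means = self.components.sample_means()
        means["stoch_branch_avg"] = self.components.sample_means_branch_averaged()
        return means
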