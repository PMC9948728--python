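"""Core data containers: community count tables, geochemistry, and sample geometry.

All downstream stages operate on these three aligned containers.  Alignment
means identical ``sample_ids`` in identical order; :func:`check_alignment`
enforces this and every pipeline entry point calls it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTable",
    "GeochemTable",
    "SiteGeometry",
    "AlignmentError",
    "filter_samples",
    "aggregate_taxa",
    "check_alignment",
]


class AlignmentError(ValueError):
    """Raised when the community/geochemistry/geometry tables disagree on samples."""


@dataclass
class CommunityTable:
    """Samples x taxa read counts with a sample-to-site mapping.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer read counts, rows are samples, columns taxa.
    site_ids : sequence of str
        Site identifier for each sample (same order as ``counts.index``).
    taxon_level : {"ASV", "phylum"}
        Granularity of the columns.
    """

    counts: pd.DataFrame
    site_ids: Sequence[str]
    taxon_level: str = "ASV"

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        if len(self.site_ids) != self.counts.shape[0]:
            raise ValueError(
                f"site_ids has {len(self.site_ids)} entries for "
                f"{self.counts.shape[0]} samples"
            )
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample_ids: {dups}")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("negative counts are not allowed")
        if self.taxon_level not in ("ASV", "phylum"):
            raise ValueError(f"unknown taxon_level {self.taxon_level!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def totals(self) -> np.ndarray:
        """Total reads per sample."""
        return self.counts.to_numpy().sum(axis=1)

    def richness(self) -> np.ndarray:
        """Observed taxon richness per sample."""
        return (self.counts.to_numpy() > 0).sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised relative abundances x_jk."""
        totals = self.totals().astype(float)
        if (totals <= 0).any():
            bad = [s for s, t in zip(self.sample_ids, totals) if t <= 0]
            raise ValueError(f"samples with zero total reads: {bad}")
        return self.counts.div(totals, axis=0)

    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence matrix."""
        return self.counts > 0

    def site_of(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.site_ids))


@dataclass
class GeochemTable:
    """Samples x geochemical variables (salts in ppm, NH3 in ppb, moisture fraction)."""

    values: pd.DataFrame
    units: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.copy().astype(float)
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample_ids in geochemistry table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def positive_values(self) -> pd.DataFrame:
        """Values with non-positive entries replaced by half the variable's
        smallest positive value (below-detection handling before log transform)."""
        out = self.values.copy()
        for col in out.columns:
            v = out[col].to_numpy()
            nonpos = v <= 0
            if nonpos.any():
                positive = v[v > 0]
                if positive.size == 0:
                    raise ValueError(f"variable {col!r} has no positive values")
                repl = 0.5 * positive.min()
                warnings.warn(
                    f"{nonpos.sum()} non-positive value(s) in {col!r} replaced "
                    f"by {repl:g} (half the smallest positive value) before log transform",
                    stacklevel=2,
                )
                v = v.copy()
                v[nonpos] = repl
                out[col] = v
        return out


@dataclass
class SiteGeometry:
    """Per-sample coordinates, either geographic (lat/lon degrees) or projected (km)."""

    coords: pd.DataFrame
    crs: str = "geographic"

    def __post_init__(self) -> None:
        self.coords = self.coords.copy().astype(float)
        if self.crs not in ("geographic", "projected"):
            raise ValueError(f"crs must be 'geographic' or 'projected', got {self.crs!r}")
        if self.coords.shape[1] != 2:
            raise ValueError("coords must have exactly two columns")
        if not np.isfinite(self.coords.to_numpy()).all():
            raise ValueError("coordinates must be finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coords.index)

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]


def check_alignment(
    community: CommunityTable,
    geochem: GeochemTable | None = None,
    geometry: SiteGeometry | None = None,
) -> None:
    """Verify that all provided tables share the community's sample order.

    Raises
    ------
    AlignmentError
        Listing the offending sample ids.
    """
    ref = community.sample_ids
    for name, other in (("geochemistry", geochem), ("geometry", geometry)):
        if other is None:
            continue
        ids = other.sample_ids
        if ids != ref:
            missing = sorted(set(ref) - set(ids))
            extra = sorted(set(ids) - set(ref))
            detail = []
            if missing:
                detail.append(f"missing from {name}: {missing[:10]}")
            if extra:
                detail.append(f"extra in {name}: {extra[:10]}")
            if not detail:
                detail.append("same ids, different order")
            raise AlignmentError(
                f"{name} table not aligned with community table ({'; '.join(detail)})"
            )


def filter_samples(table: CommunityTable, min_reads: int) -> CommunityTable:
    """Drop samples with fewer than ``min_reads`` total reads.

    Taxa left with zero total count across the retained samples are dropped
    too; the original sample order is preserved.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    totals = table.totals()
    keep = totals >= min_reads
    if not keep.any():
        raise ValueError(
            f"no samples pass the {min_reads}-read filter "
            f"(max total = {totals.max() if totals.size else 0})"
        )
    counts = table.counts.loc[keep]
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    return CommunityTable(
        counts=counts,
        site_ids=np.asarray(table.site_ids)[keep],
        taxon_level=table.taxon_level,
    )


def aggregate_taxa(table: CommunityTable, taxon_map: Mapping[str, str]) -> CommunityTable:
    """Sum counts within higher-level groups (typically ASV -> phylum).

    Taxa absent from ``taxon_map`` are pooled into an ``"Unassigned"`` bucket.
    Row sums are conserved exactly.
    """
    groups = [taxon_map.get(t, "Unassigned") for t in table.taxon_ids]
    agg = table.counts.T.groupby(pd.Index(groups, name="taxon")).sum().T
    return CommunityTable(counts=agg, site_ids=table.site_ids, taxon_level="phylum")
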