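"""Readers and writers for the plain-text input/output formats.

Inputs: community TSV (rows = samples, columns = taxa, plus a ``site``
column), geochemistry CSV, coordinates CSV (``lat``/``lon`` or
``x_km``/``y_km``), taxonomy TSV (taxon, phylum) and a flat YAML run config.
Outputs are TSV matrices and JSON summaries; floats are written with
17 significant digits so write-then-read round-trips to full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from .tables import CommunityTable, GeochemTable, SiteGeometry

__all__ = [
    "RunConfig",
    "read_community",
    "read_geochem",
    "read_geometry",
    "read_taxonomy",
    "write_community",
    "write_geochem",
    "write_geometry",
    "write_matrix",
    "read_matrix",
    "write_json",
]

FLOAT_FMT = "%.17g"
SITE_COLUMN = "site"


@dataclass
class RunConfig:
    """Flat run configuration, loadable from YAML."""

    min_reads: int = 586
    rarefy_to: int = 3000
    n_null_sims: int = 1000
    n_battery_sims: int = 1000
    n_bootstrap: int = 1000
    n_mems: int = 4
    lowess_frac: float = 0.67
    seed: int = 0
    taxon_level: str = "phylum"

    def __post_init__(self) -> None:
        for name in ("min_reads", "rarefy_to", "n_null_sims", "n_battery_sims",
                     "n_bootstrap", "n_mems"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.lowess_frac <= 1:
            raise ValueError("lowess_frac must lie in (0, 1]")
        if self.taxon_level not in ("ASV", "phylum"):
            raise ValueError(f"unknown taxon_level {self.taxon_level!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def read_community(path: str | Path) -> CommunityTable:
    """Community TSV: first column sample id, a ``site`` column, taxa columns."""
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if SITE_COLUMN not in frame.columns:
        raise ValueError(f"community table needs a {SITE_COLUMN!r} column")
    sites = frame.pop(SITE_COLUMN).astype(str).to_numpy()
    counts = frame.astype(int)
    return CommunityTable(counts=counts, site_ids=sites)


def write_community(table: CommunityTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.insert(0, SITE_COLUMN, table.site_ids)
    out.to_csv(path, sep="\t")


def read_geochem(path: str | Path) -> GeochemTable:
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return GeochemTable(values=frame)


def write_geochem(table: GeochemTable, path: str | Path) -> None:
    table.values.to_csv(path, float_format=FLOAT_FMT)


def read_geometry(path: str | Path) -> SiteGeometry:
    """Coordinates CSV with either lat/lon (geographic) or x_km/y_km (projected)."""
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    cols = {c.lower() for c in frame.columns}
    if {"lat", "lon"} <= cols:
        frame = frame.rename(columns=str.lower)[["lat", "lon"]]
        crs = "geographic"
    elif {"x_km", "y_km"} <= cols:
        frame = frame.rename(columns=str.lower)[["x_km", "y_km"]]
        crs = "projected"
    else:
        raise ValueError(
            "coordinates file needs either lat/lon or x_km/y_km columns; "
            f"got {sorted(frame.columns)}"
        )
    return SiteGeometry(coords=frame, crs=crs)


def write_geometry(geometry: SiteGeometry, path: str | Path) -> None:
    geometry.coords.to_csv(path, float_format=FLOAT_FMT)


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping taxon id to phylum."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("taxonomy TSV needs two columns (taxon, phylum)")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def write_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(value):
    try:
        return value.item()
    except AttributeError:
        return str(value)
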