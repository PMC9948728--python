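"""Synthetic transect datasets with known assembly rules.

The generator emulates a polar soil-transect survey: ~12 sites strung along
a ~120-km transect, several soil samples per site (co-located), a single
latent environmental gradient (position along the transect) that drives a
suite of positively covarying log-normal salt concentrations and a
negatively loading soil-moisture variable, and communities whose occurrence
and abundance follow one of the seven two-stage assembly processes.  Read
depths vary from hundreds to tens of thousands of reads so the read-depth
filter and rarefaction have something to do.

Ground truth (the generating rule, each taxon's niche optimum, home site and
regional abundance) is returned alongside the tables so downstream inference
can be validated against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tables import CommunityTable, GeochemTable, SiteGeometry

__all__ = ["SynthParams", "SyntheticDataset", "generate_geometry", "generate_geochem",
           "generate_community", "generate_dataset", "RULES"]

# occurrence -> abundance rule labels accepted by the generator
RULES = ("f->a", "e->a", "d->a", "e->e", "e->d", "d->e", "d->d")

# log-scale intercepts and gradient slopes for each geochemical variable;
# slopes are per-km on the natural-log scale, positive for all salts so they
# covary along the gradient, negative for moisture
DEFAULT_VARIABLES: dict[str, tuple[float, float]] = {
    "F": (0.5, 0.018),
    "Cl": (3.0, 0.025),
    "SO4": (2.5, 0.022),
    "Na": (3.2, 0.024),
    "Mg": (1.8, 0.020),
    "K": (1.5, 0.019),
    "Ca": (2.0, 0.021),
    "SiO2": (2.2, 0.015),
    "NO3": (1.0, 0.030),
    "NH3": (4.0, 0.017),
    "moisture": (-3.0, -0.012),
}


@dataclass
class SynthParams:
    """Parameters of the synthetic transect generator.

    Defaults describe the emulated survey: 12 sites over 120 km, 86 samples
    in total (4-10 per site), 30 phylum-level taxa, one latent gradient with
    log-scale noise sd 0.5, Gaussian niches of 15 km breadth, and read
    depths uniform between 500 and 20,000.
    """

    n_sites: int = 12
    samples_per_site: tuple[int, int] = (4, 10)
    n_samples_total: int | None = 86
    transect_km: float = 120.0
    n_taxa: int = 30
    gradient_loading: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VARIABLES)
    )
    noise_sd: float = 0.5
    lateral_sd_km: float = 20.0
    env_site_sd: float = 15.0
    env_sample_sd: float = 5.0
    assembly_rule: str = "f->a"
    niche_breadth: float = 15.0
    dispersal_floor_km: float = 5.0
    freq_abund_corr: float = 0.0
    pool_sigma: float = 0.3
    depth_range: tuple[int, int] = (500, 20000)
    richness_frac: tuple[float, float] = (0.3, 0.7)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValueError("n_sites must be >= 3")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.noise_sd <= 0 or self.niche_breadth <= 0:
            raise ValueError("noise_sd and niche_breadth must be positive")
        if self.assembly_rule not in RULES:
            raise ValueError(
                f"assembly_rule {self.assembly_rule!r} not one of {RULES}"
            )


@dataclass
class SyntheticGeometry:
    """Sample geometry plus the latent gradients.

    ``gradient`` is the spatial position along the transect (km);
    ``env_value`` is the latent environmental state driving geochemistry and
    niches: position plus site- and sample-level heterogeneity, so the
    environment correlates with space without being a pure function of it
    (as in real soil transects, where local soil conditions vary within and
    among nearby sites).
    """

    geometry: SiteGeometry
    site_ids: np.ndarray
    gradient: np.ndarray  # per-sample position along the transect
    env_value: np.ndarray  # per-sample latent environmental state


@dataclass
class SyntheticDataset:
    community: CommunityTable
    geochem: GeochemTable
    geometry: SiteGeometry
    gradient: np.ndarray
    truth: dict


def _site_sample_counts(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    lo, hi = params.samples_per_site
    counts = rng.integers(lo, hi + 1, size=params.n_sites)
    target = params.n_samples_total
    if target is not None:
        if not params.n_sites * lo <= target <= params.n_sites * hi:
            raise ValueError(
                f"n_samples_total={target} unreachable with {params.n_sites} "
                f"sites of {lo}-{hi} samples"
            )
        # nudge site counts within bounds until the total matches
        while counts.sum() != target:
            diff = target - counts.sum()
            i = rng.integers(params.n_sites)
            if diff > 0 and counts[i] < hi:
                counts[i] += 1
            elif diff < 0 and counts[i] > lo:
                counts[i] -= 1
    return counts


def generate_geometry(params: SynthParams) -> SyntheticGeometry:
    """Sites scattered around a transect axis; co-located samples at each site.

    The macro-gradient runs along x; sites also scatter laterally
    (``lateral_sd_km``), so geographic distance carries information the
    gradient alone does not -- dispersal operates in the full 2-D landscape
    while the environment varies along the transect axis.
    """
    rng = np.random.default_rng(params.seed)
    along = np.linspace(0.0, params.transect_km, params.n_sites)
    jitter = rng.normal(0.0, params.transect_km / (10 * params.n_sites), params.n_sites)
    along = np.clip(along + jitter, 0.0, params.transect_km)
    lateral = rng.normal(0.0, params.lateral_sd_km, params.n_sites)

    counts = _site_sample_counts(params, rng)
    site_offset = rng.normal(0.0, params.env_site_sd, params.n_sites)
    site_ids, xs, ys, env = [], [], [], []
    sample_ids = []
    for s in range(params.n_sites):
        for r in range(counts[s]):
            site_ids.append(f"site{s + 1:02d}")
            sample_ids.append(f"site{s + 1:02d}_s{r + 1}")
            xs.append(along[s])
            ys.append(lateral[s])
            env.append(along[s] + site_offset[s] + rng.normal(0.0, params.env_sample_sd))
    coords = pd.DataFrame(
        {"x_km": xs, "y_km": ys}, index=pd.Index(sample_ids, name="sample")
    )
    geometry = SiteGeometry(coords=coords, crs="projected")
    return SyntheticGeometry(
        geometry=geometry,
        site_ids=np.asarray(site_ids, dtype=object),
        gradient=np.asarray(xs, dtype=float),
        env_value=np.asarray(env, dtype=float),
    )


def generate_geochem(params: SynthParams, geom: SyntheticGeometry) -> GeochemTable:
    """Log-normal geochemistry driven by the latent gradient.

    For each variable v, log(v) = a_v + b_v * h + Normal(0, noise_sd), where
    h is the latent environmental state (position plus local heterogeneity);
    salts have positive slopes b_v (so they positively covary along the
    transect) and moisture a negative one.
    """
    rng = np.random.default_rng(params.seed + 1)
    g = geom.env_value
    data = {}
    for var, (a, b) in params.gradient_loading.items():
        eps = rng.normal(0.0, params.noise_sd, size=len(g))
        data[var] = np.exp(a + b * g + eps)
    values = pd.DataFrame(data, index=geom.geometry.coords.index)
    units = {v: ("ppb" if v == "NH3" else "fraction" if v == "moisture" else "ppm")
             for v in values.columns}
    return GeochemTable(values=values, units=units)


def _truth_weights(
    params: SynthParams, geom: SyntheticGeometry, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], dict]:
    """Per-sample x taxon occurrence/abundance weights for each rule family."""
    t = params.n_taxa
    xy = geom.geometry.coords.to_numpy()
    h = geom.env_value
    mu = rng.uniform(h.min(), h.max(), size=t)  # niche optima on the env axis
    # dispersal sources are 2-D points in the landscape
    home_x = rng.uniform(0.0, params.transect_km, size=t)
    home_y = rng.normal(0.0, params.lateral_sd_km, size=t)
    # pool abundance and pool occupancy frequency: correlated lognormals
    # (widespread taxa tend to be abundant, but not perfectly so)
    rho = params.freq_abund_corr
    z_a = rng.normal(size=t)
    z_f = rho * z_a + np.sqrt(1.0 - rho**2) * rng.normal(size=t)
    regional = np.exp(params.pool_sigma * z_a)  # pool abundances
    frequency = np.exp(params.pool_sigma * z_f)  # pool occurrence frequencies

    env = regional[None, :] * np.exp(
        -((h[:, None] - mu[None, :]) ** 2) / (2.0 * params.niche_breadth**2)
    )
    home_dist = np.sqrt(
        (xy[:, 0][:, None] - home_x[None, :]) ** 2
        + (xy[:, 1][:, None] - home_y[None, :]) ** 2
    )
    disp = regional[None, :] / (home_dist + params.dispersal_floor_km)
    n = len(h)
    weights = {
        "f": np.tile(frequency, (n, 1)),
        "a": np.tile(regional, (n, 1)),
        "e": env,
        "d": disp,
    }
    truth = {
        "assembly_rule": params.assembly_rule,
        "niche_optimum": mu.tolist(),
        "home_x_km": home_x.tolist(),
        "home_y_km": home_y.tolist(),
        "regional_abundance": regional.tolist(),
        "pool_frequency": frequency.tolist(),
        "niche_breadth": params.niche_breadth,
        "seed": params.seed,
    }
    return weights, truth


def generate_community(
    params: SynthParams,
    geom: SyntheticGeometry,
    geochem: GeochemTable | None = None,
) -> tuple[CommunityTable, dict]:
    """Two-stage community draw under the configured assembly rule.

    Occurrence: per-sample richness taxa drawn without replacement with
    probability proportional to the occurrence family's weights.  Abundance:
    Dirichlet(alpha = w*/min(w*)) over the chosen taxa using the abundance
    family's weights.  Reads: multinomial at a depth uniform in depth_range.
    """
    rng = np.random.default_rng(params.seed + 2)
    weights, truth = _truth_weights(params, geom, rng)
    occ_kind, ab_kind = params.assembly_rule.split("->")
    occ_w, ab_w = weights[occ_kind], weights[ab_kind]

    n = len(geom.gradient)
    t = params.n_taxa
    lo, hi = params.richness_frac
    richness = np.maximum(1, (rng.uniform(lo, hi, size=n) * t).astype(int))
    depths = rng.integers(params.depth_range[0], params.depth_range[1] + 1, size=n)

    counts = np.zeros((n, t), dtype=int)
    for i in range(n):
        w = occ_w[i].astype(float)
        if (w > 0).sum() < richness[i]:  # numerically extinct taxa: tiny floor
            w = w + w[w > 0].min() * 1e-12 if (w > 0).any() else np.ones(t)
        chosen = rng.choice(t, size=richness[i], replace=False, p=w / w.sum())
        aw = ab_w[i, chosen].astype(float)
        if aw.max() <= 0:
            aw = np.ones_like(aw)
        aw = np.where(aw <= 0, 1e-6 * aw.max(), aw)
        if richness[i] == 1:
            rel = np.array([1.0])
        else:
            rel = rng.dirichlet(aw / aw.min())
        counts[i, chosen] = rng.multinomial(depths[i], rel)

    frame = pd.DataFrame(
        counts,
        index=geom.geometry.coords.index,
        columns=[f"taxon{k + 1:03d}" for k in range(t)],
    )
    table = CommunityTable(
        counts=frame,
        site_ids=geom.site_ids,
        taxon_level="phylum" if t <= 60 else "ASV",
    )
    truth["richness"] = richness.tolist()
    truth["depths"] = depths.tolist()
    return table, truth


def generate_dataset(params: SynthParams) -> SyntheticDataset:
    """Geometry, geochemistry and community in one call."""
    geom = generate_geometry(params)
    geochem = generate_geochem(params, geom)
    community, truth = generate_community(params, geom, geochem)
    truth["params"] = {
        k: v for k, v in asdict(params).items() if k != "gradient_loading"
    }
    return SyntheticDataset(
        community=community,
        geochem=geochem,
        geometry=geom.geometry,
        gradient=geom.gradient,
        truth=truth,
    )
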