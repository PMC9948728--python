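"""End-to-end orchestration of the three hypothesis pipelines.

``run_pipeline`` reads aligned community/geochemistry/geometry tables,
applies the read-depth filter and optional taxonomic aggregation, and runs:

* hypothesis 1 — soil PCA, rarefied richness, MEM construction, RDA and
  spatial/environmental variance partitioning, with trend fits;
* hypothesis 2 — the neutral null model and the stochastic/deterministic
  partition of beta-diversity (both metrics);
* hypothesis 3 — the seven-process mechanism battery.

All randomness flows from the single config seed through spawned
``numpy.random.SeedSequence`` children, one per stochastic stage, so a fixed
seed gives byte-identical output files.  Stage timings and seeds are logged,
never written to result files.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as aio
from .diversity import hellinger, rarefy_table
from .mechanisms import MechanismBattery, weight_correlation
from .nullmodel import StochasticityPartition
from .ordination import RDA, soil_pca, variance_partition
from .spatial import build_mems, pairwise_distances
from .tables import (
    CommunityTable,
    GeochemTable,
    SiteGeometry,
    aggregate_taxa,
    check_alignment,
    filter_samples,
)
from .trends import fit_trend

__all__ = ["run_pipeline", "prepare_inputs"]

logger = logging.getLogger(__name__)


def _child_seed(root: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(root).spawn(index + 1)[index])


def prepare_inputs(
    config: aio.RunConfig,
    community: CommunityTable,
    geochem: GeochemTable,
    geometry: SiteGeometry,
    taxonomy: Mapping[str, str] | None = None,
) -> tuple[CommunityTable, GeochemTable, SiteGeometry]:
    """Filter by read depth, optionally aggregate taxa, subset the paired tables."""
    check_alignment(community, geochem, geometry)
    table = filter_samples(community, config.min_reads)
    if taxonomy is not None and config.taxon_level == "phylum" and community.taxon_level == "ASV":
        table = aggregate_taxa(table, taxonomy)
    keep = table.sample_ids
    geochem = GeochemTable(values=geochem.values.loc[keep], units=dict(geochem.units))
    geometry = SiteGeometry(coords=geometry.coords.loc[keep], crs=geometry.crs)
    return table, geochem, geometry


def _stage(name: str):
    logger.info("stage %s starting", name)
    return time.perf_counter()


def _done(name: str, t0: float) -> None:
    logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)


def run_pipeline(
    config: aio.RunConfig,
    community: CommunityTable,
    geochem: GeochemTable,
    geometry: SiteGeometry,
    outdir: str | Path,
    taxonomy: Mapping[str, str] | None = None,
    stages: tuple[str, ...] = ("hyp1", "hyp2", "hyp3"),
) -> dict:
    """Run the requested hypothesis stages and write all results to ``outdir``.

    Returns the scalar-summary dictionary that is also written to
    ``summary.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline seed=%d stages=%s", config.seed, ",".join(stages))

    table, geochem, geometry = prepare_inputs(
        config, community, geochem, geometry, taxonomy
    )
    distances = pairwise_distances(geometry)
    aio.write_matrix(distances, outdir / "distances_km.tsv")

    summary: dict = {
        "n_samples": table.n_samples,
        "n_taxa": table.n_taxa,
        "config": {
            "min_reads": config.min_reads,
            "rarefy_to": config.rarefy_to,
            "n_null_sims": config.n_null_sims,
            "n_battery_sims": config.n_battery_sims,
            "n_bootstrap": config.n_bootstrap,
            "n_mems": config.n_mems,
            "lowess_frac": config.lowess_frac,
            "seed": config.seed,
            "taxon_level": config.taxon_level,
        },
    }

    if "hyp1" in stages:
        t0 = _stage("hyp1")
        summary["hyp1"] = _run_hyp1(config, table, geochem, geometry, outdir)
        _done("hyp1", t0)
    if "hyp2" in stages:
        t0 = _stage("hyp2")
        summary["hyp2"] = _run_hyp2(config, table, outdir)
        _done("hyp2", t0)
    if "hyp3" in stages:
        t0 = _stage("hyp3")
        summary["hyp3"] = _run_hyp3(config, table, geochem, distances, outdir)
        _done("hyp3", t0)

    aio.write_json(summary, outdir / "summary.json")
    return summary


def _run_hyp1(config, table, geochem, geometry, outdir: Path) -> dict:
    pca = soil_pca(geochem)
    aio.write_matrix(pca.scores, outdir / "soil_pca_scores.tsv")
    aio.write_matrix(pca.loadings, outdir / "soil_pca_loadings.tsv")

    richness = rarefy_table(table, config.rarefy_to)
    aio.write_matrix(richness.to_frame(), outdir / "rarefied_richness.tsv")

    mems = build_mems(geometry)
    aio.write_matrix(mems.eigenvectors, outdir / "mem_scores.tsv")
    n_mems = min(config.n_mems, mems.n_axes)
    spatial = mems.scores(n_mems)
    env = pca.scores.iloc[:, :2]

    predictors = pd.concat([env, spatial], axis=1)
    rda_res = RDA(hellinger(table), predictors).fit()
    aio.write_matrix(rda_res.site_scores, outdir / "rda_site_scores.tsv")
    aio.write_matrix(rda_res.biplot_scores, outdir / "rda_biplot_scores.tsv")

    part = variance_partition(hellinger(table), spatial, env)

    # trend fits against the salt-proxy variable (NO3 where present)
    salt_var = "NO3" if "NO3" in geochem.variables else geochem.variables[0]
    log_salt = np.log(geochem.positive_values()[salt_var].to_numpy())
    rng = _child_seed(config.seed, 3)
    pc1_fit = fit_trend(
        log_salt, pca.scores.iloc[:, 0].to_numpy(), fit_type="linear",
        n_bootstrap=config.n_bootstrap, seed=int(rng.integers(2**31)),
    )
    rich_fit = fit_trend(
        log_salt, richness.to_numpy(), fit_type="lowess", frac=config.lowess_frac,
        n_bootstrap=config.n_bootstrap, seed=int(rng.integers(2**31)),
    )
    aio.write_matrix(pc1_fit.envelope(), outdir / "trend_pc1_vs_salt.tsv")
    aio.write_matrix(rich_fit.envelope(), outdir / "trend_richness_vs_salt.tsv")

    return {
        "pca_var_explained": pca.var_explained.tolist(),
        "mem_threshold_km": mems.threshold_km,
        "n_positive_mems": mems.n_axes,
        "rda_r2": rda_res.r2,
        "rda_axis_var_fitted": rda_res.axis_var_fitted.tolist(),
        "rda_axis_var_total": rda_res.axis_var_total.tolist(),
        "variance_partition": part.summary().to_dict(),
        "pseudo_r2_pc1_vs_salt": pc1_fit.pseudo_r2,
        "pseudo_r2_richness_vs_salt": rich_fit.pseudo_r2,
        "salt_variable": salt_var,
    }


def _run_hyp2(config, table, outdir: Path) -> dict:
    out = {}
    for j, metric in enumerate(("sorensen", "bray_curtis")):
        rng = _child_seed(config.seed, j)
        res = StochasticityPartition(table, metric=metric).fit(
            n_sims=config.n_null_sims, seed=int(rng.integers(2**31))
        )
        comp = res.components
        aio.write_matrix(comp.stoch, outdir / f"stoch_{metric}.tsv")
        aio.write_matrix(comp.det_a, outdir / f"det_a_{metric}.tsv")
        aio.write_matrix(comp.det_b, outdir / f"det_b_{metric}.tsv")
        aio.write_matrix(comp.expected, outdir / f"expected_dissim_{metric}.tsv")
        means = res.summary()
        aio.write_matrix(means, outdir / f"partition_means_{metric}.tsv")
        out[metric] = {
            "mean_stoch": float(means["stoch"].mean()),
            "mean_det_a": float(means["det_a"].mean()),
            "mean_det_b": float(means["det_b"].mean()),
            "n_sims": config.n_null_sims,
        }
    return out


def _run_hyp3(config, table, geochem, distances, outdir: Path) -> dict:
    pca = soil_pca(geochem)
    rng = _child_seed(config.seed, 2)
    model = MechanismBattery(
        table, distances, pca.scores, classifier_seed=int(rng.integers(2**31))
    )
    for kind, w in model.weights.items():
        aio.write_matrix(w.values, outdir / f"weights_{kind}.tsv")
    res = model.fit(n_sims=config.n_battery_sims, seed=int(rng.integers(2**31)))
    ranking = res.summary()
    aio.write_matrix(ranking, outdir / "battery_ranking.tsv")
    for metric in ("sorensen", "bray_curtis"):
        aio.write_matrix(
            res.sample_scores(metric), outdir / f"battery_scores_{metric}.tsv"
        )
    return {
        "best_process_bray_curtis": res.best_process("bray_curtis"),
        "best_process_sorensen": res.best_process("sorensen"),
        "ranking": {m: ranking[m].to_dict() for m in ranking.columns},
        "weight_correlation_log": weight_correlation(
            model.weights["w_d"], model.weights["w_e"]
        ),
        "n_sims": config.n_battery_sims,
    }
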