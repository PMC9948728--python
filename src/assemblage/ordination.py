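"""Unconstrained and constrained ordination: soil PCA, RDA, variance partitioning.

The PCA of soil geochemistry log-transforms every variable, standardises to
zero mean and unit variance, and decomposes by SVD; the leading axis is
expected to recover the dominant geochemical gradient (a salt axis in saline
soil transects).

RDA (redundancy analysis) is the constrained counterpart: a multivariate
least-squares regression of the (column-centered) Hellinger-transformed
community matrix on the predictors, followed by a PCA of the fitted values.
R^2 = SS_fitted / SS_total.  Variance partitioning fits spatial-only (S),
environment-only (E) and joint (S+E) RDAs and decomposes R^2_{S+E} into

    pure spatial   = R^2_{S+E} - R^2_E
    pure environ.  = R^2_{S+E} - R^2_S
    shared         = R^2_S + R^2_E - R^2_{S+E}

Negative components (suppressor structure) are reported as-is with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import GeochemTable

__all__ = ["soil_pca", "PCAResult", "RDA", "RDAResults", "variance_partition", "VariancePartition"]


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a PCA."""

    scores: pd.DataFrame  # samples x axes
    loadings: pd.DataFrame  # variables x axes (orthonormal columns)
    var_explained: np.ndarray  # fraction per axis, sums to 1

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "var_explained": self.var_explained,
                "cumulative": np.cumsum(self.var_explained),
            },
            index=self.scores.columns,
        )


def soil_pca(geochem: GeochemTable) -> PCAResult:
    """PCA of log-transformed, standardised geochemistry.

    Each variable is log-transformed (non-positive values are handled by the
    table's below-detection rule), centred and scaled to unit standard
    deviation, then the standardised matrix is decomposed by SVD.
    """
    if len(geochem.variables) < 2:
        raise ValueError("PCA needs at least 2 variables")
    logged = np.log(geochem.positive_values().to_numpy())
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    constant = sd <= 0
    if constant.any():
        names = [v for v, c in zip(geochem.variables, constant) if c]
        raise ValueError(f"constant variable(s) after log transform: {names}")
    z = (logged - mean) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # orient each axis so its largest-|loading| variable loads positively
    for j in range(vt.shape[0]):
        row = vt[j]
        if row[np.argmax(np.abs(row))] < 0:
            vt[j] = -row
            u[:, j] = -u[:, j]
    axes = [f"PC{k + 1}" for k in range(len(s))]
    scores = pd.DataFrame(u * s, index=geochem.sample_ids, columns=axes)
    loadings = pd.DataFrame(vt.T, index=geochem.variables, columns=axes)
    var_explained = s**2 / np.sum(s**2)
    return PCAResult(scores=scores, loadings=loadings, var_explained=var_explained)


class RDA:
    """Redundancy analysis of a multivariate response on a predictor matrix.

    Parameters
    ----------
    response : pandas.DataFrame
        Samples x variables response (typically Hellinger-transformed
        community data).  Columns are centered internally.
    predictors : pandas.DataFrame
        Samples x predictors; centered internally.
    """

    def __init__(self, response: pd.DataFrame, predictors: pd.DataFrame):
        if response.shape[0] != predictors.shape[0]:
            raise ValueError("response and predictors must have equal sample counts")
        if response.shape[0] <= predictors.shape[1]:
            raise ValueError(
                f"need n_samples ({response.shape[0]}) > n_predictors "
                f"({predictors.shape[1]})"
            )
        self.response = response
        self.predictors = predictors

    def fit(self) -> "RDAResults":
        y = self.response.to_numpy(dtype=float)
        x = self.predictors.to_numpy(dtype=float)
        y = y - y.mean(axis=0)
        x = x - x.mean(axis=0)

        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            warnings.warn(
                "rank-deficient predictor matrix; using pseudo-inverse",
                stacklevel=2,
            )
        beta = np.linalg.pinv(x) @ y
        fitted = x @ beta

        ss_total = float((y**2).sum())
        ss_fitted = float((fitted**2).sum())
        r2 = ss_fitted / ss_total if ss_total > 0 else 0.0

        u, s, vt = np.linalg.svd(fitted, full_matrices=False)
        keep = s > 1e-10 * max(s.max(), 1e-300)
        u, s, vt = u[:, keep], s[keep], vt[keep]
        for j in range(len(s)):
            row = vt[j]
            if row[np.argmax(np.abs(row))] < 0:
                vt[j] = -row
                u[:, j] = -u[:, j]
        axes = [f"RDA{k + 1}" for k in range(len(s))]
        site_scores = pd.DataFrame(u * s, index=self.response.index, columns=axes)

        # correlations of predictors with constrained axis scores
        biplot = np.zeros((x.shape[1], len(s)))
        for j in range(len(s)):
            axis = site_scores.iloc[:, j].to_numpy()
            denom = np.linalg.norm(x, axis=0) * np.linalg.norm(axis)
            with np.errstate(invalid="ignore", divide="ignore"):
                biplot[:, j] = np.where(denom > 0, (x.T @ axis) / denom, 0.0)
        biplot_scores = pd.DataFrame(biplot, index=self.predictors.columns, columns=axes)

        axis_var_fitted = s**2 / ss_fitted if ss_fitted > 0 else np.zeros_like(s)
        axis_var_total = s**2 / ss_total if ss_total > 0 else np.zeros_like(s)
        return RDAResults(
            model=self,
            r2=r2,
            site_scores=site_scores,
            biplot_scores=biplot_scores,
            axis_var_fitted=axis_var_fitted,
            axis_var_total=axis_var_total,
        )


@dataclass
class RDAResults:
    """Fitted RDA: R^2, constrained-axis site scores, predictor correlations.

    ``axis_var_fitted`` gives each constrained axis's share of the fitted
    (constrained) variance; ``axis_var_total`` its share of total response
    variance.  Both conventions appear in the literature, so both are kept.
    """

    model: RDA
    r2: float
    site_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    axis_var_fitted: np.ndarray
    axis_var_total: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.site_scores.shape[1]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "var_of_fitted": self.axis_var_fitted,
                "var_of_total": self.axis_var_total,
                "cum_var_of_fitted": np.cumsum(self.axis_var_fitted),
            },
            index=self.site_scores.columns,
        )


@dataclass
class VariancePartition:
    """Decomposition of joint RDA R^2 into pure and shared fractions."""

    spatial: float
    environmental: float
    shared: float
    residual: float
    r2_s: float
    r2_e: float
    r2_joint: float

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "pure_spatial": self.spatial,
                "pure_environmental": self.environmental,
                "shared": self.shared,
                "residual": self.residual,
                "r2_spatial_only": self.r2_s,
                "r2_environment_only": self.r2_e,
                "r2_joint": self.r2_joint,
            }
        )


def variance_partition(
    response: pd.DataFrame, spatial: pd.DataFrame, environmental: pd.DataFrame
) -> VariancePartition:
    """Three-model variance partitioning of a community response.

    Fits RDAs on the spatial predictors alone, the environmental predictors
    alone, and both together, then decomposes the joint R^2.
    """
    r2_s = RDA(response, spatial).fit().r2
    r2_e = RDA(response, environmental).fit().r2
    joint = pd.concat([spatial, environmental], axis=1)
    r2_se = RDA(response, joint).fit().r2

    pure_spatial = r2_se - r2_e
    pure_environmental = r2_se - r2_s
    shared = r2_s + r2_e - r2_se
    if min(pure_spatial, pure_environmental, shared) < 0:
        warnings.warn(
            "negative variance-partition component (suppressor structure); "
            "reported as-is",
            stacklevel=2,
        )
    return VariancePartition(
        spatial=pure_spatial,
        environmental=pure_environmental,
        shared=shared,
        residual=1.0 - r2_se,
        r2_s=r2_s,
        r2_e=r2_e,
        r2_joint=r2_se,
    )
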