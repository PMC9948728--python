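"""Trend fitting with bootstrap envelopes: linear and LOWESS fits plus a
pseudo-R^2 defined artifact-wide as 1 - SS_residual / SS_total about the
fitted curve.  Bootstrap resamples (x, y) pairs with replacement and refits;
the 2.5-97.5 percentile band of the bootstrap curves gives a confidence
envelope.  Negative pseudo-R^2 (possible for LOWESS on pathological data) is
reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["TrendModel", "TrendFit", "fit_trend"]

_lowess = sm.nonparametric.lowess


def _fit_curve(x, y, grid, fit_type, frac):
    if fit_type == "linear":
        slope, intercept = np.polyfit(x, y, 1)
        return intercept + slope * grid
    out = _lowess(y, x, frac=frac, xvals=grid)
    return np.asarray(out, dtype=float)


@dataclass
class TrendFit:
    """Point fit, bootstrap curves and pseudo-R^2 for one x-y relationship."""

    x: np.ndarray
    y: np.ndarray
    fit_type: str
    frac: float
    grid: np.ndarray
    fitted: np.ndarray  # point fit evaluated on grid
    fitted_at_x: np.ndarray  # point fit evaluated at the observations
    boot_curves: np.ndarray  # n_bootstrap x len(grid)
    pseudo_r2: float

    @property
    def n_bootstrap(self) -> int:
        return self.boot_curves.shape[0]

    def envelope(self, lower: float = 2.5, upper: float = 97.5) -> pd.DataFrame:
        lo = np.nanpercentile(self.boot_curves, lower, axis=0)
        hi = np.nanpercentile(self.boot_curves, upper, axis=0)
        return pd.DataFrame(
            {"x": self.grid, "fit": self.fitted, "lower": lo, "upper": hi}
        )

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "fit_type": self.fit_type,
                "n_obs": len(self.x),
                "n_bootstrap": self.n_bootstrap,
                "frac": self.frac if self.fit_type == "lowess" else np.nan,
                "pseudo_r2": self.pseudo_r2,
            }
        )


def fit_trend(
    x,
    y,
    fit_type: str = "lowess",
    frac: float = 0.67,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    grid: np.ndarray | None = None,
) -> TrendFit:
    """Fit a linear or LOWESS trend with a bootstrap envelope.

    Parameters
    ----------
    x, y : array-like
        Observations; non-finite pairs are dropped; >= 5 pairs required.
    fit_type : {"linear", "lowess"}
    frac : float
        LOWESS span (fraction of points per local window).
    n_bootstrap : int
        Number of pair-resampling bootstrap replicates.
    grid : array-like, optional
        Evaluation grid; defaults to 100 points spanning the data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 5:
        raise ValueError(f"need >= 5 finite (x, y) pairs, got {n}")
    if fit_type not in ("linear", "lowess"):
        raise ValueError(f"unknown fit_type {fit_type!r}")
    if fit_type == "lowess":
        if not 0 < frac <= 1:
            raise ValueError("frac must lie in (0, 1]")
        if frac * n < 3:
            raise ValueError(
                f"frac={frac} gives a local window of fewer than 3 of the "
                f"{n} points; increase frac"
            )
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    grid = np.asarray(grid, dtype=float)

    fitted = _fit_curve(x, y, grid, fit_type, frac)
    fitted_at_x = _fit_curve(x, y, x, fit_type, frac)
    ss_res = float(((y - fitted_at_x) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    pseudo_r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

    rng = np.random.default_rng(seed)
    boot = np.empty((n_bootstrap, len(grid)))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0:  # degenerate resample: flat line at the mean
            boot[b] = yb.mean()
            continue
        boot[b] = _fit_curve(xb, yb, grid, fit_type, frac)
    return TrendFit(
        x=x,
        y=y,
        fit_type=fit_type,
        frac=frac,
        grid=grid,
        fitted=fitted,
        fitted_at_x=fitted_at_x,
        boot_curves=boot,
        pseudo_r2=pseudo_r2,
    )


class TrendModel:
    """statsmodels-style wrapper: ``TrendModel(x, y, fit_type).fit()``."""

    def __init__(self, x, y, fit_type: str = "lowess", frac: float = 0.67):
        self.x = x
        self.y = y
        self.fit_type = fit_type
        self.frac = frac

    def fit(self, n_bootstrap: int = 1000, seed: int | None = None) -> TrendFit:
        return fit_trend(
            self.x,
            self.y,
            fit_type=self.fit_type,
            frac=self.frac,
            n_bootstrap=n_bootstrap,
            seed=seed,
        )
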