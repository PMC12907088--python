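"""Influent-concentration regression with outlier pruning and prediction intervals.

Class-total influent concentration is regressed on a plant covariate
(served population by default, designed capacity as an option) by ordinary
least squares. High-influence points are pruned iteratively — one point per
iteration, the largest Cook's distance first — until the fit reaches the
target R^2 or the retained set would shrink below a floor. Concentrations at
unsampled plants are then predicted with the standard new-observation
prediction interval

    y_hat +/- t(alpha/2, n-2) * sigma * sqrt(1 + 1/n + (x - x_bar)^2 / S_xx)

whose spread term also feeds the Monte-Carlo concentration uncertainty.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = ["RegressionFit", "Prediction", "fit_with_pruning", "predict_interval",
           "slope_confint", "default_min_n"]


@dataclass
class RegressionFit:
    """OLS fit bookkeeping needed for extrapolation with prediction intervals."""

    covariate: str
    slope: float
    intercept: float
    residual_sd: float
    n_retained: int
    r_squared: float
    x_mean: float
    s_xx: float
    retained_ids: list[str]
    excluded_ids: list[str]
    below_target: bool = False

    def predict_mean(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass
class Prediction:
    """Predicted concentration with a new-observation interval (ng/L)."""

    plant: str
    mean: float
    lower: float
    upper: float
    sd_pred: float


def default_min_n(n_points: int) -> int:
    """Pruning floor: max(10, 60% of the input points), never above n."""
    return min(n_points, max(10, math.ceil(0.6 * n_points)))


def _ols(x: np.ndarray, y: np.ndarray):
    X = sm.add_constant(x)
    return sm.OLS(y, X).fit()


def fit_with_pruning(
    points: Sequence[tuple[str, float, float]],
    target_r2: float = 0.95,
    min_n: int | None = None,
    covariate: str = "population",
) -> RegressionFit:
    """OLS fit with iterative influence-based outlier removal.

    While R^2 < ``target_r2`` and more than ``min_n`` points remain, the
    single point with the largest Cook's distance is removed (ties broken
    lexicographically by plant id) and the model refit. If the floor is
    reached below target, the fit is returned with ``below_target=True`` and
    a warning, not an error.
    """
    ids = [str(p[0]) for p in points]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate plant ids in regression points")
    x_all = np.array([float(p[1]) for p in points])
    y_all = np.array([float(p[2]) for p in points])
    if min_n is None:
        min_n = default_min_n(len(ids))
    min_n = max(min_n, 3)
    if len(ids) < min(min_n, 3):
        raise ValueError(f"need at least {min(min_n, 3)} points, got {len(ids)}")

    retained = list(range(len(ids)))
    excluded: list[str] = []
    while True:
        x = x_all[retained]
        y = y_all[retained]
        if np.ptp(x) == 0:
            raise ValueError("degenerate covariate: all x values equal")
        res = _ols(x, y)
        r2 = float(res.rsquared)
        if r2 >= target_r2 or len(retained) <= min_n:
            break
        cooks = OLSInfluence(res).cooks_distance[0]
        worst = np.max(cooks)
        candidates = [retained[i] for i in range(len(retained)) if np.isclose(cooks[i], worst)]
        drop = min(candidates, key=lambda j: ids[j])
        excluded.append(ids[drop])
        retained = [j for j in retained if j != drop]

    n = len(retained)
    dof = n - 2
    sigma = float(np.sqrt(res.ssr / dof)) if dof > 0 else 0.0
    below = r2 < target_r2
    if below:
        warnings.warn(
            f"pruning floor reached at n={n} with R^2={r2:.3f} < target {target_r2:.3f}"
        )
    x = x_all[retained]
    return RegressionFit(
        covariate=covariate,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        residual_sd=sigma,
        n_retained=n,
        r_squared=r2,
        x_mean=float(np.mean(x)),
        s_xx=float(np.sum((x - np.mean(x)) ** 2)),
        retained_ids=[ids[j] for j in retained],
        excluded_ids=excluded,
        below_target=below,
    )


def predict_interval(fit: RegressionFit, x: float, alpha_sig: float = 0.05,
                     plant: str = "") -> Prediction:
    """New-observation prediction at covariate value x.

    sd_pred = sigma * sqrt(1 + 1/n + (x - x_bar)^2 / S_xx); the interval is
    mean +/- t(alpha/2, n-2) * sd_pred, with the lower bound floored at 0
    for reporting (concentrations cannot be negative).
    """
    if not 0 < alpha_sig < 1:
        raise ValueError("alpha_sig must be in (0, 1)")
    if fit.n_retained < 3:
        raise ValueError("fit has fewer than 3 retained points")
    mean = fit.predict_mean(x)
    spread = math.sqrt(1.0 + 1.0 / fit.n_retained + (x - fit.x_mean) ** 2 / fit.s_xx)
    sd_pred = fit.residual_sd * spread
    t = stats.t.ppf(1.0 - alpha_sig / 2.0, fit.n_retained - 2)
    half = t * sd_pred
    return Prediction(
        plant=plant,
        mean=mean,
        lower=max(mean - half, 0.0),
        upper=mean + half,
        sd_pred=sd_pred,
    )


def slope_confint(fit: RegressionFit, alpha_sig: float = 0.05) -> tuple[float, float]:
    """Two-sided confidence interval for the fitted slope."""
    if fit.s_xx <= 0 or fit.n_retained < 3:
        raise ValueError("fit cannot support a slope interval")
    se = fit.residual_sd / math.sqrt(fit.s_xx)
    t = stats.t.ppf(1.0 - alpha_sig / 2.0, fit.n_retained - 2)
    return fit.slope - t * se, fit.slope + t * se


def fit_to_frame(fits: dict[str, RegressionFit]) -> pd.DataFrame:
    rows = []
    for label, f in fits.items():
        rows.append(
            {
                "response": label, "covariate": f.covariate, "slope": f.slope,
                "intercept": f.intercept, "residual_sd": f.residual_sd,
                "n_retained": f.n_retained, "r_squared": f.r_squared,
                "x_mean": f.x_mean, "s_xx": f.s_xx,
                "excluded_ids": ";".join(f.excluded_ids),
                "below_target": f.below_target,
            }
        )
    return pd.DataFrame(rows)
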