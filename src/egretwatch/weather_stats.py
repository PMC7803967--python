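"""Detrended multivariable regression of log-counts on weather factors.

Log-counts and each of the 12 weather factors are detrended by removing an
OLS quadratic in the day index; the detrended log-count is then regressed
on the detrended factors without an intercept.  A preliminary test (HT3)
asks whether a linear time term is significant alongside the raw factors,
i.e. whether detrending is warranted at all.

Model statistics (t, F, R^2) are computed on the uncentred residual sums
of squares, with the residual degrees of freedom optionally reduced to
account for the trend parameters absorbed by the detrending step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import FACTOR_COLUMNS

__all__ = [
    "TABLE1_NAMES",
    "wind_components",
    "detrend",
    "DetrendFit",
    "ht3_time_test",
    "fit_regression",
    "RegressionReport",
    "analyze",
    "report_markdown",
]

TABLE1_NAMES = {
    "mean_pressure_hpa": "Mean pressure (hPa)",
    "abs_max_temp_c": "Absolute maximum daily temperature (°C)",
    "mean_temp_c": "Daily mean temperature (°C)",
    "abs_min_temp_c": "Absolute minimum daily temperature (°C)",
    "mean_dew_point_c": "Mean dew point (°C)",
    "mean_rel_humidity_pct": "Mean relative humidity (%)",
    "mean_cloud_pct": "Mean amount of cloud (%)",
    "total_rainfall_mm": "Total rainfall (mm)",
    "total_bright_sunshine_h": "Total bright sunshine (hours)",
    "mean_wind_speed_kmh": "Mean wind speed (km/h)",
    "wind_dir_ew_deg": "Prevailing wind direction (EW, °)",
    "wind_dir_ns_deg": "Prevailing wind direction (NS, °)",
}


def wind_components(direction_deg: float, scale: float = 90.0) -> tuple[float, float]:
    """Encode a circular wind direction as (EW, NS) components.

    North is 0°, east 90°; components are sin/cos scaled to ``scale`` so
    the units read as degrees.
    """
    if not (0.0 <= direction_deg < 360.0):
        raise ValueError("direction must lie in [0, 360)")
    rad = np.deg2rad(direction_deg)
    return float(np.sin(rad) * scale), float(np.cos(rad) * scale)


@dataclass
class DetrendFit:
    coefficients: np.ndarray  # (const, t, t^2)
    residuals: np.ndarray
    fitted: np.ndarray


def detrend(series: np.ndarray, t_index: np.ndarray | None = None) -> DetrendFit:
    """Remove an OLS quadratic-in-time component.

    The time basis is centred and scaled internally for conditioning; the
    returned coefficients are on the raw ``(1, t, t^2)`` basis.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 observations to fit a quadratic trend")
    t = np.arange(n, dtype=float) if t_index is None else np.asarray(t_index, float)
    if np.ptp(t) == 0:
        raise ValueError("time index is constant")
    tc = (t - t.mean()) / t.std()
    design = np.column_stack([np.ones(n), tc, tc**2])
    coef_c, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef_c
    # map back to the raw polynomial basis
    mu, sd = t.mean(), t.std()
    a2 = coef_c[2] / sd**2
    a1 = coef_c[1] / sd - 2 * coef_c[2] * mu / sd**2
    a0 = coef_c[0] - coef_c[1] * mu / sd + coef_c[2] * mu**2 / sd**2
    return DetrendFit(np.array([a0, a1, a2]), y - fitted, fitted)


@dataclass
class RegressionReport:
    factor_names: list
    beta: np.ndarray
    se: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r_squared: float
    f_statistic: float
    f_p_value: float
    n_obs: int
    df_resid: int
    fitted: np.ndarray
    condition_number: float
    intercept: float | None = None
    significance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.significance = [
            "*" if p < 0.05 else ("**" if p < 0.10 else "") for p in self.p_values
        ]


def fit_regression(
    y: np.ndarray,
    X: np.ndarray,
    factor_names: list | None = None,
    intercept: bool = False,
    dof_adjust: int = 0,
) -> RegressionReport:
    """Least-squares fit of (detrended) response on (detrended) factors.

    No intercept by default — the detrended variables already carry no
    polynomial-trend component.  ``dof_adjust`` subtracts additional
    residual degrees of freedom consumed upstream (3 per detrended
    variable set when used after :func:`detrend`).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    names = list(factor_names) if factor_names is not None else [f"x{i}" for i in range(p)]
    design = np.column_stack([np.ones(n), X]) if intercept else X
    k = design.shape[1]
    df_resid = n - k - dof_adjust
    if df_resid <= 0:
        raise ValueError("not enough observations for the number of factors")
    cond = float(np.linalg.cond(design))
    if cond > 1e12:
        raise ValueError(f"singular design matrix (condition number {cond:.3g})")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    resid = y - fitted
    ssr = float(resid @ resid)
    sst = float(y @ y) if not intercept else float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    sigma2 = ssr / df_resid
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se_all = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = np.where(se_all > 0, coef / se_all, 0.0)
    p_all = 2.0 * stats.t.sf(np.abs(t_all), df_resid)
    if ssr > 0:
        f_stat = ((sst - ssr) / k) / sigma2
        f_p = float(stats.f.sf(f_stat, k, df_resid))
    else:
        f_stat, f_p = np.inf, 0.0
    off = 1 if intercept else 0
    return RegressionReport(
        factor_names=names,
        beta=coef[off:],
        se=se_all[off:],
        t_values=t_all[off:],
        p_values=p_all[off:],
        r_squared=float(r2),
        f_statistic=float(f_stat),
        f_p_value=f_p,
        n_obs=n,
        df_resid=df_resid,
        fitted=fitted,
        condition_number=cond,
        intercept=float(coef[0]) if intercept else None,
    )


def ht3_time_test(
    ln_counts: np.ndarray, weather: np.ndarray, t_index: np.ndarray | None = None
) -> dict:
    """Does time influence the count-weather relationship?

    Fits ln-count on intercept + factors + linear time and runs a
    two-tailed t-test on the time coefficient.  A perfect (zero-residual)
    fit is flagged degenerate with p = 0.
    """
    y = np.asarray(ln_counts, float)
    X = np.asarray(weather, float)
    n = len(y)
    t = np.arange(n, dtype=float) if t_index is None else np.asarray(t_index, float)
    tc = (t - t.mean()) / t.std()
    design = np.column_stack([np.ones(n), X, tc])
    k = design.shape[1]
    if n <= k:
        raise ValueError("not enough observations")
    cond = float(np.linalg.cond(design))
    if cond > 1e12:
        raise ValueError("collinear design in HT3")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ssr = float(resid @ resid)
    df = n - k
    if ssr <= 1e-12 * max(float(y @ y), 1.0):
        return {"t": np.inf, "p": 0.0, "reject": True, "degenerate": True}
    sigma2 = ssr / df
    cov = sigma2 * np.linalg.inv(design.T @ design)
    t_stat = coef[-1] / np.sqrt(cov[-1, -1])
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return {"t": float(t_stat), "p": p, "reject": bool(p < 0.05), "degenerate": False}


def analyze(
    weather: pd.DataFrame,
    counts: pd.Series | None = None,
    factor_columns: list | None = None,
    intercept: bool = False,
) -> dict:
    """Full pipeline: HT3, quadratic detrending, no-intercept regression.

    ``weather`` carries one row per day with the 12 factor columns; counts
    default to its ``count_all`` column.  Returns the HT3 report, the
    detrend fits and the :class:`RegressionReport`.
    """
    cols = factor_columns or FACTOR_COLUMNS
    y = np.log(
        (counts if counts is not None else weather["count_all"]).to_numpy(float)
    )
    if not np.all(np.isfinite(y)):
        raise ValueError("counts must be positive")
    X = weather[cols].to_numpy(float)
    ht3 = ht3_time_test(y, X)
    y_fit = detrend(y)
    x_fits = [detrend(X[:, i]) for i in range(X.shape[1])]
    Xd = np.column_stack([f.residuals for f in x_fits])
    report = fit_regression(
        y_fit.residuals, Xd, factor_names=cols, intercept=intercept, dof_adjust=3
    )
    return {"ht3": ht3, "count_trend": y_fit, "factor_trends": x_fits, "regression": report}


def report_markdown(report: RegressionReport, ht3: dict | None = None) -> str:
    """Table-style markdown summary of the regression fit."""
    lines = [
        "# Multivariable linear regression analysis",
        "",
        "## Overall model fit",
        f"- Number of observations: {report.n_obs}",
        f"- R^2: {report.r_squared:.3f}",
        f"- p-value (F-test): {report.f_p_value:.3f}",
    ]
    if ht3 is not None:
        lines.append(f"- HT3 time-influence p-value: {ht3['p']:.3f}")
    lines += [
        "",
        "## Parameter estimates",
        "| Independent variable | Coefficient | p-value (Student's t-test) | |",
        "|---|---|---|---|",
    ]
    for name, b, p, mark in zip(
        report.factor_names, report.beta, report.p_values, report.significance
    ):
        pretty = TABLE1_NAMES.get(name, name)
        lines.append(f"| {pretty} | {b:.4f} | {p:.3f} | {mark} |")
    lines += [
        "",
        "`*` p < 0.05 (statistically significant); `**` p < 0.10 (marginally significant).",
    ]
    return "\n".join(lines)
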