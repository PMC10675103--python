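"""Distributional screening and Box-Cox normalisation.

Each (water, cycle) slice of a response variable is screened before
modelling: Anderson-Darling on the pooled within-cell residuals (cell
means differ by design, so raw values are never tested directly) and
Bartlett's test for variance homogeneity across the 20 design cells.
If either test rejects at level alpha, the one-parameter Box-Cox
transform

    y = (x**lam - 1) / lam        (lam != 0)
    y = log(x)                    (lam == 0, the analytic limit)

is applied with lambda chosen by profile log-likelihood over a fixed
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad

from .exceptions import ConfigError, DegenerateDataError
from .simulate import IRRIGATION_LEVELS, SAMPLING_DAYS

LAMBDA_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 2)
MIN_LAMBDA_N = 8


@dataclass(frozen=True)
class ScreeningReport:
    """Outcome of the normality / homoscedasticity screen for one slice."""

    variable: str
    group_key: tuple  # (water, cycle)
    ad_statistic: float
    ad_p: float
    bartlett_statistic: float
    bartlett_p: float
    normal: bool
    homoscedastic: bool
    lambda_used: float | None
    alpha: float

    def to_dict(self) -> dict:
        payload = asdict(self)
        payload["group_key"] = list(self.group_key)
        return payload


def boxcox_transform(x, lam: float):
    """One-parameter Box-Cox transform, elementwise; requires x > 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DegenerateDataError(
            "Box-Cox transform requires strictly positive values"
        )
    if lam == 0.0:
        out = np.log(x)
    else:
        out = (np.power(x, lam) - 1.0) / lam
    return out if out.ndim else float(out)


def inverse_boxcox(y, lam: float):
    """Inverse of :func:`boxcox_transform`."""
    y = np.asarray(y, dtype=float)
    if lam == 0.0:
        out = np.exp(y)
    else:
        out = np.power(lam * y + 1.0, 1.0 / lam)
    return out if out.ndim else float(out)


def select_lambda(values) -> float:
    """Box-Cox lambda maximising the profile log-likelihood on the grid.

    The grid spans [-2, 2] in steps of 0.01; ties resolve to the smallest
    lambda, so the choice is deterministic for a fixed input.
    """
    values = np.asarray(values, dtype=float)
    if values.size < MIN_LAMBDA_N:
        raise DegenerateDataError(
            f"need at least {MIN_LAMBDA_N} values to select lambda"
        )
    if np.any(values <= 0):
        raise DegenerateDataError("lambda selection requires positive values")
    if np.ptp(values) == 0.0:
        raise DegenerateDataError("constant vector: lambda is undefined")
    llf = np.array([stats.boxcox_llf(lam, values) for lam in LAMBDA_GRID])
    return float(LAMBDA_GRID[int(np.argmax(llf))])


def _slice_residuals(subset: pd.DataFrame, variable: str):
    """Within-cell residuals and per-cell value lists for one slice."""
    groups = []
    residuals = []
    for dat in SAMPLING_DAYS:
        for il in IRRIGATION_LEVELS:
            cell = subset[(subset["dat"] == dat)
                          & (subset["irrigation_level"] == il)]
            if cell.empty:
                raise ConfigError(
                    f"design cell dat={dat}, irrigation_level={il} is empty"
                )
            if len(cell) < 2:
                raise DegenerateDataError(
                    f"Bartlett's test needs >= 2 replicates per cell; "
                    f"cell dat={dat}, irrigation_level={il} has {len(cell)}"
                )
            values = cell[variable].to_numpy(dtype=float)
            groups.append(values)
            residuals.append(values - values.mean())
    return np.concatenate(residuals), groups


def screen(records: pd.DataFrame, variable: str, water: str, cycle: int,
           alpha: float = 0.05) -> ScreeningReport:
    """Screen one (water, cycle) slice of ``variable``.

    Anderson-Darling runs on the pooled residuals, Bartlett across the
    20 cells; when either rejects at ``alpha`` a Box-Cox lambda is fitted
    on the raw (positive) values and recorded in the report.
    """
    subset = records[(records["water"] == water)
                     & (records["cycle"] == cycle)]
    if subset.empty:
        raise ConfigError(f"no records for water={water!r} cycle={cycle}")
    residuals, groups = _slice_residuals(subset, variable)
    if np.ptp(residuals) == 0.0:
        raise DegenerateDataError(
            "residuals are identically zero; screening is undefined "
            "(noise-free data)"
        )
    ad_stat, ad_p = normal_ad(residuals)
    bart_stat, bart_p = stats.bartlett(*groups)
    normal = bool(ad_p >= alpha)
    homoscedastic = bool(bart_p >= alpha)
    lambda_used = None
    if not (normal and homoscedastic):
        lambda_used = select_lambda(subset[variable].to_numpy(dtype=float))
    return ScreeningReport(
        variable=variable, group_key=(water, cycle),
        ad_statistic=float(ad_stat), ad_p=float(ad_p),
        bartlett_statistic=float(bart_stat), bartlett_p=float(bart_p),
        normal=normal, homoscedastic=homoscedastic,
        lambda_used=lambda_used, alpha=alpha,
    )


def apply_screening(records: pd.DataFrame, variable: str,
                    report: ScreeningReport) -> pd.DataFrame:
    """Return a copy of the slice with the transform applied when needed."""
    water, cycle = report.group_key
    subset = records[(records["water"] == water)
                     & (records["cycle"] == cycle)].copy()
    if report.lambda_used is not None:
        subset[variable] = boxcox_transform(
            subset[variable].to_numpy(dtype=float), report.lambda_used
        )
    return subset


def screen_all(records: pd.DataFrame, variables,
               alpha: float = 0.05) -> list[ScreeningReport]:
    """Screen every (variable, water, cycle) combination in the table."""
    reports = []
    for variable in variables:
        for water in sorted(records["water"].unique()):
            for cycle in sorted(int(c) for c in records["cycle"].unique()):
                reports.append(
                    screen(records, variable, water, cycle, alpha=alpha)
                )
    return reports
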