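"""Association metrics and the fuzzy-vs-regression comparison.

Three criteria quantify how well a model tracks the observations:

    MSE  mean squared error, sum((obs - pred)^2) / n
    r    Pearson product-moment correlation
    d    Willmott index of agreement,
         1 - sum((pred - obs)^2) / sum((|pred - obar| + |obs - obar|)^2)

with obar the observed mean.  d is 1 for a perfect model and 0 for a
model that predicts the observed mean everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, DegenerateDataError
from .inference import FuzzyModel, _infer_grid
from .regression import PolynomialModel, predict
from .simulate import (IRRIGATION_LEVELS, RESPONSE_VARIABLES, SAMPLING_DAYS,
                       cell_means)


@dataclass(frozen=True)
class FitMetrics:
    """MSE / r / d for one (model, variable, water, cycle) combination."""

    mse: float
    r: float
    d: float
    n: int
    model_kind: str  # "fuzzy" | "regression"
    variable: str = ""
    water: str = ""
    cycle: int = 0
    r_p: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def _paired(observed, predicted):
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ConfigError("observed and predicted must be equal-length 1-D")
    return observed, predicted


def mse(observed, predicted) -> float:
    """Mean squared error over paired observations."""
    observed, predicted = _paired(observed, predicted)
    if observed.size == 0:
        raise ConfigError("mse needs at least one pair")
    return float(np.mean((observed - predicted) ** 2))


def pearson_r(observed, predicted) -> float:
    """Product-moment correlation between observations and predictions."""
    observed, predicted = _paired(observed, predicted)
    if observed.size < 3:
        raise ConfigError("pearson_r needs at least 3 pairs")
    if np.ptp(observed) == 0.0 or np.ptp(predicted) == 0.0:
        raise DegenerateDataError(
            "correlation undefined for a constant vector"
        )
    return float(stats.pearsonr(observed, predicted).statistic)


def willmott_d(observed, predicted) -> float:
    """Willmott index of agreement (observed-mean reference)."""
    observed, predicted = _paired(observed, predicted)
    if observed.size < 2:
        raise ConfigError("willmott_d needs at least 2 pairs")
    obar = observed.mean()
    denom = np.sum((np.abs(predicted - obar) + np.abs(observed - obar)) ** 2)
    if denom <= 0.0:
        raise DegenerateDataError(
            "Willmott denominator is zero: all values equal the observed mean"
        )
    return float(1.0 - np.sum((predicted - observed) ** 2) / denom)


def fit_metrics(observed, predicted, model_kind: str, variable: str = "",
                water: str = "", cycle: int = 0) -> FitMetrics:
    observed, predicted = _paired(observed, predicted)
    r = pearson_r(observed, predicted)
    r_p = float(stats.pearsonr(observed, predicted).pvalue)
    return FitMetrics(
        mse=mse(observed, predicted), r=r, d=willmott_d(observed, predicted),
        n=observed.size, model_kind=model_kind, variable=variable,
        water=water, cycle=cycle, r_p=r_p,
    )


def _design_points():
    dats, ils = [], []
    for dat in SAMPLING_DAYS:
        for il in IRRIGATION_LEVELS:
            dats.append(float(dat))
            ils.append(float(il))
    return np.array(dats), np.array(ils)


def compare_models(records: pd.DataFrame, fuzzy_model: FuzzyModel,
                   poly_model: PolynomialModel, variable: str,
                   replicate_level: bool = False
                   ) -> tuple[FitMetrics, FitMetrics]:
    """Score both models on the same (water, cycle) slice.

    By default predictions are paired with the 20 per-cell means — the
    quantities the fuzzy rules were induced from; ``replicate_level=True``
    pairs them with every replicate instead.
    """
    water, cycle = fuzzy_model.water, fuzzy_model.cycle
    subset = records[(records["water"] == water)
                     & (records["cycle"] == cycle)]
    if subset.empty:
        raise ConfigError(f"no records for water={water!r} cycle={cycle}")
    means = cell_means(subset, variable)
    if replicate_level:
        dats = subset["dat"].to_numpy(dtype=float)
        ils = subset["irrigation_level"].to_numpy(dtype=float)
        observed = subset[variable].to_numpy(dtype=float)
        fuzzy_pred = np.array([
            _infer_grid(fuzzy_model, [d], [il],
                        variables=[variable])[variable][0, 0]
            for d, il in zip(dats, ils)
        ])
    else:
        dats, ils = _design_points()
        observed = np.array([
            means[(water, cycle, int(d), int(il))]
            for d, il in zip(dats, ils)
        ])
        grid = _infer_grid(fuzzy_model, sorted(set(dats)), sorted(set(ils)),
                           variables=[variable])[variable]
        dat_order = {d: i for i, d in enumerate(sorted(set(dats)))}
        il_order = {il: j for j, il in enumerate(sorted(set(ils)))}
        fuzzy_pred = np.array([
            grid[dat_order[d], il_order[il]] for d, il in zip(dats, ils)
        ])
    poly_pred = predict(poly_model, dats, ils, water=water)
    fuzzy_metrics = fit_metrics(observed, fuzzy_pred, "fuzzy", variable,
                                water, cycle)
    poly_metrics = fit_metrics(observed, np.asarray(poly_pred, dtype=float),
                               "regression", variable, water, cycle)
    return fuzzy_metrics, poly_metrics


def comparison_table(records: pd.DataFrame,
                     fuzzy_models: dict, poly_models: dict,
                     variables=RESPONSE_VARIABLES,
                     replicate_level: bool = False) -> pd.DataFrame:
    """Long-format comparison across variables, waters, models and cycles.

    ``fuzzy_models`` and ``poly_models`` are keyed by (water, cycle); for
    polynomial models the key is (water, cycle, variable).  The result has
    one row per (variable, water, model_kind, cycle) with MSE, r and d —
    2 model kinds x 5 variables x 2 waters x 2 cycles = 40 rows for a full
    two-cycle design.
    """
    rows = []
    for variable in variables:
        for (water, cycle), fuzzy_model in sorted(fuzzy_models.items()):
            poly_model = poly_models[(water, cycle, variable)]
            fm, pm = compare_models(records, fuzzy_model, poly_model,
                                    variable, replicate_level=replicate_level)
            for m in (fm, pm):
                rows.append({
                    "variable": variable, "water": water,
                    "model": m.model_kind, "cycle": cycle,
                    "mse": m.mse, "r": m.r, "r_p": m.r_p, "d": m.d,
                    "n": m.n,
                })
    return pd.DataFrame(rows)
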