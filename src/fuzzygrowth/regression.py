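"""Cubic polynomial-regression baseline.

For each (water, cycle) slice the response is modelled by ordinary least
squares on the seven-term additive cubic

    y = b0 + a1*IL + a2*IL^2 + a3*IL^3 + b1*DAT + b2*DAT^2 + b3*DAT^3

with no interaction terms, reporting R^2, the overall F test and
two-sided t tests per coefficient.  A pooled mode replaces the per-slice
fits by a single model with a binary water-source dummy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ConfigError

TERM_NAMES = ("intercept", "il", "il2", "il3", "dat", "dat2", "dat3")
ALPHA_DEFAULT = 0.05


@dataclass
class PolynomialModel:
    """Fitted cubic response surface with its inference statistics."""

    beta0: float
    a1: float
    a2: float
    a3: float
    b1: float
    b2: float
    b3: float
    r_squared: float
    f_statistic: float
    model_p: float
    coef_p: dict[str, float]
    variable: str = ""
    water: str = ""
    cycle: int = 0
    water_dummy: float | None = None  # pooled mode only
    n_obs: int = 0
    alpha: float = ALPHA_DEFAULT

    @property
    def coefficients(self) -> dict[str, float]:
        return {"intercept": self.beta0, "il": self.a1, "il2": self.a2,
                "il3": self.a3, "dat": self.b1, "dat2": self.b2,
                "dat3": self.b3}

    def significant_terms(self) -> list[str]:
        return [t for t, p in self.coef_p.items() if p < self.alpha]

    def to_dict(self) -> dict:
        payload = {
            "variable": self.variable, "water": self.water,
            "cycle": self.cycle, "n_obs": self.n_obs, "alpha": self.alpha,
            "coefficients": self.coefficients,
            "r_squared": self.r_squared,
            "f_statistic": self.f_statistic,
            "model_p": self.model_p,
            "coef_p": dict(self.coef_p),
        }
        if self.water_dummy is not None:
            payload["water_dummy"] = self.water_dummy
        return payload

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, payload: dict) -> "PolynomialModel":
        coef = payload["coefficients"]
        return cls(
            beta0=coef["intercept"], a1=coef["il"], a2=coef["il2"],
            a3=coef["il3"], b1=coef["dat"], b2=coef["dat2"], b3=coef["dat3"],
            r_squared=payload["r_squared"],
            f_statistic=payload["f_statistic"],
            model_p=payload["model_p"],
            coef_p=dict(payload["coef_p"]),
            variable=payload.get("variable", ""),
            water=payload.get("water", ""),
            cycle=payload.get("cycle", 0),
            water_dummy=payload.get("water_dummy"),
            n_obs=payload.get("n_obs", 0),
            alpha=payload.get("alpha", ALPHA_DEFAULT),
        )

    @classmethod
    def load(cls, path) -> "PolynomialModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _design_matrix(il: np.ndarray, dat: np.ndarray,
                   water_dummy: np.ndarray | None = None) -> np.ndarray:
    columns = [np.ones_like(il), il, il ** 2, il ** 3,
               dat, dat ** 2, dat ** 3]
    if water_dummy is not None:
        columns.append(water_dummy)
    return np.column_stack(columns)


def fit_polynomial(records: pd.DataFrame, variable: str,
                   water: str | None = None, cycle: int | None = None,
                   pooled: bool = False,
                   alpha: float = ALPHA_DEFAULT) -> PolynomialModel:
    """Fit the seven-term cubic by OLS on one (water, cycle) slice.

    With ``pooled=True`` the water/cycle filters are ignored and a single
    model with an extra binary water dummy (CW = 0, MW = 1) is fitted to
    the whole table instead.
    """
    subset = records
    if not pooled:
        if water is not None:
            subset = subset[subset["water"] == water]
        if cycle is not None:
            subset = subset[subset["cycle"] == cycle]
    if subset.empty:
        raise ConfigError(
            f"no records for water={water!r} cycle={cycle!r}"
        )
    il = subset["irrigation_level"].to_numpy(dtype=float)
    dat = subset["dat"].to_numpy(dtype=float)
    y = subset[variable].to_numpy(dtype=float)

    n_params = 8 if pooled else 7
    if len(y) < n_params + 2:
        raise ConfigError(
            f"need at least {n_params + 2} observations to fit "
            f"{n_params} parameters, got {len(y)}"
        )
    if len(np.unique(il)) < 4 or len(np.unique(dat)) < 4:
        raise ConfigError(
            "cubic terms need at least 4 distinct irrigation levels and "
            "4 distinct sampling days"
        )
    dummy = None
    if pooled:
        dummy = (subset["water"] == "MW").to_numpy(dtype=float)
    design = _design_matrix(il, dat, dummy)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ConfigError("design matrix is rank-deficient")

    fit = sm.OLS(y, design).fit()
    params = fit.params
    coef_p = {name: float(p) for name, p in zip(TERM_NAMES, fit.pvalues)}
    model = PolynomialModel(
        beta0=float(params[0]), a1=float(params[1]), a2=float(params[2]),
        a3=float(params[3]), b1=float(params[4]), b2=float(params[5]),
        b3=float(params[6]),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        model_p=float(fit.f_pvalue),
        coef_p=coef_p,
        variable=variable,
        water="" if pooled else (water or ""),
        cycle=0 if pooled or cycle is None else cycle,
        water_dummy=float(params[7]) if pooled else None,
        n_obs=int(fit.nobs),
        alpha=alpha,
    )
    if pooled:
        model.coef_p["water_dummy"] = float(fit.pvalues[7])
    return model


def predict(model: PolynomialModel, dat, irrigation_level,
            water: str | None = None):
    """Evaluate the fitted surface; vectorized over the inputs."""
    il = np.asarray(irrigation_level, dtype=float)
    dat = np.asarray(dat, dtype=float)
    value = (model.beta0
             + model.a1 * il + model.a2 * il ** 2 + model.a3 * il ** 3
             + model.b1 * dat + model.b2 * dat ** 2 + model.b3 * dat ** 3)
    if model.water_dummy is not None and water == "MW":
        value = value + model.water_dummy
    return value if np.ndim(value) else float(value)


def coefficient_table(models: list[PolynomialModel]) -> pd.DataFrame:
    """Coefficient summary, one row per fitted model."""
    rows = []
    for m in models:
        row = {"variable": m.variable, "water": m.water, "cycle": m.cycle}
        row.update(m.coefficients)
        row.update({"r_squared": m.r_squared, "f_statistic": m.f_statistic,
                    "model_p": m.model_p})
        rows.append(row)
    return pd.DataFrame(rows)
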