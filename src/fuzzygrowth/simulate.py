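"""Synthetic factorial growth experiments.

Emulates a 5 x 2 factorial lettuce trial: five irrigation levels (25, 50,
75, 100, 125 % of crop evapotranspiration, ETc) crossed with two water
sources (magnetically treated, MW, and conventional, CW), sampled at 14,
21, 28 and 35 days after transplanting (DAT) with replicated measurements
of five biometric responses per plant:

    ln   leaf number (count)
    fsb  fresh shoot biomass (g)
    frb  fresh root biomass (g)
    dsb  dry shoot biomass (g)
    drb  dry root biomass (g)

The mean surface is logistic in time, unimodal (quadratic, floored at
zero) in irrigation level, and carries a multiplicative water-source gain;
replicate noise is either mean-proportional Gaussian or right-skewed
(multiplicative lognormal with matched coefficient of variation), so both
normal-theory and transformation-requiring regimes can be produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError, MissingCellError

IRRIGATION_LEVELS = (25, 50, 75, 100, 125)
SAMPLING_DAYS = (14, 21, 28, 35)
WATER_TYPES = ("MW", "CW")
RESPONSE_VARIABLES = ("ln", "fsb", "frb", "dsb", "drb")

#: tidy-table column order, also the CSV header
BIOMETRIC_COLUMNS = (
    "cycle", "water", "irrigation_level", "dat", "replicate",
    "ln", "fsb", "frb", "dsb", "drb",
)

_DEFAULT_ASYMPTOTES = {
    # plateau values typical of a mature crisphead lettuce plant
    "ln": 30.0,    # leaves
    "fsb": 250.0,  # g fresh shoot
    "frb": 30.0,   # g fresh root
    "dsb": 12.0,   # g dry shoot
    "drb": 3.0,    # g dry root
}


@dataclass(frozen=True)
class BiometricRecord:
    """One replicate measurement at a design cell."""

    cycle: int
    water: str
    irrigation_level: int
    dat: int
    replicate: int
    ln: float
    fsb: float
    frb: float
    dsb: float
    drb: float


@dataclass(frozen=True)
class GrowthSimConfig:
    """Parameters of the synthetic mean surface and replicate noise.

    The mean response for variable ``v`` at a cell is::

        asymptote[v] * logistic(dat; growth_rate, growth_midpoint)
                     * max(0, 1 - il_curvature * (IL - il_optimum)**2)
                     * (water_effect if MW else 1)

    ``noise_sd`` is the residual scale as a fraction of the cell mean
    (a coefficient of variation); ``noise_family`` selects symmetric
    Gaussian or right-skewed lognormal residuals.
    """

    n_replicates: int = 4
    cycles: tuple[int, ...] = (1, 2)
    water_effect: float = 1.15
    il_optimum: float = 100.0
    il_curvature: float = 1.0e-4
    growth_rate: float = 0.25
    growth_midpoint: float = 24.5
    asymptote_per_variable: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ASYMPTOTES)
    )
    noise_sd: float = 0.08
    noise_family: str = "symmetric"
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not self.cycles:
            raise ConfigError("cycles must be non-empty")
        if self.water_effect < 0:
            raise ConfigError("water_effect must be >= 0")
        if not 25 <= self.il_optimum <= 125:
            raise ConfigError("il_optimum must lie within [25, 125]")
        if self.il_curvature < 0:
            raise ConfigError("il_curvature must be >= 0")
        if self.growth_rate <= 0:
            raise ConfigError("growth_rate must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.noise_family not in ("symmetric", "right-skewed"):
            raise ConfigError(
                "noise_family must be 'symmetric' or 'right-skewed'"
            )
        missing = [v for v in RESPONSE_VARIABLES
                   if v not in self.asymptote_per_variable]
        if missing:
            raise ConfigError(
                f"asymptote_per_variable missing entries for {missing}"
            )
        if any(a <= 0 for a in self.asymptote_per_variable.values()):
            raise ConfigError("asymptote_per_variable values must be > 0")

    def with_seed(self, seed: int) -> "GrowthSimConfig":
        return replace(self, seed=seed)


def mean_response(config: GrowthSimConfig, variable: str,
                  dat, irrigation_level, water: str = "CW"):
    """Noise-free mean surface; vectorized over ``dat`` / ``irrigation_level``."""
    dat = np.asarray(dat, dtype=float)
    il = np.asarray(irrigation_level, dtype=float)
    growth = 1.0 / (1.0 + np.exp(-config.growth_rate
                                 * (dat - config.growth_midpoint)))
    irrigation = np.maximum(
        0.0, 1.0 - config.il_curvature * (il - config.il_optimum) ** 2
    )
    gain = config.water_effect if water == "MW" else 1.0
    return config.asymptote_per_variable[variable] * growth * irrigation * gain


def generate_experiment(config: GrowthSimConfig) -> pd.DataFrame:
    """Draw a complete factorial experiment table.

    Returns a tidy DataFrame with one row per replicate measurement and
    the :data:`BIOMETRIC_COLUMNS` schema; row count is exactly
    ``|cycles| * 2 waters * 5 levels * 4 samplings * n_replicates``.
    Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    rows = []
    for cycle in config.cycles:
        for water in WATER_TYPES:
            for il in IRRIGATION_LEVELS:
                for dat in SAMPLING_DAYS:
                    for rep in range(1, config.n_replicates + 1):
                        rows.append((cycle, water, il, dat, rep))
    frame = pd.DataFrame(rows, columns=BIOMETRIC_COLUMNS[:5])

    n = len(frame)
    shocks = rng.standard_normal((n, len(RESPONSE_VARIABLES)))
    dat = frame["dat"].to_numpy(dtype=float)
    il = frame["irrigation_level"].to_numpy(dtype=float)
    gain = np.where(frame["water"].to_numpy() == "MW",
                    config.water_effect, 1.0)
    growth = 1.0 / (1.0 + np.exp(-config.growth_rate
                                 * (dat - config.growth_midpoint)))
    irrigation = np.maximum(
        0.0, 1.0 - config.il_curvature * (il - config.il_optimum) ** 2
    )
    base = growth * irrigation * gain
    for j, var in enumerate(RESPONSE_VARIABLES):
        mean = config.asymptote_per_variable[var] * base
        if config.noise_family == "symmetric":
            values = mean * (1.0 + config.noise_sd * shocks[:, j])
        else:
            # lognormal multiplicative noise with E[factor] = 1 and
            # CV = noise_sd, so the cell mean is preserved
            sd_log = np.sqrt(np.log1p(config.noise_sd ** 2))
            values = mean * np.exp(sd_log * shocks[:, j] - 0.5 * sd_log ** 2)
        values = np.maximum(values, 0.0)
        if var == "ln":
            values = np.round(values)
        frame[var] = values
    return frame


def validate_table(records: pd.DataFrame) -> None:
    """Check the tidy-table schema and the uniqueness of the design key."""
    missing = [c for c in BIOMETRIC_COLUMNS if c not in records.columns]
    if missing:
        raise ConfigError(f"experiment table missing columns {missing}")
    key = ["cycle", "water", "irrigation_level", "dat", "replicate"]
    if records.duplicated(subset=key).any():
        raise ConfigError(
            "duplicate (cycle, water, irrigation_level, dat, replicate) keys"
        )


def cell_means(records: pd.DataFrame, variable: str) -> dict:
    """Mean of ``variable`` over replicates, per design cell.

    Returns ``{(water, cycle, dat, irrigation_level): mean}``.  Every
    (water, cycle) pair present in the table must cover all 20
    (dat, irrigation_level) cells.
    """
    if variable not in RESPONSE_VARIABLES:
        raise ConfigError(
            f"unknown variable {variable!r}; expected one of "
            f"{RESPONSE_VARIABLES}"
        )
    grouped = records.groupby(
        ["water", "cycle", "dat", "irrigation_level"], sort=True
    )[variable].mean()
    means = {key: float(v) for key, v in grouped.items()}
    for (water, cycle) in {(w, c) for (w, c, _, _) in means}:
        for dat in SAMPLING_DAYS:
            for il in IRRIGATION_LEVELS:
                if (water, cycle, dat, il) not in means:
                    raise MissingCellError(
                        f"no records for water={water} cycle={cycle} "
                        f"dat={dat} irrigation_level={il}"
                    )
    return means
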