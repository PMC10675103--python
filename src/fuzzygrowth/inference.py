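"""Mamdani inference with discrete-centroid defuzzification.

The classical configuration is used throughout: AND = min over antecedent
memberships, implication = min (clipping each consequent set at the rule's
firing strength), aggregation = max over rules, and the crisp output is
the discrete centroid

    y = sum_x mu(x) * x / sum_x mu(x)

evaluated on a uniform grid spanning the output universe (the first set's
lower foot to the last set's upper foot).  Crisp inputs are clipped to
the modelled rectangle [14, 35] DAT x [25, 125] % ETc; the model cannot
extrapolate beyond the fuzzy-set supports.

Surface simulation is vectorised; a single ``infer`` call runs the same
code path on a 1 x 1 grid, so surface nodes and point queries agree
bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DefuzzificationError
from .partitions import (FuzzyPartition, OutputPartitionSpec, dat_partition,
                         irrigation_partition, build_output_partition)
from .rules import FuzzyRule, build_rule_base
from .simulate import RESPONSE_VARIABLES, cell_means

DEFAULT_DEFUZZ_RESOLUTION = 1001


@dataclass
class FuzzyModel:
    """A fitted Mamdani system for one (water, cycle) slice."""

    il_partition: FuzzyPartition
    dat_partition: FuzzyPartition
    output_partitions: dict[str, FuzzyPartition]
    rules: list[FuzzyRule]
    defuzz_resolution: int = DEFAULT_DEFUZZ_RESOLUTION
    water: str = ""
    cycle: int = 0
    output_specs: dict[str, OutputPartitionSpec] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.defuzz_resolution < 101:
            raise ConfigError("defuzz_resolution must be >= 101")
        n_dat = len(self.dat_partition.sets)
        n_il = len(self.il_partition.sets)
        for rule in self.rules:
            if not 1 <= rule.dat_index <= n_dat:
                raise ConfigError(f"rule references DAT set P{rule.dat_index}")
            if not 1 <= rule.il_index <= n_il:
                raise ConfigError(f"rule references level set L{rule.il_index}")
            for var, c in rule.consequents.items():
                part = self.output_partitions.get(var)
                if part is None:
                    raise ConfigError(f"no output partition for {var!r}")
                if not 1 <= c <= len(part.sets):
                    raise ConfigError(
                        f"rule consequent C{c} out of range for {var!r}"
                    )

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.output_partitions)

    def output_grid(self, variable: str) -> np.ndarray:
        part = self.output_partitions[variable]
        return np.linspace(part.sets[0].a, part.sets[-1].d,
                           self.defuzz_resolution)

    def to_dict(self) -> dict:
        return {
            "water": self.water,
            "cycle": self.cycle,
            "defuzz_resolution": self.defuzz_resolution,
            "il_partition": self.il_partition.to_dict(),
            "dat_partition": self.dat_partition.to_dict(),
            "output_partitions": {v: p.to_dict()
                                  for v, p in self.output_partitions.items()},
            "output_specs": {v: s.to_dict()
                             for v, s in self.output_specs.items()},
            "rules": [r.to_dict() for r in self.rules],
            "manifest": self.manifest,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, payload: dict) -> "FuzzyModel":
        specs = {
            v: OutputPartitionSpec(
                percentile_levels=tuple(s["percentile_levels"]),
                delimiters=tuple(s["delimiters"]),
                extension=tuple(s["extension"]),
            )
            for v, s in payload.get("output_specs", {}).items()
        }
        return cls(
            il_partition=FuzzyPartition.from_dict(payload["il_partition"]),
            dat_partition=FuzzyPartition.from_dict(payload["dat_partition"]),
            output_partitions={
                v: FuzzyPartition.from_dict(p)
                for v, p in payload["output_partitions"].items()
            },
            rules=[FuzzyRule.from_dict(r) for r in payload["rules"]],
            defuzz_resolution=payload["defuzz_resolution"],
            water=payload.get("water", ""),
            cycle=payload.get("cycle", 0),
            output_specs=specs,
            manifest=payload.get("manifest", {}),
        )

    @classmethod
    def load(cls, path) -> "FuzzyModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_fuzzy_model(records: pd.DataFrame, water: str, cycle: int,
                      defuzz_resolution: int = DEFAULT_DEFUZZ_RESOLUTION,
                      variables=RESPONSE_VARIABLES) -> FuzzyModel:
    """Induce a complete fuzzy model from one (water, cycle) slice.

    Output partitions are anchored on the percentiles of the slice's 20
    cell means per variable — the same means that feed rule induction.
    """
    subset = records[(records["water"] == water)
                     & (records["cycle"] == cycle)]
    if subset.empty:
        raise ConfigError(f"no records for water={water!r} cycle={cycle}")
    means_by_var = {}
    partitions = {}
    specs = {}
    for var in variables:
        means = cell_means(subset, var)
        by_cell = {(dat, il): m
                   for (_, _, dat, il), m in means.items()}
        spec, partition = build_output_partition(list(by_cell.values()))
        means_by_var[var] = by_cell
        partitions[var] = partition
        specs[var] = spec
    rules = build_rule_base(means_by_var, partitions)
    manifest = {
        "quantile_rule": "linear interpolation between order statistics",
        "tie_break": "max membership, ties to the lower set index",
        "inference": "Mamdani: AND=min, implication=min, aggregation=max",
        "defuzzification": "discrete centroid",
    }
    return FuzzyModel(
        il_partition=irrigation_partition(),
        dat_partition=dat_partition(),
        output_partitions=partitions,
        rules=rules,
        defuzz_resolution=defuzz_resolution,
        water=water,
        cycle=cycle,
        output_specs=specs,
        manifest=manifest,
    )


def discrete_centroid(memberships, grid) -> float:
    """Centroid sum(mu*x)/sum(mu) of sampled membership over a grid."""
    memberships = np.asarray(memberships, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if memberships.shape != grid.shape:
        raise ConfigError("membership samples and grid differ in length")
    if np.any(memberships < 0):
        raise ConfigError("membership samples must be nonnegative")
    total = memberships.sum()
    if total <= 0.0:
        raise DefuzzificationError("membership is zero everywhere")
    return float((memberships * grid).sum() / total)


def _infer_grid(model: FuzzyModel, dat_values, il_values,
                variables=None) -> dict[str, np.ndarray]:
    """Crisp outputs on the Cartesian grid ``dat_values x il_values``.

    Returns variable -> array of shape ``(len(dat_values), len(il_values))``.
    All point queries, including single-point `infer`, go through this
    routine so the arithmetic is identical everywhere.
    """
    if variables is None:
        variables = model.variables
    dat_lo, dat_hi = model.dat_partition.universe
    il_lo, il_hi = model.il_partition.universe
    dat_values = np.clip(np.atleast_1d(np.asarray(dat_values, float)),
                         dat_lo, dat_hi)
    il_values = np.clip(np.atleast_1d(np.asarray(il_values, float)),
                        il_lo, il_hi)
    pm = model.dat_partition.memberships(dat_values)   # (nd, n_P)
    lm = model.il_partition.memberships(il_values)     # (ni, n_L)
    nd, ni = len(dat_values), len(il_values)

    # firing strength of each rule on the grid: min of the two antecedents
    strengths = [
        np.minimum(pm[:, rule.dat_index - 1][:, None],
                   lm[None, :, rule.il_index - 1])
        for rule in model.rules
    ]

    outputs: dict[str, np.ndarray] = {}
    for var in variables:
        grid = model.output_grid(var)
        part = model.output_partitions[var]
        consequent_mu = [
            part.sets[rule.consequents[var] - 1].membership(grid)
            for rule in model.rules
        ]
        values = np.empty((nd, ni))
        for i in range(nd):
            agg = np.zeros((ni, grid.size))
            for s, mu in zip(strengths, consequent_mu):
                row = s[i]
                if row.max() == 0.0:
                    continue
                np.maximum(agg, np.minimum(row[:, None], mu[None, :]),
                           out=agg)
            total = agg.sum(axis=1)
            if np.any(total <= 0.0):
                raise DefuzzificationError(
                    f"aggregated membership vanished for {var!r}"
                )
            values[i] = (agg * grid).sum(axis=1) / total
        outputs[var] = values
    return outputs


def infer(model: FuzzyModel, dat: float,
          irrigation_level: float) -> dict[str, float]:
    """Crisp prediction of every response at one (DAT, irrigation) input."""
    grids = _infer_grid(model, [dat], [irrigation_level])
    return {var: float(vals[0, 0]) for var, vals in grids.items()}


def simulate_surface(model: FuzzyModel, variable: str, step: float = 0.1):
    """Crisp response surface over the full modelled rectangle.

    Returns ``(dat_axis, il_axis, values)`` with ``values[i, j]`` the
    output at ``(dat_axis[i], il_axis[j])``; both axes include their
    endpoints, so at step 0.1 the grid is 211 x 1001 nodes.
    """
    if step <= 0:
        raise ConfigError("step must be positive")
    dat_lo, dat_hi = model.dat_partition.universe
    il_lo, il_hi = model.il_partition.universe
    n_dat = int(round((dat_hi - dat_lo) / step)) + 1
    n_il = int(round((il_hi - il_lo) / step)) + 1
    n_dat = max(n_dat, 1)
    n_il = max(n_il, 1)
    dat_axis = np.linspace(dat_lo, dat_lo + (n_dat - 1) * step, n_dat)
    il_axis = np.linspace(il_lo, il_lo + (n_il - 1) * step, n_il)
    # keep nodes inside the universe even when step does not divide the span
    dat_axis = np.clip(dat_axis, dat_lo, dat_hi)
    il_axis = np.clip(il_axis, il_lo, il_hi)
    values = _infer_grid(model, dat_axis, il_axis, variables=[variable])
    return dat_axis, il_axis, values[variable]


def find_optimum(model: FuzzyModel, variable: str,
                 step: float = 0.1) -> tuple[float, float, float]:
    """Argmax of the simulated surface; ties go to the smallest DAT, then
    the smallest irrigation level (row-major first occurrence)."""
    dat_axis, il_axis, values = simulate_surface(model, variable, step)
    flat = int(np.argmax(values))
    i, j = divmod(flat, values.shape[1])
    return float(dat_axis[i]), float(il_axis[j]), float(values[i, j])


def surface_frame(dat_axis, il_axis, values,
                  variable: str) -> pd.DataFrame:
    """Long-format (dat, il, value) table of a simulated surface."""
    dat_grid, il_grid = np.meshgrid(dat_axis, il_axis, indexing="ij")
    return pd.DataFrame({
        "dat": dat_grid.ravel(),
        "il": il_grid.ravel(),
        "variable": variable,
        "value": values.ravel(),
    })
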