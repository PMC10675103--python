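"""End-to-end pipeline: simulate/load -> screen -> fuzzy + regression ->
compare, with every artifact serialized under one output directory."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .exceptions import ConfigError
from .inference import (DEFAULT_DEFUZZ_RESOLUTION, FuzzyModel,
                        build_fuzzy_model, simulate_surface, surface_frame)
from .metrics import comparison_table
from .preprocessing import screen_all
from .regression import fit_polynomial
from .simulate import (RESPONSE_VARIABLES, GrowthSimConfig,
                       generate_experiment, validate_table)

logger = logging.getLogger("fuzzygrowth")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    input_csv: str | None = None
    sim_config: GrowthSimConfig | None = None
    variables: tuple[str, ...] = RESPONSE_VARIABLES
    alpha: float = 0.05
    defuzz_resolution: int = DEFAULT_DEFUZZ_RESOLUTION
    surface_step: float | None = None  # set to export surfaces
    out_dir: str = "fuzzygrowth_out"
    seed: int = 0

    def validate(self) -> None:
        unknown = [v for v in self.variables if v not in RESPONSE_VARIABLES]
        if unknown:
            raise ConfigError(
                f"unknown variables {unknown}; expected a subset of "
                f"{RESPONSE_VARIABLES}"
            )
        if self.input_csv is None and self.sim_config is None:
            raise ConfigError("either input_csv or sim_config is required")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle to ``out_dir``.

    Returns a dict with the in-memory artifacts: the records table, the
    screening reports, fuzzy and regression models keyed by slice, and
    the comparison table.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    if config.input_csv is not None:
        records = pd.read_csv(config.input_csv)
    else:
        sim = config.sim_config.with_seed(config.seed)
        records = generate_experiment(sim)
        records.to_csv(out / "records.csv", index=False,
                       float_format="%.17g")
    validate_table(records)
    logger.info("stage=data rows=%d elapsed=%.2fs", len(records),
                time.perf_counter() - t0)

    t0 = time.perf_counter()
    reports = screen_all(records, config.variables, alpha=config.alpha)
    with open(out / "screening.json", "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=1)
    logger.info("stage=screen reports=%d elapsed=%.2fs", len(reports),
                time.perf_counter() - t0)

    waters = sorted(records["water"].unique())
    cycles = sorted(int(c) for c in records["cycle"].unique())

    fuzzy_models: dict[tuple, FuzzyModel] = {}
    poly_models: dict[tuple, object] = {}
    for water in waters:
        for cycle in cycles:
            t0 = time.perf_counter()
            fm = build_fuzzy_model(
                records, water, cycle,
                defuzz_resolution=config.defuzz_resolution,
                variables=config.variables,
            )
            fuzzy_models[(water, cycle)] = fm
            fm.save(out / f"fuzzy_{water}_c{cycle}.json")
            for variable in config.variables:
                pm = fit_polynomial(records, variable, water, cycle,
                                    alpha=config.alpha)
                poly_models[(water, cycle, variable)] = pm
                pm.save(out / f"regression_{variable}_{water}_c{cycle}.json")
            logger.info("stage=fit water=%s cycle=%d elapsed=%.2fs",
                        water, cycle, time.perf_counter() - t0)

    t0 = time.perf_counter()
    table = comparison_table(records, fuzzy_models, poly_models,
                             variables=config.variables)
    table.to_csv(out / "metrics.csv", index=False, float_format="%.17g")
    logger.info("stage=evaluate rows=%d elapsed=%.2fs", len(table),
                time.perf_counter() - t0)

    if config.surface_step is not None:
        for (water, cycle), fm in fuzzy_models.items():
            for variable in config.variables:
                axes = simulate_surface(fm, variable,
                                        step=config.surface_step)
                frame = surface_frame(*axes, variable)
                frame.to_csv(
                    out / f"surface_{variable}_{water}_c{cycle}.csv",
                    index=False, float_format="%.17g",
                )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "defuzz_resolution": config.defuzz_resolution,
        "variables": list(config.variables),
        "quantile_rule": "linear interpolation between order statistics",
        "tie_break": "max membership, ties to the lower set index",
        "inference": "Mamdani: AND=min, implication=min, aggregation=max; "
                     "centroid defuzzification",
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return {
        "records": records,
        "screening": reports,
        "fuzzy_models": fuzzy_models,
        "poly_models": poly_models,
        "metrics": table,
    }
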