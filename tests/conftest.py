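import pytest

from fuzzygrowth import GrowthSimConfig, build_fuzzy_model, generate_experiment


@pytest.fixture(scope="session")
def default_records():
    """Full two-cycle factorial with default noise, fixed seed."""
    return generate_experiment(GrowthSimConfig(seed=42))


@pytest.fixture(scope="session")
def noisefree_records():
    """Noise-free factorial: every replicate equals its cell mean."""
    return generate_experiment(GrowthSimConfig(noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def noisefree_model(noisefree_records):
    return build_fuzzy_model(noisefree_records, "MW", 1)


def null_config(seed: int, n_replicates: int = 4) -> GrowthSimConfig:
    """Flat mean surface: equal-variance Gaussian residuals (the null)."""
    return GrowthSimConfig(
        cycles=(1,), n_replicates=n_replicates, water_effect=1.0,
        il_curvature=0.0, growth_rate=1e-9, seed=seed,
    )
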