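"""Mamdani inference, centroid defuzzification, surfaces and optima."""

import numpy as np
import pytest

from fuzzygrowth import (ConfigError, DefuzzificationError, FuzzyModel,
                         TrapezoidMF, discrete_centroid, find_optimum, infer,
                         simulate_surface)
from fuzzygrowth.inference import _infer_grid
from fuzzygrowth.partitions import (FuzzyPartition, dat_partition,
                                    irrigation_partition)
from fuzzygrowth.rules import FuzzyRule


def test_discrete_centroid_symmetry_and_point_mass():
    grid = np.linspace(0, 10, 1001)
    assert discrete_centroid(np.ones_like(grid), grid) == pytest.approx(5.0)
    mu = np.zeros_like(grid)
    mu[np.searchsorted(grid, 7.0)] = 0.4
    assert discrete_centroid(mu, grid) == pytest.approx(7.0)


def test_discrete_centroid_triangle_converges_to_analytic():
    # rising triangle on [0, 1]: integral centroid is 2/3
    errors = []
    for res in (101, 1001, 10001):
        grid = np.linspace(0, 1, res)
        errors.append(abs(discrete_centroid(grid.copy(), grid) - 2 / 3))
    assert errors[-1] < 1e-4
    assert errors == sorted(errors, reverse=True)


def test_discrete_centroid_errors():
    grid = np.linspace(0, 1, 101)
    with pytest.raises(DefuzzificationError):
        discrete_centroid(np.zeros_like(grid), grid)
    with pytest.raises(ConfigError):
        discrete_centroid(np.ones(50), grid)


def _constant_model(consequent: int = 4, resolution: int = 1001) -> FuzzyModel:
    """All 20 rules share one consequent set: the surface is constant."""
    sets = tuple(TrapezoidMF(m - 0.5, m - 0.25, m + 0.25, m + 0.5,
                             label=f"C{m}") for m in range(1, 11))
    part = FuzzyPartition(universe=(0.5, 10.5), sets=sets,
                          anchors=tuple(float(m) for m in range(1, 11)),
                          spacing_k=100 / 19)
    rules = [FuzzyRule(p, l, {"fsb": consequent})
             for p in range(1, 5) for l in range(1, 6)]
    return FuzzyModel(il_partition=irrigation_partition(),
                      dat_partition=dat_partition(),
                      output_partitions={"fsb": part}, rules=rules,
                      defuzz_resolution=resolution, water="CW", cycle=1)


def test_anchor_input_fires_single_rule(noisefree_model):
    # at (14, 25) only the (P1, L1) rule fires, at full strength: the crisp
    # output is the centroid of that rule's consequent trapezoid
    model = noisefree_model
    rule = next(r for r in model.rules if (r.dat_index, r.il_index) == (1, 1))
    crisp = infer(model, 14.0, 25.0)
    for var, c_index in rule.consequents.items():
        mf = model.output_partitions[var].sets[c_index - 1]
        grid = model.output_grid(var)
        step = grid[1] - grid[0]
        assert abs(crisp[var] - mf.centroid()) <= step


def test_symmetric_consequent_centroid_is_midpoint():
    model = _constant_model(consequent=4)
    crisp = infer(model, 14.0, 25.0)["fsb"]
    mf = model.output_partitions["fsb"].sets[3]
    assert mf.d - mf.c == pytest.approx(mf.b - mf.a)
    assert crisp == pytest.approx(0.5 * (mf.a + mf.d), abs=1e-9)


def test_mid_transition_output_is_bounded_by_firing_consequents(
        noisefree_model):
    model = noisefree_model
    dat, il = 17.5, 41.665  # mid-transition in both inputs
    pm = model.dat_partition.memberships(dat)[0]
    lm = model.il_partition.memberships(il)[0]
    assert np.sum(pm > 0) == 2 and np.sum(lm > 0) == 2
    fired = [r for r in model.rules
             if pm[r.dat_index - 1] > 0 and lm[r.il_index - 1] > 0]
    assert len(fired) == 4
    for var in ("ln", "fsb"):
        centroids = [
            model.output_partitions[var].sets[r.consequents[var] - 1]
            .centroid() for r in fired
        ]
        value = infer(model, dat, il)[var]
        grid = model.output_grid(var)
        step = grid[1] - grid[0]
        assert min(centroids) - step <= value <= max(centroids) + step


def test_output_within_universe_and_resolution_convergence(noisefree_model):
    model = noisefree_model
    rng = np.random.default_rng(2)
    points = list(zip(rng.uniform(14, 35, 25), rng.uniform(25, 125, 25)))
    import dataclasses
    finer = dataclasses.replace(model, defuzz_resolution=2001)
    for dat, il in points:
        for var, value in infer(model, dat, il).items():
            grid = model.output_grid(var)
            assert grid[0] <= value <= grid[-1]
            value2 = infer(finer, dat, il)[var]
            span = grid[-1] - grid[0]
            assert abs(value2 - value) < 0.01 * span


def test_inputs_outside_rectangle_are_clipped(noisefree_model):
    inside = infer(noisefree_model, 35.0, 125.0)
    outside = infer(noisefree_model, 60.0, 400.0)
    assert inside == outside


def test_continuity_along_input_path(noisefree_model):
    dats = np.linspace(14, 35, 300)
    ils = np.linspace(25, 125, 300)
    values = np.array([
        _infer_grid(noisefree_model, [d], [il], variables=["fsb"])
        ["fsb"][0, 0] for d, il in zip(dats, ils)
    ])
    span = values.max() - values.min()
    assert np.max(np.abs(np.diff(values))) < 0.1 * span


def test_surface_grid_dimensions_and_consistency(noisefree_model):
    dat_axis, il_axis, values = simulate_surface(noisefree_model, "fsb",
                                                 step=3.5)
    assert values.shape == (7, 30)  # 21/3.5 + 1 and floor(100/3.5) + 1
    assert dat_axis[0] == 14.0 and il_axis[0] == 25.0
    for i in (0, 3, 6):
        for j in (0, 15, 29):
            assert infer(noisefree_model, dat_axis[i], il_axis[j])["fsb"] \
                == values[i, j]


def test_surface_degenerate_step():
    model = _constant_model()
    _, _, values = simulate_surface(model, "fsb", step=1000.0)
    assert values.shape == (1, 1)
    with pytest.raises(ConfigError):
        simulate_surface(model, "fsb", step=0.0)


def test_find_optimum_monotone_growth(noisefree_model):
    # growth is monotone in DAT, so the optimum lies on the terminal DAT
    # plateau [32, 35]; the surface is exactly constant there and the tie
    # rule returns its smallest grid node
    dat_star, il_star, value = find_optimum(noisefree_model, "fsb", step=1.0)
    assert 32.0 <= dat_star <= 35.0
    assert value == infer(noisefree_model, 35.0, il_star)["fsb"]


def test_find_optimum_tie_break_is_row_major(noisefree_model):
    dat_axis, il_axis, values = simulate_surface(noisefree_model, "fsb",
                                                 step=1.0)
    dat_star, il_star, value = find_optimum(noisefree_model, "fsb", step=1.0)
    assert value == values.max()
    ties = np.argwhere(values == value)
    assert len(ties) > 1  # the terminal plateau creates genuine ties
    i, j = ties[0]  # row-major first: smallest DAT, then smallest level
    assert (dat_axis[i], il_axis[j]) == (dat_star, il_star)


def test_model_roundtrip_serialization(noisefree_model, tmp_path):
    path = tmp_path / "model.json"
    noisefree_model.save(path)
    loaded = FuzzyModel.load(path)
    assert loaded.rules == noisefree_model.rules
    assert infer(loaded, 20.0, 60.0) == infer(noisefree_model, 20.0, 60.0)


def test_model_validation():
    with pytest.raises(ConfigError, match="defuzz_resolution"):
        _constant_model(resolution=50)
    with pytest.raises(ConfigError, match="C11"):
        _constant_model(consequent=11)
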