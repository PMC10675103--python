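"""Cubic polynomial baseline: recovery, guards, inference statistics."""

import numpy as np
import pandas as pd
import pytest

from fuzzygrowth import ConfigError, PolynomialModel, fit_polynomial, predict

TRUE_COEF = {"intercept": 4.0, "il": 0.3, "il2": -0.002, "il3": 5e-6,
             "dat": 1.2, "dat2": -0.01, "dat3": 2e-4}


def _cubic_table(noise_sd=0.0, seed=0, reps=4):
    rng = np.random.default_rng(seed)
    rows = []
    for dat in (14, 21, 28, 35):
        for il in (25, 50, 75, 100, 125):
            for rep in range(1, reps + 1):
                y = (TRUE_COEF["intercept"]
                     + TRUE_COEF["il"] * il + TRUE_COEF["il2"] * il ** 2
                     + TRUE_COEF["il3"] * il ** 3
                     + TRUE_COEF["dat"] * dat + TRUE_COEF["dat2"] * dat ** 2
                     + TRUE_COEF["dat3"] * dat ** 3)
                if noise_sd:
                    y += rng.normal(0, noise_sd)
                rows.append({"cycle": 1, "water": "CW",
                             "irrigation_level": il, "dat": dat,
                             "replicate": rep, "ln": 1, "fsb": y,
                             "frb": 1, "dsb": 1, "drb": 1})
    return pd.DataFrame(rows)


def test_noiseless_cubic_recovery():
    records = _cubic_table()
    model = fit_polynomial(records, "fsb", "CW", 1)
    for term, true in TRUE_COEF.items():
        assert model.coefficients[term] == pytest.approx(true, rel=1e-6)
    assert model.r_squared == pytest.approx(1.0, abs=1e-10)
    # an exact fit interpolates every training point
    assert predict(model, 21, 75) == pytest.approx(
        records.query("dat == 21 and irrigation_level == 75")["fsb"].iloc[0],
        rel=1e-10,
    )


def test_r_squared_matches_independent_residual_computation():
    records = _cubic_table(noise_sd=3.0, seed=4)
    model = fit_polynomial(records, "fsb", "CW", 1)
    y = records["fsb"].to_numpy()
    yhat = np.asarray(predict(model, records["dat"],
                              records["irrigation_level"]))
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    assert model.r_squared == pytest.approx(1 - ss_res / ss_tot, rel=1e-10)


def test_pure_noise_response_is_nonsignificant():
    rng = np.random.default_rng(9)
    records = _cubic_table()
    records["fsb"] = rng.standard_normal(len(records)) + 10
    model = fit_polynomial(records, "fsb", "CW", 1)
    assert model.r_squared < 0.25
    assert model.model_p > 0.05


def test_observation_and_rank_guards():
    records = _cubic_table(reps=1)
    with pytest.raises(ConfigError, match="observations"):
        fit_polynomial(records.head(8), "fsb", "CW", 1)
    squished = records.copy()
    squished["irrigation_level"] = 75  # one distinct level only
    with pytest.raises(ConfigError, match="distinct"):
        fit_polynomial(squished, "fsb", "CW", 1)
    with pytest.raises(ConfigError, match="no records"):
        fit_polynomial(records, "fsb", "MW", 1)


def test_predict_term_structure():
    base = dict(r_squared=1.0, f_statistic=0.0, model_p=1.0, coef_p={})
    constant = PolynomialModel(beta0=3.5, a1=0, a2=0, a3=0, b1=0, b2=0, b3=0,
                               **base)
    assert predict(constant, 20, 50) == 3.5
    linear = PolynomialModel(beta0=2.0, a1=1.0, a2=0, a3=0, b1=0, b2=0, b3=0,
                             **base)
    assert predict(linear, 20, 50) == 52.0


def test_pooled_mode_recovers_water_dummy():
    cw = _cubic_table()
    mw = cw.copy()
    mw["water"] = "MW"
    mw["fsb"] += 7.5
    records = pd.concat([cw, mw], ignore_index=True)
    records["replicate"] = np.arange(len(records))  # keep keys unique
    model = fit_polynomial(records, "fsb", pooled=True)
    assert model.water_dummy == pytest.approx(7.5, rel=1e-8)
    assert predict(model, 21, 75, water="MW") - \
        predict(model, 21, 75, water="CW") == pytest.approx(7.5, rel=1e-8)


def test_significance_flags(default_records):
    model = fit_polynomial(default_records, "fsb", "MW", 1)
    assert model.model_p < 0.05  # growth signal is strong by design
    assert set(model.coef_p) >= {"intercept", "il", "dat3"}
    assert all(0 <= p <= 1 for p in model.coef_p.values())
    assert "dat" in model.significant_terms() or \
        "dat2" in model.significant_terms() or \
        "dat3" in model.significant_terms()


def test_model_roundtrip(tmp_path, default_records):
    model = fit_polynomial(default_records, "ln", "CW", 2)
    path = tmp_path / "reg.json"
    model.save(path)
    loaded = PolynomialModel.load(path)
    assert loaded.coefficients == model.coefficients
    assert loaded.r_squared == model.r_squared
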