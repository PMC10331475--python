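"""Residual attribution: climate model, influence classes, driver table."""

import numpy as np
import pandas as pd
import pytest

from veqi.attribution import (
    CLIMATE_FEATURES,
    AttributionResult,
    ClimateModelReport,
    attribute_drivers,
    baseline_linear_model,
    build_training_table,
    classify_influence,
    classify_influence_grid,
    fit_climate_model,
    predict_veqi_c,
    regional_summary,
    residual_human,
)
from veqi.errors import ConfigurationError, SampleSizeError, ShapeError


def make_table(n=2000, seed=0, target="tem", noise=0.0):
    """Training table with a known climate-to-target response."""
    rng = np.random.default_rng(seed)
    cols = {name: rng.uniform(0, 1, n) for name in CLIMATE_FEATURES}
    cols["tem"] = rng.uniform(0, 25, n)
    if target == "tem":
        y = 1.0 / (1.0 + np.exp(-(cols["tem"] - 12) / 4))
    elif target == "linear_tem":
        y = 0.02 * cols["tem"] + 0.1
    elif target == "nonlinear":
        y = np.sin(cols["tem"] / 4.0) ** 2 * 0.5 + 0.25 * (cols["pre"] > 0.5)
    else:  # pure noise
        y = rng.uniform(0, 1, n)
    cols["veqi"] = y + noise * rng.normal(size=n)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# training table
# ---------------------------------------------------------------------------

def test_training_table_count_and_mask(small_scene):
    veqi = np.clip(small_scene.evi.values.reshape(8, 12, 16, 16).mean(axis=1), 0, 1)
    table = build_training_table(veqi, small_scene.climate, small_scene.reserve_mask)
    assert len(table) == small_scene.reserve_mask.sum() * 8
    assert set(table.columns) == set(CLIMATE_FEATURES) | {"veqi"}
    # values must come from reserve pixels only: compare against a direct pull
    from veqi.attribution import annual_climate_features

    tem_annual = annual_climate_features(small_scene.climate)["tem"]
    expected = np.sort(tem_annual[:, small_scene.reserve_mask].ravel())
    assert np.allclose(np.sort(table["tem"].to_numpy()), expected)


def test_training_table_empty_mask_rejected(small_scene):
    veqi = np.zeros((8, 16, 16))
    with pytest.raises(ConfigurationError):
        build_training_table(veqi, small_scene.climate, np.zeros((16, 16), bool))


# ---------------------------------------------------------------------------
# climate model
# ---------------------------------------------------------------------------

class TestClimateModel:
    def test_recovers_noise_free_temperature_response(self):
        model, report = fit_climate_model(make_table(target="tem"), seed=1)
        assert report.r2 > 0.95
        top = max(report.importances, key=report.importances.get)
        assert top == "tem"
        assert sum(report.importances.values()) == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_target_has_no_skill(self):
        _, report = fit_climate_model(make_table(target="noise"), seed=1)
        assert report.r2 <= 0.1

    def test_seed_determinism(self):
        _, a = fit_climate_model(make_table(), seed=7)
        _, b = fit_climate_model(make_table(), seed=7)
        assert a.r2 == b.r2 and a.rmse == b.rmse and a.importances == b.importances

    def test_too_few_rows_rejected(self):
        with pytest.raises(SampleSizeError):
            fit_climate_model(make_table(n=20))

    def test_prediction_grid_contract(self, small_scene):
        veqi = np.clip(small_scene.evi.values.reshape(8, 12, 16, 16).mean(axis=1), 0, 1)
        table = build_training_table(veqi, small_scene.climate, small_scene.reserve_mask)
        model, _ = fit_climate_model(table, seed=0)
        valid = np.ones((16, 16), bool)
        pred = predict_veqi_c(model, small_scene.climate, valid)
        assert pred.shape == veqi.shape
        assert np.nanmin(pred) >= 0.0 and np.nanmax(pred) <= 1.0
        masked = predict_veqi_c(model, small_scene.climate, ~valid)
        assert np.all(np.isnan(masked))


# ---------------------------------------------------------------------------
# residual identity
# ---------------------------------------------------------------------------

def test_residual_identity_and_antisymmetry(rng):
    a = rng.uniform(0, 1, (4, 3, 3))
    b = rng.uniform(0, 1, (4, 3, 3))
    np.testing.assert_array_equal(residual_human(a, a), np.zeros_like(a))
    np.testing.assert_allclose(residual_human(a, b), -residual_human(b, a), atol=1e-15)
    assert residual_human(np.array(0.6), np.array(0.45)) == pytest.approx(0.15)
    with pytest.raises(ShapeError):
        residual_human(a, b[:2])


# ---------------------------------------------------------------------------
# influence degrees
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "slope, z, label",
    [
        (0.01, 2.2, "significantly promoted"),
        (0.01, 1.7, "moderately promoted"),
        (0.01, 0.5, "slightly promoted"),
        (0.0, 3.0, "no effects"),
        (-0.01, 0.5, "slightly inhibited"),
        (-0.01, 1.7, "moderately inhibited"),
        (-0.01, 2.2, "significantly inhibited"),
    ],
)
def test_influence_classification(slope, z, label):
    assert classify_influence(slope, z) == label


def test_influence_total_on_finite_inputs(rng):
    codes = classify_influence_grid(rng.normal(size=1000), rng.normal(size=1000) * 3)
    assert set(np.unique(codes)) <= {-3, -2, -1, 0, 1, 2, 3}


# ---------------------------------------------------------------------------
# driver table
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "st_, sc, sh, driver, cc, ch, gap",
    [
        (0.08, 0.02, 0.06, "C&H", 25.0, 75.0, False),
        (0.02, 0.03, -0.01, "C", 100.0, 0.0, False),
        (0.02, -0.01, 0.03, "H", 0.0, 100.0, False),
        (-0.08, -0.02, -0.06, "C&H", 25.0, 75.0, False),
        (-0.02, -0.03, 0.01, "C", 100.0, 0.0, False),
        (-0.02, 0.01, -0.03, "H", 0.0, 100.0, False),
        (0.04, 0.02, 0.02, "C&H", 50.0, 50.0, False),
        (0.0, 0.01, -0.01, "none", np.nan, np.nan, False),
        # Sen non-additivity gaps -> dominant magnitude with flag
        (0.01, -0.02, -0.005, "C", 100.0, 0.0, True),
        (0.01, -0.005, -0.02, "H", 0.0, 100.0, True),
        (0.01, 0.0, 0.0, "none", np.nan, np.nan, True),
    ],
)
def test_attribute_drivers_table(st_, sc, sh, driver, cc, ch, gap):
    d, got_cc, got_ch, got_gap = attribute_drivers(st_, sc, sh)
    assert d == driver
    assert got_gap == gap
    if np.isnan(cc):
        assert np.isnan(got_cc) and np.isnan(got_ch)
    else:
        assert got_cc == pytest.approx(cc)
        assert got_ch == pytest.approx(ch)
        assert got_cc + got_ch == pytest.approx(100.0)


def test_attribute_drivers_scale_invariance(rng):
    st_ = rng.normal(size=200)
    sc = rng.normal(size=200)
    sh = rng.normal(size=200)
    base = attribute_drivers(st_, sc, sh)
    scaled = attribute_drivers(3.7 * st_, 3.7 * sc, 3.7 * sh)
    np.testing.assert_array_equal(base[0], scaled[0])
    np.testing.assert_allclose(base[1], scaled[1], atol=1e-9)
    np.testing.assert_array_equal(base[3], scaled[3])


def test_contributions_bounded_for_consistent_signs(rng):
    _, cc, ch, gap = attribute_drivers(rng.normal(size=500), rng.normal(size=500), rng.normal(size=500))
    ok = ~np.isnan(cc)
    assert np.all((cc[ok] >= 0) & (cc[ok] <= 100))
    assert np.allclose((cc + ch)[ok], 100.0)


# ---------------------------------------------------------------------------
# regional summary
# ---------------------------------------------------------------------------

def make_result(driver, cc, ch, sen_c=None, sen_h=None):
    shape = driver.shape
    z = np.zeros(shape)
    rep = ClimateModelReport(0.9, 0.05, {k: 1 / 6 for k in CLIMATE_FEATURES}, {}, 100)
    sen_c = np.where(driver == 1, 0.01, 0.0) if sen_c is None else sen_c
    sen_h = np.where(driver == 2, 0.01, 0.0) if sen_h is None else sen_h
    return AttributionResult(
        veqi_c=np.zeros((3, *shape)), veqi_h=np.zeros((3, *shape)),
        sen_total=sen_c + sen_h, sen_c=sen_c, sen_h=sen_h,
        z_total=z, z_c=z, z_h=z,
        influence_climate=np.zeros(shape, int), influence_human=np.zeros(shape, int),
        driver=driver, contrib_climate=cc, contrib_human=ch,
        table_gap=np.zeros(shape, bool), report=rep)


def test_regional_summary_uniform_climate_driver():
    shape = (4, 4)
    driver = np.ones(shape, int)
    result = make_result(driver, np.full(shape, 100.0), np.zeros(shape))
    table = regional_summary(result, np.ones(shape, bool), np.full(shape, "all"))
    row = table.iloc[0]
    assert row["driver_C_pct"] == pytest.approx(100.0)
    assert row["mean_contrib_climate"] == pytest.approx(100.0)
    assert row["mean_contrib_human"] == pytest.approx(0.0)


def test_regional_summary_partition_and_pooling():
    shape = (4, 4)
    driver = np.ones(shape, int)
    driver[:, 2:] = 2
    cc = np.where(driver == 1, 100.0, 0.0)
    result = make_result(driver, cc, 100.0 - cc)
    labels = np.where(np.arange(4)[None, :] < 2, "west", "east")
    labels = np.broadcast_to(labels, shape)
    table = regional_summary(result, np.ones(shape, bool), labels).set_index("region")
    assert table.loc["west", "driver_C_pct"] == pytest.approx(100.0)
    assert table.loc["east", "driver_H_pct"] == pytest.approx(100.0)
    driver_cols = [c for c in table.columns if c.startswith("driver_")]
    np.testing.assert_allclose(table[driver_cols].sum(axis=1), 100.0)
    # pooled equal-area shares: half driver C, half driver H
    pooled = regional_summary(result, np.ones(shape, bool), np.full(shape, "all")).iloc[0]
    assert pooled["driver_C_pct"] == pytest.approx(50.0)
    assert pooled["driver_H_pct"] == pytest.approx(50.0)


# ---------------------------------------------------------------------------
# stepwise-linear baseline
# ---------------------------------------------------------------------------

class TestBaseline:
    def test_linear_target_recovered(self):
        _, report = baseline_linear_model(make_table(target="linear_tem"), seed=2)
        assert report.r2 > 0.99
        assert report.hyperparameters["selected"][0] == "tem"

    def test_boosted_trees_beat_linear_on_nonlinear_truth(self):
        table = make_table(target="nonlinear", seed=3)
        _, linear = baseline_linear_model(table, seed=4)
        _, boosted = fit_climate_model(table, seed=4)
        assert boosted.r2 > linear.r2

    def test_seed_determinism(self):
        _, a = baseline_linear_model(make_table(), seed=5)
        _, b = baseline_linear_model(make_table(), seed=5)
        assert a.r2 == b.r2 and a.importances == b.importances
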