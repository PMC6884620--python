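import numpy as np
import pandas as pd
import pytest

from invafun.brt import (
    BRTParams,
    fit_brt,
    influence_direction,
    influence_table,
    partial_dependence,
    relative_influence,
)


def make_xy(n=500, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"x1": rng.uniform(0, 1, n), "x2": rng.uniform(0, 1, n)})
    y = X["x1"] + noise * rng.normal(size=n)
    return X, y


def test_constant_response_yields_zero_tree_model():
    X, _ = make_xy(50)
    with pytest.warns(UserWarning, match="constant"):
        model = fit_brt(X, np.full(50, 3.25), BRTParams(n_trees=100, rng_seed=0))
    assert model.trees == []
    np.testing.assert_allclose(model.predict(X), 3.25)


def test_zero_shrinkage_predicts_the_mean():
    X, y = make_xy(100, seed=1)
    model = fit_brt(X, y, BRTParams(shrinkage=0.0, n_trees=50, rng_seed=0))
    np.testing.assert_allclose(model.predict(X), y.mean(), atol=1e-12)


def test_noise_free_signal_is_learned():
    """y = x1 exactly, x2 pure noise: 3000 stumps reach training R^2 > 0.95."""
    X, y = make_xy(500, seed=2)
    model = fit_brt(X, y, BRTParams(shrinkage=0.01, n_trees=3000, rng_seed=0))
    resid = y - model.predict(X)
    r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
    assert r2 > 0.95
    infl = relative_influence(model)
    assert infl["x1"] == pytest.approx(100.0, abs=1.0)


def test_influences_sum_to_100_and_rank_signal_strength():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.uniform(0, 1, size=(500, 3)), columns=["x1", "x2", "x3"])
    y = X["x1"] + 0.1 * X["x2"] + 0.02 * rng.normal(size=500)
    model = fit_brt(X, y, BRTParams(shrinkage=0.05, n_trees=500, rng_seed=1))
    infl = relative_influence(model)
    assert infl.sum() == pytest.approx(100.0, abs=1e-6)
    assert infl["x1"] > infl["x2"] > infl["x3"]


def test_determinism_and_seed_sensitivity():
    X, y = make_xy(120, seed=4, noise=0.1)
    p = BRTParams(shrinkage=0.05, n_trees=200, rng_seed=9)
    m1, m2 = fit_brt(X, y, p), fit_brt(X, y, p)
    np.testing.assert_array_equal(m1.predict(X), m2.predict(X))
    pd.testing.assert_series_equal(relative_influence(m1), relative_influence(m2))
    m3 = fit_brt(X, y, BRTParams(shrinkage=0.05, n_trees=200, rng_seed=10))
    assert not np.array_equal(m1.predict(X), m3.predict(X))


def test_relative_influence_invariant_to_affine_response_rescale():
    X, y = make_xy(200, seed=5, noise=0.2)
    p = BRTParams(shrinkage=0.05, n_trees=300, rng_seed=2)
    i1 = relative_influence(fit_brt(X, y, p))
    i2 = relative_influence(fit_brt(X, 5.0 * y - 11.0, p))
    assert (i1 - i2).abs().max() < 1e-9


def test_binary_predictor_converges_to_group_means():
    rng = np.random.default_rng(6)
    x = rng.integers(0, 2, size=200).astype(float)
    X = pd.DataFrame({"g": x})
    y = np.where(x > 0.5, 2.0, -1.0)
    model = fit_brt(
        X, y, BRTParams(shrinkage=0.05, bag_fraction=1.0, n_trees=2000, rng_seed=0)
    )
    pred = model.predict(X)
    np.testing.assert_allclose(pred[x > 0.5], 2.0, atol=1e-3)
    np.testing.assert_allclose(pred[x < 0.5], -1.0, atol=1e-3)


def test_partial_dependence_shapes():
    X, y = make_xy(300, seed=7)
    model = fit_brt(X, y, BRTParams(shrinkage=0.05, n_trees=500, rng_seed=3))
    grid, curve = partial_dependence(model, "x1")
    assert grid.shape == curve.shape == (100,)
    assert (np.diff(curve) >= -1e-9).all()  # monotone signal -> non-decreasing curve
    # x2 is never informative: near-flat curve and tiny influence
    _, flat = partial_dependence(model, "x2")
    assert np.ptp(flat) < 0.02 * np.ptp(curve)
    with pytest.raises(KeyError):
        partial_dependence(model, "nope")


def test_influence_direction_signs():
    rng = np.random.default_rng(8)
    X = pd.DataFrame({"up": rng.uniform(0, 1, 300), "down": rng.uniform(0, 1, 300)})
    y = 2.0 * X["up"] - 3.0 * X["down"]
    model = fit_brt(X, y, BRTParams(shrinkage=0.05, n_trees=800, rng_seed=4))
    assert influence_direction(model, "up") == "+"
    assert influence_direction(model, "down") == "-"


def test_influence_table_columns_and_grouping():
    X, y = make_xy(100, seed=9, noise=0.1)
    model = fit_brt(X, y, BRTParams(shrinkage=0.05, n_trees=100, rng_seed=5))
    table = influence_table(model, groups={"x1": "geographical"})
    assert list(table.columns) == [
        "variable", "group", "relative_influence_pct", "direction",
    ]
    assert table.loc[table["variable"] == "x1", "group"].item() == "geographical"
    assert table.loc[table["variable"] == "x2", "group"].item() == "other"
    assert table["relative_influence_pct"].sum() == pytest.approx(100.0, abs=1e-6)


def test_matches_reference_gradient_boosting_without_bagging():
    """With bag fraction 1 and depth 1 the ensemble coincides with
    scikit-learn's gradient boosting (same loss, splits and shrinkage)."""
    GradientBoostingRegressor = pytest.importorskip(
        "sklearn.ensemble"
    ).GradientBoostingRegressor

    rng = np.random.default_rng(10)
    X = pd.DataFrame(rng.normal(size=(80, 3)), columns=["a", "b", "c"])
    y = np.sin(X["a"]) + 0.5 * X["b"] + 0.1 * rng.normal(size=80)
    params = BRTParams(shrinkage=0.1, bag_fraction=1.0, n_trees=150, rng_seed=0)
    ours = fit_brt(X, y, params)
    ref = GradientBoostingRegressor(
        learning_rate=0.1, n_estimators=150, max_depth=1, subsample=1.0,
        random_state=0,
    ).fit(X.values, y)
    np.testing.assert_allclose(ours.predict(X), ref.predict(X.values), atol=1e-8)
    infl = relative_influence(ours).reindex(["a", "b", "c"])
    np.testing.assert_allclose(infl.values, 100 * ref.feature_importances_, atol=1e-6)


def test_small_sample_and_missing_values_rejected():
    X, y = make_xy(10)
    with pytest.raises(ValueError, match="20"):
        fit_brt(X, y)
    X2, y2 = make_xy(30)
    X2.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        fit_brt(X2, y2, BRTParams(n_trees=10))
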