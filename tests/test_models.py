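import numpy as np
import pandas as pd
import pytest

import reportdelay as rd
from reportdelay import areal, models


@pytest.fixture(scope="module")
def small_data():
    return rd.generate(rd.preset("spatial", seed=21, n_events=800, grid_tracts=(10, 10)))


@pytest.fixture(scope="module")
def small_context(small_data):
    return areal.event_context(small_data.events, small_data.tracts, None, "point")


def test_spec_validation():
    with pytest.raises(ValueError):
        models.ModelSpec("NS9", "d_day")
    with pytest.raises(ValueError):
        models.ModelSpec("NS1", "delay")  # not a modelling target
    with pytest.raises(ValueError, match="coordinates"):
        models.ModelSpec("S1", "d_day", "gaussian_process")
    assert models.ModelSpec("S3", "d_day", "gaussian_process").task == "classification"


def test_feature_groups_per_model(small_data, small_context):
    ev = small_data.events
    X1, y, g1 = models.assemble_features(ev, models.ModelSpec("NS1", "d_day"))
    assert set(g1.values()) == {"V"}
    assert all(c.startswith("vict.") for c in X1.columns)
    X2, _, g2 = models.assemble_features(ev, models.ModelSpec("NS2", "d_day"))
    assert set(g2.values()) == {"V", "Z"}
    m = ev["district_id"].nunique()
    X3, _, g3 = models.assemble_features(ev, models.ModelSpec("S2", "d_day"))
    assert sum(1 for v in g3.values() if v == "Q") == m - 1
    X4, _, g4 = models.assemble_features(
        ev, models.ModelSpec("S3", "log_delay"), small_context
    )
    assert g4["lon"] == "C" and g4["lat"] == "C"
    assert "poverty" in X4.columns
    with pytest.raises(ValueError, match="areal context"):
        models.assemble_features(ev, models.ModelSpec("S1", "d_day"))


def test_l1_keeps_signal_drops_noise():
    rng = np.random.default_rng(0)
    kept_signal = 0
    noise_frac = []
    for s in range(8):
        n = 2000
        X = pd.DataFrame(
            rng.normal(size=(n, 11)), columns=["signal"] + [f"noise{i}" for i in range(10)]
        )
        y = 2.0 * X["signal"] + rng.normal(size=n)
        sel = models.l1_select(X, y, "regression", seed=s)
        kept_signal += "signal" in sel
        noise_frac.append(sum(c.startswith("noise") for c in sel) / 10)
    assert kept_signal == 8
    # lasso-with-inner-CV keeps some noise, but far from all of it
    assert np.mean(noise_frac) < 0.5


def test_l1_always_keep_contract():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.normal(size=(300, 4)), columns=["lon", "lat", "a", "b"])
    y = pd.Series(rng.normal(size=300))  # coordinates carry no signal
    sel = models.l1_select(X, y, "regression", seed=0, always_keep=("lon", "lat"))
    assert sel[:2] == ["lon", "lat"]


def test_majority_baseline():
    assert models.majority_baseline([1, 1, 1, 0, 0]) == 0.6
    assert models.majority_baseline([0, 1, 0, 1]) == 0.5
    assert models.majority_baseline([1, 1]) == 1.0


def test_metrics_definitions():
    m = models.compute_metrics([0.9, 0.1], [1, 0], "classification")
    assert m["auc"] == 1.0 and m["accuracy"] == 1.0
    m2 = models.compute_metrics([0.7, 0.7], [1, 0], "classification")
    assert m2["auc"] == 0.5  # tie credited half
    m3 = models.compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "regression")
    assert m3["rmse"] == 0.0 and m3["r2"] == 1.0
    with pytest.raises(ValueError):
        models.compute_metrics([0.5], [1, 0], "classification")


def test_cv_predicts_every_row_once(small_data, small_context):
    ev = small_data.events
    spec = models.ModelSpec("S1", "log_delay", "lasso_lm", seed=0)
    X, y, _ = models.assemble_features(ev, spec, small_context)
    cv = models.fit_predict_cv(X, y, spec)
    assert len(cv.predictions) == len(ev)
    assert cv.predictions.index.equals(X.index)
    assert np.isfinite(cv.predictions).all()
    counts = np.bincount(cv.fold_assignment, minlength=spec.cv_folds)
    assert counts.sum() == len(ev) and (counts > 0).all()


def test_separable_target_near_perfect_auc():
    rng = np.random.default_rng(3)
    n = 400
    X = pd.DataFrame({"x": rng.normal(size=n), "z": rng.normal(size=n)})
    y = pd.Series((X["x"] > 0).astype(int))
    spec = models.ModelSpec("NS1", "d_day", "gradient_boosting", seed=0)
    cv = models.fit_predict_cv(X, y, spec)
    assert cv.metrics["auc"] >= 0.99


def test_null_target_auc_near_half_and_r2_near_zero():
    rng = np.random.default_rng(4)
    aucs, r2s = [], []
    for s in range(5):
        n = 1500
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        yb = pd.Series(rng.integers(0, 2, n))
        spec = models.ModelSpec("NS1", "d_day", "lasso_lm", seed=s)
        aucs.append(models.fit_predict_cv(X, yb, spec).metrics["auc"])
        yr = pd.Series(rng.normal(size=n))
        spec_r = models.ModelSpec("NS1", "log_delay", "lasso_lm", seed=s)
        r2s.append(models.fit_predict_cv(X, yr, spec_r).metrics["r2"])
    assert 0.45 < np.mean(aucs) < 0.55
    assert np.mean(r2s) <= 0.02


def test_fixed_seed_gives_identical_metrics(small_data, small_context):
    ev = small_data.events
    spec = models.ModelSpec("S3", "d_week", "random_forest", seed=5)
    X, y, _ = models.assemble_features(ev, spec, small_context)
    a = models.fit_predict_cv(X, y, spec)
    b = models.fit_predict_cv(X, y, spec)
    assert a.metrics == b.metrics
    assert np.array_equal(a.predictions.to_numpy(), b.predictions.to_numpy())


def test_no_leakage_from_test_fold_targets(small_data, small_context):
    """Corrupting one test fold's regression targets leaves that fold's
    out-of-sample predictions unchanged (training never saw them)."""
    ev = small_data.events
    spec = models.ModelSpec("NS2", "log_delay", "lasso_lm", seed=2)
    X, y, _ = models.assemble_features(ev, spec)
    cv = models.fit_predict_cv(X, y, spec)
    fold0 = cv.fold_assignment == 0
    y_bad = y.copy()
    y_bad.loc[y_bad.index[fold0]] = 99.0
    cv_bad = models.fit_predict_cv(X, y_bad, spec)
    assert np.allclose(
        cv.predictions.to_numpy()[fold0], cv_bad.predictions.to_numpy()[fold0]
    )


def test_gp_learner_runs_on_small_n():
    data = rd.generate(rd.preset("spatial", seed=31, n_events=250, grid_tracts=(10, 10)))
    ctx = areal.event_context(data.events, data.tracts, None, "point")
    spec = models.ModelSpec(
        "S3", "log_delay", "gaussian_process", cv_folds=3, seed=0, gp_max_train=150
    )
    X, y, _ = models.assemble_features(data.events, spec, ctx)
    cv = models.fit_predict_cv(X, y, spec)
    assert np.isfinite(cv.metrics["rmse"])
    # coordinates bypass L1 selection in every fold
    for sel in cv.selected_features:
        assert sel[:2] == ["lon", "lat"]
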