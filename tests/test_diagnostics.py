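import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

import reportdelay as rd
from reportdelay import diagnostics, weights


def test_rsa_calibrated_on_shuffled_residuals():
    """Residuals shuffled over locations show no spatial structure: the
    pseudo p-values are roughly uniform."""
    rng = np.random.default_rng(0)
    labels = np.repeat(np.arange(20), 10)
    w = weights.same_district_weights(labels)
    ps = []
    for _ in range(60):
        res = rng.normal(size=200)
        ps.append(diagnostics.rsa_test(res, w, n_perm=99, seed=int(rng.integers(2**31))).pseudo_p)
    ps = np.array(ps)
    assert 0.0 < (ps < 0.05).mean() < 0.15
    assert 0.3 < (ps < 0.5).mean() < 0.7


def test_rsa_detects_clustered_residuals():
    rng = np.random.default_rng(1)
    labels = np.repeat(np.arange(20), 10)
    w = weights.same_district_weights(labels)
    res = rng.normal(size=200) + np.repeat(rng.normal(0, 2, 20), 10)
    out = diagnostics.rsa_test(res, w, n_perm=199, seed=0)
    assert out.pseudo_p < 0.01


def test_rsa_rejects_nonfinite_and_constant():
    w = weights.same_district_weights([0, 0, 1, 1])
    with pytest.raises(ValueError):
        diagnostics.rsa_test([1.0, np.nan, 0.0, 2.0], w)
    with pytest.raises(ValueError, match="variance"):
        diagnostics.rsa_test([1.0, 1.0, 1.0, 1.0], w)


def test_significant_coefficients_recover_injected_effect():
    rng = np.random.default_rng(2)
    n = 1500
    X = pd.DataFrame(
        {
            "federal": rng.integers(0, 2, n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        }
    )
    y = 1.0 * X["federal"] + rng.normal(size=n)
    out = diagnostics.significant_coefficients(X, y, "regression")
    row = out.set_index("feature").loc["federal"]
    assert row["coef"] > 0 and row["p"] < 0.05


def test_significant_coefficients_type_i_rate():
    """Pure-noise features are flagged at roughly the nominal 5% level."""
    rng = np.random.default_rng(3)
    flagged = total = 0
    for _ in range(30):
        X = pd.DataFrame(rng.normal(size=(300, 8)), columns=[f"f{i}" for i in range(8)])
        y = rng.normal(size=300)
        out = diagnostics.significant_coefficients(X, y, "regression")
        flagged += len(out)
        total += 8
    rate = flagged / total
    assert 0.005 < rate < 0.12


def test_aliased_columns_dropped():
    rng = np.random.default_rng(4)
    X = pd.DataFrame({"a": rng.normal(size=200)})
    X["b"] = 2 * X["a"]  # perfectly collinear
    y = X["a"] + rng.normal(size=200, scale=0.1)
    out = diagnostics.significant_coefficients(X, y, "regression")
    assert "b" not in set(out["feature"])


def test_logistic_refit_on_binary_target():
    rng = np.random.default_rng(5)
    n = 1200
    X = pd.DataFrame({"u18": rng.integers(0, 2, n), "noise": rng.normal(size=n)})
    logit = -0.5 + 1.2 * X["u18"]
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    out = diagnostics.significant_coefficients(X, y, "classification")
    row = out.set_index("feature").loc["u18"]
    assert row["coef"] > 0 and row["p"] < 0.05


@pytest.fixture(scope="module")
def rf_fit():
    rng = np.random.default_rng(6)
    n = 600
    X = pd.DataFrame(
        {
            "driver": rng.normal(size=n),
            "bystander": rng.normal(size=n),
        }
    )
    y = X["driver"] * 2.0 + 0.1 * rng.normal(size=n)
    rf = RandomForestRegressor(n_estimators=100, random_state=0).fit(X, y)
    return rf, X, y


def test_permutation_importance_ranks_driver_first(rf_fit):
    rf, X, y = rf_fit
    imp = diagnostics.permutation_importance(rf, X, y, "rmse", n_repeats=5, seed=0)
    t = imp.table.set_index("feature")
    assert t.loc["driver", "rank"] == 1
    assert t.loc["driver", "importance"] > 10 * abs(t.loc["bystander", "importance"])
    assert abs(t.loc["bystander", "importance"]) < 0.05
    assert sorted(imp.table["rank"]) == [1, 2]


def test_duplicated_feature_masks_importance():
    rng = np.random.default_rng(7)
    n = 600
    base = rng.normal(size=n)
    y = 2.0 * base + 0.1 * rng.normal(size=n)
    X1 = pd.DataFrame({"driver": base, "noise": rng.normal(size=n)})
    X2 = X1.copy()
    X2["driver_copy"] = base
    rf1 = RandomForestRegressor(n_estimators=100, random_state=0).fit(X1, y)
    rf2 = RandomForestRegressor(n_estimators=100, random_state=0).fit(X2, y)
    i1 = diagnostics.permutation_importance(rf1, X1, y, "rmse", 5, seed=0).table
    i2 = diagnostics.permutation_importance(rf2, X2, y, "rmse", 5, seed=0).table
    solo = i1.set_index("feature").loc["driver", "importance"]
    dup = i2.set_index("feature").loc["driver", "importance"]
    dup_copy = i2.set_index("feature").loc["driver_copy", "importance"]
    assert dup < solo and dup_copy < solo


def test_importance_metric_mismatch_errors(rf_fit):
    rf, X, y = rf_fit
    with pytest.raises(ValueError):
        diagnostics.permutation_importance(rf, X, y, "nonsense", 3, seed=0)


def test_staged_rsa_pattern_on_spatial_scenario(spatial_data):
    """Non-spatial model residuals stay spatially clustered; the combined
    spatial model absorbs the signal (qualitative staged-model pattern)."""
    from reportdelay import areal, models

    ev = spatial_data.events
    ctx = areal.event_context(ev, spatial_data.tracts, None, "point")
    w = weights.same_district_weights(ev["district_id"].to_numpy())
    ps = {}
    for name, context in (("NS1", None), ("S3", ctx)):
        spec = models.ModelSpec(name, "log_delay", "gradient_boosting", seed=3)
        X, y, _ = models.assemble_features(ev, spec, context)
        cv = models.fit_predict_cv(X, y, spec)
        ps[name] = diagnostics.rsa_test(cv.residuals.to_numpy(), w, 199, seed=3).pseudo_p
    assert ps["NS1"] < 0.05
    assert ps["S3"] >= 0.05
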