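"""Residual spatial autocorrelation, significant coefficients and
permutation importance for the staged models.

The non-spatial baselines should leave spatially clustered residuals
(small Moran pseudo p under same-district weights); the combined spatial
model should not.  The coefficient refit should recover the injected
positive federal-holiday and under-18 effects on log-delay.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from reportdelay import areal, delays, diagnostics, io, models, weights

OUT = Path("results/tables")
OUT.mkdir(parents=True, exist_ok=True)

ev = delays.add_delay_columns(io.read_events_csv("results/data/spatial_events.csv"))
ev = delays.ensure_temporal_features(ev)
tracts = io.read_areas_geojson("results/data/spatial_tracts.geojson", "tract_id")
ctx = areal.event_context(ev, tracts, None, "point")
w = weights.same_district_weights(ev["district_id"].to_numpy())

rows = []
for name in ("NS1", "NS2", "S1", "S2", "S3"):
    spec = models.ModelSpec(name, "log_delay", "gradient_boosting", seed=7)
    X, y, _ = models.assemble_features(ev, spec, ctx if "X" in spec.feature_groups else None)
    cv = models.fit_predict_cv(X, y, spec)
    rsa = diagnostics.rsa_test(cv.residuals.to_numpy(), w, n_perm=999, seed=7)
    rows.append((name, rsa.statistic, rsa.pseudo_p, int(rsa.pseudo_p < 0.05)))
    print(f"{name}: residual Moran I={rsa.statistic:+.4f} pseudo p={rsa.pseudo_p:.3f}")
pd.DataFrame(rows, columns=["model", "moran_i", "pseudo_p", "significant"]).to_csv(
    OUT / "rsa_tests.csv", index=False
)

spec = models.ModelSpec("S3", "log_delay", "lasso_lm", seed=7)
X, y, _ = models.assemble_features(ev, spec, ctx)
sel = models.l1_select(X, y, "regression", seed=7, always_keep=("lon", "lat"))
coefs = diagnostics.significant_coefficients(X, y, "regression", selected=sel)
coefs.to_csv(OUT / "significant_coefficients.csv", index=False)
print("\nsignificant coefficients (p < 0.05):")
print(coefs.to_string(index=False))

rf_spec = models.ModelSpec("S3", "log_delay", "random_forest", seed=7)
rf = models._make_learner(rf_spec, X.shape[1])
rf.fit(X.to_numpy(dtype=float), np.asarray(y))
imp = diagnostics.permutation_importance(rf, X, y, "rmse", n_repeats=5, seed=7)
imp.table.head(10).to_csv(OUT / "permutation_importance_top10.csv", index=False)
print("\ntop-10 permutation importance (RMSE increase when shuffled):")
print(imp.table.head(10).to_string(index=False))
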