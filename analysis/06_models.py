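"""Staged model comparison under 10-fold cross-validation.

Fits the five specifications (survivor-only NS1 through the combined
spatial model S3) on the spatial scenario for the one-month indicator and
the log-delay, with the L1 linear model and gradient boosting, and writes
a metrics table (rows = learner, columns = specification).
"""

from pathlib import Path

import pandas as pd

from reportdelay import areal, delays, io, models

OUT = Path("results/tables")
OUT.mkdir(parents=True, exist_ok=True)

ev = delays.add_delay_columns(io.read_events_csv("results/data/spatial_events.csv"))
ev = delays.ensure_temporal_features(ev)
tracts = io.read_areas_geojson("results/data/spatial_tracts.geojson", "tract_id")
ctx = areal.event_context(ev, tracts, None, "point")

rows = []
for target in ("d_month", "log_delay"):
    for learner in ("lasso_lm", "gradient_boosting"):
        for name in ("NS1", "NS2", "S1", "S2", "S3"):
            spec = models.ModelSpec(name, target, learner, seed=6)
            X, y, _ = models.assemble_features(ev, spec, ctx if "X" in spec.feature_groups else None)
            cv = models.fit_predict_cv(X, y, spec)
            row = {"target": target, "learner": learner, "model": name, **cv.metrics}
            if spec.task == "classification":
                row["majority_baseline"] = models.majority_baseline(y)
            rows.append(row)
            metric = "auc" if spec.task == "classification" else "rmse"
            print(f"{target:9s} {learner:18s} {name}: {metric}={cv.metrics[metric]:.3f}")

pd.DataFrame(rows).to_csv(OUT / "model_metrics.csv", index=False)
print("wrote", OUT / "model_metrics.csv")
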