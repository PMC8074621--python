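"""End-to-end pipeline: simulate (or load) -> delay processing -> areal
aggregation -> spatial autocorrelation -> disparity tests -> model grid ->
residual diagnostics -> coefficients and importance.

Every artefact is written as CSV under the output directory together with
a JSON manifest recording the configuration and all seeds, which suffices
to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import areal, delays, diagnostics, disparity, io, models, moran, synth, weights

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``preset`` or (``events_csv``, ``tracts_geojson``,
    ``districts_geojson``) must be given.
    """

    output_dir: str = "results/run"
    preset: str | None = "null"
    events_csv: str | None = None
    tracts_geojson: str | None = None
    districts_geojson: str | None = None
    coordinate_regime: str = "point"
    weights_scheme: str = "same_district"  # event-level RSA scheme
    knn_k: int = 50
    n_perm: int = 999
    envelope_perm: int = 1000
    model_names: tuple = ("NS1", "NS2", "S1", "S2", "S3")
    learners: tuple = ("lasso_lm",)
    targets: tuple = ("d_month", "log_delay")
    importance_top: int = 10
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        """Load a run configuration from a JSON file (tuples restored)."""
        raw = json.loads(Path(path).read_text())
        tuple_fields = {"model_names", "learners", "targets"}
        kwargs = {
            k: tuple(v) if k in tuple_fields and isinstance(v, list) else v
            for k, v in raw.items()
        }
        return cls(**kwargs)

    def validate(self):
        from_files = all(
            p is not None
            for p in (self.events_csv, self.tracts_geojson, self.districts_geojson)
        )
        if (self.preset is None) == (not from_files):
            raise ValueError("give exactly one of a preset or the three input paths")


def _event_weights(events: pd.DataFrame, scheme: str, k: int) -> weights.SpatialWeights:
    if scheme == "same_district":
        return weights.same_district_weights(
            events["district_id"].to_numpy(), ids=events["event_id"].to_numpy()
        )
    if scheme == "knn":
        return weights.knn_weights(
            events[["lon", "lat"]].to_numpy(), k, ids=events["event_id"].to_numpy()
        )
    raise ValueError(f"unknown weights scheme {scheme!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the artefact dictionary also written to
    ``config.output_dir``.  Any stage error aborts with the stage name."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(8)
    artefacts: dict = {}
    stage = "simulate/load"
    try:
        if config.preset is not None:
            cfg = synth.preset(config.preset, seed=int(seeds[0]) % 2**31)
            data = synth.generate(cfg)
            events, tracts, districts = data.events, data.tracts, data.districts
            regime = cfg.coordinate_regime
            artefacts["truth_district_effects"] = data.truth["district_effects"]
        else:
            events = io.read_events_csv(config.events_csv)
            tracts = io.read_areas_geojson(config.tracts_geojson, "tract_id")
            districts = io.read_areas_geojson(config.districts_geojson, "district_id")
            regime = config.coordinate_regime
            events = delays.add_delay_columns(events)
            events = delays.ensure_temporal_features(events)

        stage = "delay processing"
        summary = delays.area_summaries(events, districts["district_id"])
        summary.to_csv(out / "district_summary.csv")
        artefacts["district_summary"] = summary

        stage = "areal aggregation"
        iw = areal.intersection_weights(tracts, districts)
        district_attrs = areal.aggregate_attributes(tracts, iw)
        iw.to_csv(out / "intersection_weights.csv", index=False)
        district_attrs.to_csv(out / "district_attributes.csv")
        context = areal.event_context(events, tracts, district_attrs, regime)
        artefacts["district_attributes"] = district_attrs

        stage = "spatial autocorrelation"
        occupied = summary.loc[summary["n"] > 0]
        qw = weights.queen_weights(
            districts.set_index("district_id").loc[occupied.index, "geometry"],
            ids=occupied.index.to_numpy(),
        )
        moran_rows = []
        for col in ("p_day", "p_week", "p_month", "mean_log_delay"):
            res = moran.global_moran(
                occupied[col].to_numpy(), qw, n_perm=config.n_perm,
                seed=int(seeds[1]) % 2**31,
            )
            moran_rows.append((col, res.statistic, res.pseudo_p))
        moran_tbl = pd.DataFrame(moran_rows, columns=["variable", "moran_i", "pseudo_p"])
        moran_tbl.to_csv(out / "moran_global.csv", index=False)
        artefacts["moran_global"] = moran_tbl

        stage = "disparity tests"
        env = disparity.ranked_median_envelope(
            events["delay_days"], events["district_id"],
            n_perm=config.envelope_perm, seed=int(seeds[2]) % 2**31,
        )
        env_tbl = pd.DataFrame(
            {
                "rank": np.arange(1, len(env.observed_ranked) + 1),
                "observed": env.observed_ranked,
                "null_mean": env.null_mean,
                "ci_low": env.ci_low,
                "ci_high": env.ci_high,
                "outside": env.outside.astype(int),
            }
        )
        env_tbl.to_csv(out / "ranked_median_envelope.csv", index=False)
        disp_rows = []
        for statistic in ("gini", "idr"):
            res = disparity.disparity_test(
                events["delay_days"], events["district_id"], statistic,
                n_perm=config.n_perm, seed=int(seeds[3]) % 2**31,
            )
            disp_rows.append((statistic, res.observed, res.p_value))
        disp_tbl = pd.DataFrame(disp_rows, columns=["statistic", "observed", "p"])
        disp_tbl.to_csv(out / "disparity_tests.csv", index=False)
        artefacts["envelope"] = env_tbl
        artefacts["disparity"] = disp_tbl

        stage = "model grid"
        ew = _event_weights(events, config.weights_scheme, config.knn_k)
        metric_rows, rsa_rows = [], []
        results: dict = {}
        for target in config.targets:
            for name in config.model_names:
                for learner in config.learners:
                    if learner == "gaussian_process" and name != "S3":
                        continue
                    spec = models.ModelSpec(
                        name, target, learner, seed=int(seeds[4]) % 2**31
                    )
                    matrix, y, _ = models.assemble_features(events, spec, context)
                    cv = models.fit_predict_cv(matrix, y, spec)
                    results[(target, name, learner)] = cv
                    row = {"target": target, "model": name, "learner": learner}
                    row.update(cv.metrics)
                    if spec.task == "classification":
                        row["majority_baseline"] = models.majority_baseline(y)
                    metric_rows.append(row)
                    rsa = diagnostics.rsa_test(
                        cv.residuals.to_numpy(), ew, n_perm=config.n_perm,
                        seed=int(seeds[5]) % 2**31,
                    )
                    rsa_rows.append(
                        {
                            "target": target, "model": name, "learner": learner,
                            "moran_i": rsa.statistic, "pseudo_p": rsa.pseudo_p,
                            "significant": int(rsa.pseudo_p < 0.05),
                        }
                    )
        metrics_tbl = pd.DataFrame(metric_rows)
        metrics_tbl.to_csv(out / "model_metrics.csv", index=False)
        rsa_tbl = pd.DataFrame(rsa_rows)
        rsa_tbl.to_csv(out / "rsa_tests.csv", index=False)
        artefacts["model_metrics"] = metrics_tbl
        artefacts["rsa"] = rsa_tbl
        artefacts["cv_results"] = results

        stage = "coefficients and importance"
        coef_frames = []
        for target in config.targets:
            spec = models.ModelSpec("S3", target, "lasso_lm", seed=int(seeds[6]) % 2**31)
            matrix, y, _ = models.assemble_features(events, spec, context)
            sel = models.l1_select(
                matrix, y, spec.task, seed=spec.seed, always_keep=("lon", "lat")
            )
            coefs = diagnostics.significant_coefficients(
                matrix, y, spec.task, selected=sel
            )
            coefs.insert(0, "target", target)
            coef_frames.append(coefs)
        coef_tbl = pd.concat(coef_frames, ignore_index=True)
        coef_tbl.to_csv(out / "significant_coefficients.csv", index=False)
        artefacts["coefficients"] = coef_tbl

        spec = models.ModelSpec("S3", "log_delay", "random_forest",
                                seed=int(seeds[7]) % 2**31)
        matrix, y, _ = models.assemble_features(events, spec, context)
        rf = models._make_learner(spec, matrix.shape[1])
        rf.fit(matrix.to_numpy(dtype=float), np.asarray(y))
        imp = diagnostics.permutation_importance(
            rf, matrix, y, "rmse", n_repeats=5, seed=int(seeds[7]) % 2**31
        )
        top = imp.table.head(config.importance_top)
        top.to_csv(out / "permutation_importance.csv", index=False)
        artefacts["importance"] = top
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stage_seeds": [int(s) % 2**31 for s in seeds],
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artefacts["manifest"] = manifest
    return artefacts
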