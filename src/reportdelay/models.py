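"""Staged predictive models for reporting delays.

Five specifications differ only in which feature groups they use:

* NS1 — survivor characteristics V only
* NS2 — V + temporal flags Z
* S1  — V + Z + areal socio-economic attributes X ("random effects")
* S2  — V + Z + district dummies Q ("fixed effects")
* S3  — V + Z + X + point coordinates C (no district dummies)

Each specification can be fit with an L1-regularised linear/logistic model,
a random forest, gradient boosting, or (S3 only) a Gaussian process with a
spatial kernel over the coordinates.  Evaluation is by k-fold
cross-validation with standardisation and any feature selection performed
strictly inside each training fold; predictions are pooled out-of-sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessClassifier, GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import LassoCV, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

FEATURE_GROUPS = {
    "NS1": frozenset("V"),
    "NS2": frozenset("ZV"),
    "S1": frozenset("XZV"),
    "S2": frozenset("QZV"),
    "S3": frozenset("XCZV"),
}
CLASSIFICATION_TARGETS = ("d_day", "d_week", "d_month")
REGRESSION_TARGETS = ("log_delay",)
LEARNERS = ("lasso_lm", "random_forest", "gradient_boosting", "gaussian_process")

# reference levels dropped from one-hot blocks
RACE_REFERENCE = "other"
AGE_REFERENCE = "25.44"
SEASON_REFERENCE = "fall"


@dataclass
class ModelSpec:
    name: str
    target: str
    learner: str = "lasso_lm"
    cv_folds: int = 10
    seed: int = 0
    gp_max_train: int = 1000  # subset-of-data cap for exact GP inference

    def __post_init__(self):
        if self.name not in FEATURE_GROUPS:
            raise ValueError(f"unknown model name {self.name!r}")
        if self.target not in CLASSIFICATION_TARGETS + REGRESSION_TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if self.learner not in LEARNERS:
            raise ValueError(f"unknown learner {self.learner!r}")
        if self.learner == "gaussian_process" and "C" not in self.feature_groups:
            raise ValueError(
                "gaussian_process requires coordinates (C); only S3 includes them"
            )

    @property
    def feature_groups(self) -> frozenset:
        return FEATURE_GROUPS[self.name]

    @property
    def task(self) -> str:
        return "classification" if self.target in CLASSIFICATION_TARGETS else "regression"


@dataclass
class CVResult:
    spec: ModelSpec
    predictions: pd.Series  # pooled out-of-sample (probabilities for classification)
    metrics: dict
    residuals: pd.Series
    selected_features: list = field(default_factory=list)
    fold_assignment: np.ndarray | None = None


def survivor_features(events: pd.DataFrame) -> pd.DataFrame:
    """One-hot survivor block with dropped reference levels
    (race 'other', age band '25.44')."""
    out = pd.DataFrame(index=events.index)
    for race in ("white", "black", "latin", "asian"):
        out[f"vict.{race}"] = (events["vict.race"] == race).astype(np.int8)
    out["vict.female"] = events["vict.female"].astype(np.int8)
    for band in ("u18", "18.24", "45.64", "o64"):
        out[f"vict.{band}"] = (events["vict.age"] == band).astype(np.int8)
    return out


def temporal_block(events: pd.DataFrame) -> pd.DataFrame:
    cols = ["winter", "spring", "summer", "weekend", "federal", "christian",
            "muslim", "jewish", "hindu", "celebration"]
    return events[cols].astype(np.int8)


def assemble_features(
    events: pd.DataFrame,
    spec: ModelSpec,
    areal_context: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Design matrix, target and a column->group map for one specification.

    ``areal_context`` is the per-event areal attribute frame (tract raw
    attributes under the point regime, district aggregates under the
    centroid regime) and is required for the X group.
    """
    blocks: list[pd.DataFrame] = []
    groups: dict[str, str] = {}
    g = spec.feature_groups
    if "V" in g:
        v = survivor_features(events)
        blocks.append(v)
        groups.update({c: "V" for c in v.columns})
    if "Z" in g:
        z = temporal_block(events)
        blocks.append(z)
        groups.update({c: "Z" for c in z.columns})
    if "X" in g:
        if areal_context is None:
            raise ValueError(f"model {spec.name} needs areal context for group X")
        x = areal_context.astype(float)
        blocks.append(x)
        groups.update({c: "X" for c in x.columns})
    if "Q" in g:
        dummies = pd.get_dummies(
            events["district_id"], prefix="district", dtype=np.int8
        )
        dummies = dummies.iloc[:, 1:]  # drop reference (smallest id)
        blocks.append(dummies)
        groups.update({c: "Q" for c in dummies.columns})
    if "C" in g:
        if events[["lon", "lat"]].isna().any().any():
            raise ValueError(f"model {spec.name} needs coordinates for group C")
        c = events[["lon", "lat"]].astype(float)
        blocks.append(c)
        groups.update({"lon": "C", "lat": "C"})
    matrix = pd.concat(blocks, axis=1)
    y = events[spec.target]
    return matrix, y, groups


def l1_select(
    matrix: pd.DataFrame,
    target,
    task: str,
    seed: int = 0,
    always_keep: tuple = (),
    inner_folds: int = 5,
) -> list[str]:
    """Features with nonzero coefficients of an L1-penalised linear model at
    a penalty chosen by inner cross-validation; ``always_keep`` columns
    (the coordinates in S3) bypass selection."""
    candidates = [c for c in matrix.columns if c not in always_keep]
    if len(matrix.columns) < 2:
        raise ValueError("feature selection needs at least 2 features")
    X = StandardScaler().fit_transform(matrix[candidates].to_numpy(dtype=float))
    y = np.asarray(target, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if task == "regression":
            model = LassoCV(cv=inner_folds, random_state=seed, alphas=40)
            model.fit(X, y)
            coefs = model.coef_
        else:
            model = LogisticRegressionCV(
                Cs=10, cv=inner_folds, penalty="l1", solver="liblinear",
                random_state=seed, max_iter=200,
            )
            model.fit(X, y.astype(int))
            coefs = model.coef_.ravel()
    selected = [c for c, b in zip(candidates, coefs) if b != 0]
    if not selected:
        logger.warning("L1 selection kept no features; falling back to intercept-only")
    return list(always_keep) + selected


def _make_learner(spec: ModelSpec, n_features: int):
    seed = spec.seed
    if spec.learner == "lasso_lm":
        if spec.task == "regression":
            return LassoCV(cv=5, random_state=seed, alphas=40)
        return LogisticRegressionCV(
            Cs=10, cv=5, penalty="l1", solver="liblinear",
            random_state=seed, max_iter=200,
        )
    if spec.learner == "random_forest":
        cls = RandomForestRegressor if spec.task == "regression" else RandomForestClassifier
        return cls(n_estimators=200, min_samples_leaf=5, random_state=seed, n_jobs=1)
    if spec.learner == "gradient_boosting":
        import xgboost as xgb

        cls = xgb.XGBRegressor if spec.task == "regression" else xgb.XGBClassifier
        return cls(
            n_estimators=200, max_depth=3, learning_rate=0.1,
            random_state=seed, n_jobs=1, verbosity=0,
        )
    raise AssertionError(spec.learner)


def _gp_kernel(n_features: int):
    # automatic-relevance RBF: one learned length-scale per dimension, so
    # the spatial coordinates and the selected covariates each get their own
    return ConstantKernel(1.0) * RBF(length_scale=np.ones(n_features))


class _GPLearner:
    """Gaussian-process learner: automatic-relevance squared-exponential
    kernel over the standardised coordinates and the L1-pre-selected
    remaining features; exact inference on at most ``max_train`` training
    points (random subset beyond that)."""

    def __init__(self, spec: ModelSpec, coord_cols: list[str]):
        self.spec = spec
        self.coord_cols = coord_cols

    def fit(self, X: pd.DataFrame, y):
        spec = self.spec
        rng = np.random.default_rng(spec.seed)
        self.selected_ = l1_select(
            X, y, spec.task, seed=spec.seed, always_keep=tuple(self.coord_cols)
        )
        Xs = X[self.selected_]
        kernel = _gp_kernel(len(self.selected_))
        if len(Xs) > spec.gp_max_train:
            idx = rng.choice(len(Xs), spec.gp_max_train, replace=False)
            Xs, y = Xs.iloc[idx], np.asarray(y)[idx]
        if spec.task == "regression":
            self.model_ = GaussianProcessRegressor(
                kernel=kernel + WhiteKernel(1.0),
                normalize_y=True,
                random_state=spec.seed,
            )
        else:
            self.model_ = GaussianProcessClassifier(
                kernel=kernel, random_state=spec.seed
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.model_.fit(Xs.to_numpy(dtype=float), np.asarray(y))
        return self

    def predict(self, X: pd.DataFrame):
        return self.model_.predict(X[self.selected_].to_numpy(dtype=float))

    def predict_proba(self, X: pd.DataFrame):
        return self.model_.predict_proba(X[self.selected_].to_numpy(dtype=float))


def majority_baseline(target) -> float:
    """Accuracy of always predicting the most frequent class."""
    y = pd.Series(target)
    return float(y.value_counts(normalize=True).max())


def compute_metrics(predictions, truth, task: str) -> dict:
    """Pooled out-of-sample metrics: accuracy at a 0.5 threshold and
    rank-based AUC (ties credited 0.5) for classification; RMSE and R^2
    for regression."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truth, dtype=float)
    if len(p) != len(t):
        raise ValueError("predictions and truth differ in length")
    if task == "classification":
        acc = float(np.mean((p >= 0.5) == (t == 1)))
        if len(np.unique(t)) < 2:
            auc = None
            logger.warning("AUC undefined: single-class truth")
        else:
            auc = float(roc_auc_score(t, p))
        return {"accuracy": acc, "auc": auc}
    sse = float(((t - p) ** 2).sum())
    sst = float(((t - t.mean()) ** 2).sum())
    return {"rmse": float(np.sqrt(sse / len(t))), "r2": 1.0 - sse / sst}


def fit_predict_cv(
    matrix: pd.DataFrame, target: pd.Series, spec: ModelSpec
) -> CVResult:
    """k-fold cross-validated fit: folds stratified by class for binary
    targets; scaling (and, for the GP, L1 pre-selection) refit inside each
    training fold; every row predicted exactly once out-of-sample."""
    y = np.asarray(target)
    n = len(matrix)
    if n < 2 * spec.cv_folds:
        raise ValueError("too few rows for the requested number of folds")
    if spec.task == "classification":
        # stratified folds; if a training fold still ends up single-class
        # (pathologically rare classes), folds are redrawn once, then error
        for attempt in (spec.seed, spec.seed + 1):
            splitter = StratifiedKFold(spec.cv_folds, shuffle=True, random_state=attempt)
            split = list(splitter.split(matrix, y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in split):
                break
        else:
            raise ValueError("training fold with a single class after redraw")
    else:
        splitter = KFold(spec.cv_folds, shuffle=True, random_state=spec.seed)
        split = list(splitter.split(matrix))
    preds = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    selected: list = []
    coord_cols = [c for c in ("lon", "lat") if c in matrix.columns]
    for fold, (tr, te) in enumerate(split):
        scaler = StandardScaler().fit(matrix.iloc[tr].to_numpy(dtype=float))
        Xtr = pd.DataFrame(
            scaler.transform(matrix.iloc[tr].to_numpy(dtype=float)),
            columns=matrix.columns, index=matrix.index[tr],
        )
        Xte = pd.DataFrame(
            scaler.transform(matrix.iloc[te].to_numpy(dtype=float)),
            columns=matrix.columns, index=matrix.index[te],
        )
        if spec.learner == "gaussian_process":
            model = _GPLearner(spec, coord_cols).fit(Xtr, y[tr])
            selected.append(model.selected_)
        else:
            model = _make_learner(spec, matrix.shape[1])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Xtr.to_numpy(dtype=float), y[tr])
        if spec.task == "classification":
            if isinstance(model, _GPLearner):
                preds[te] = model.predict_proba(Xte)[:, 1]
            else:
                preds[te] = model.predict_proba(Xte.to_numpy(dtype=float))[:, 1]
        else:
            preds[te] = model.predict(Xte if isinstance(model, _GPLearner) else Xte.to_numpy(dtype=float))
        fold_of[te] = fold
    predictions = pd.Series(preds, index=matrix.index, name="prediction")
    residuals = pd.Series(y.astype(float) - preds, index=matrix.index, name="residual")
    metrics = compute_metrics(preds, y, spec.task)
    return CVResult(spec, predictions, metrics, residuals, selected, fold_of)
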