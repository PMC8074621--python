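"""Model diagnostics: residual spatial autocorrelation, significant
coefficients of the selected linear model, and permutation feature
importance.

Residuals are pooled out-of-sample values (observed minus predicted value
for regression; observed label minus predicted probability for
classification, which keeps Moran's I applicable to a continuous vector).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .moran import MoranResult, global_moran
from .weights import SpatialWeights

logger = logging.getLogger(__name__)


def rsa_test(
    residuals, weights: SpatialWeights, n_perm: int = 999, seed=None
) -> MoranResult:
    """Global Moran's I permutation test on model residuals.

    A small pseudo p means the model left spatially clustered errors; a
    model that absorbed the spatial signal should test non-significant.
    """
    res = np.asarray(residuals, dtype=float)
    if not np.all(np.isfinite(res)):
        raise ValueError("residuals contain non-finite values")
    return global_moran(res, weights, n_perm=n_perm, seed=seed)


def _drop_aliased(X: pd.DataFrame) -> pd.DataFrame:
    """Drop columns that are perfectly collinear with earlier ones."""
    keep: list[str] = []
    arr = np.empty((len(X), 0))
    for c in X.columns:
        cand = np.column_stack([arr, X[c].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) > arr.shape[1]:
            keep.append(c)
            arr = cand
        else:
            logger.warning("dropping aliased column %r from coefficient refit", c)
    return X[keep]


def significant_coefficients(
    matrix: pd.DataFrame,
    target,
    task: str,
    alpha: float = 0.05,
    selected: list | None = None,
) -> pd.DataFrame:
    """Unpenalised refit on the (L1-selected) feature set with Wald p-values.

    Least squares for the regression target, maximum-likelihood logistic
    regression for binary targets.  Returns rows with p < alpha sorted by
    ascending p (columns: feature, coef, p).  Being a refit on a selected
    support, the p-values carry the usual post-selection caveat.
    """
    X = matrix[selected] if selected is not None else matrix
    X = _drop_aliased(X)
    Xc = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    y = np.asarray(target, dtype=float)
    if task == "regression":
        fit = sm.OLS(y, Xc).fit()
    else:
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    rows = pd.DataFrame(
        {"feature": X.columns, "coef": fit.params[1:], "p": fit.pvalues[1:]}
    )
    out = rows.loc[rows["p"] < alpha].sort_values("p").reset_index(drop=True)
    return out


@dataclass
class ImportanceTable:
    table: pd.DataFrame  # feature, importance, rank
    metric: str
    n_repeats: int
    seed: int | None


_LOSS_METRICS = {"rmse"}
_GAIN_METRICS = {"r2", "auc", "accuracy"}


def _score(model, X: np.ndarray, y: np.ndarray, metric: str) -> float:
    if metric in ("auc", "accuracy"):
        p = model.predict_proba(X)[:, 1]
        if metric == "accuracy":
            return float(np.mean((p >= 0.5) == (y == 1)))
        from sklearn.metrics import roc_auc_score

        return float(roc_auc_score(y, p))
    pred = model.predict(X)
    if metric == "rmse":
        return float(np.sqrt(np.mean((y - pred) ** 2)))
    if metric == "r2":
        sse = float(((y - pred) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        return 1.0 - sse / sst
    raise ValueError(f"unknown metric {metric!r}")


def permutation_importance(
    model,
    matrix: pd.DataFrame,
    target,
    metric: str,
    n_repeats: int = 10,
    seed=None,
) -> ImportanceTable:
    """Mean change in a model score when one column is shuffled.

    Positive importance always means the feature helps: for loss metrics
    (rmse) it is mean(shuffled - base), for gain metrics (r2, auc,
    accuracy) mean(base - shuffled).  Ranking ties are broken by feature
    name.
    """
    if metric in _LOSS_METRICS:
        sign = 1.0
    elif metric in _GAIN_METRICS:
        sign = -1.0
    else:
        raise ValueError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(seed)
    X = matrix.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    base = _score(model, X, y, metric)
    rows = []
    for col_i, name in enumerate(matrix.columns):
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, col_i] = rng.permutation(Xp[:, col_i])
            deltas.append(sign * (_score(model, Xp, y, metric) - base))
        rows.append((name, float(np.mean(deltas))))
    table = pd.DataFrame(rows, columns=["feature", "importance"])
    table = table.sort_values(
        ["importance", "feature"], ascending=[False, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ImportanceTable(table, metric, n_repeats, seed)
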