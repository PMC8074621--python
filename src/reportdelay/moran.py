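"""Global and local Moran's I with permutation pseudo p-values.

Both statistics use binary, non-row-standardised weights, matching their
classical double-sum definitions:

    I_global = m / S0 * (sum_{j,l} w_{jl} z_j z_l) / (sum_j z_j^2)
    I_j      = (m-1) * z_j / (sum_{l != j} z_l^2) * sum_l w_{jl} z_l

with z the mean-centred attribute and S0 the sum of all weights.  Inference
is by random relabelling of the attribute over units: the global test
shuffles all values, the local test holds unit j fixed and shuffles the
remaining values over the remaining positions (conditional permutation).
Pseudo p-values use the add-one convention and are upper-tailed (positive
autocorrelation) by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .weights import SpatialWeights


@dataclass
class MoranResult:
    statistic: float | np.ndarray
    pseudo_p: float | np.ndarray
    n_permutations: int
    seed: int | None
    expectation: float  # analytical null mean -1/(m-1)
    permuted: np.ndarray | None = None


def _as_matrix(weights) -> sp.csr_matrix:
    if isinstance(weights, SpatialWeights):
        return weights.matrix
    return sp.csr_matrix(weights)


def _check(values: np.ndarray, w: sp.csr_matrix) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) != w.shape[0]:
        raise ValueError("values length must match the weights matrix")
    if np.ptp(values) == 0:
        raise ValueError("zero variance: Moran's I undefined for constant values")
    if w.nnz == 0:
        raise ValueError("all-zero weights matrix")
    return values


def global_moran(
    values,
    weights,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
    row_standardize: bool = False,
) -> MoranResult:
    """Global Moran's I with a permutation pseudo p-value.

    ``alternative``: 'greater' (clustering, default), 'less' (dispersion) or
    'two-sided' (distance from the null mean -1/(m-1)).
    """
    w = _as_matrix(weights)
    values = _check(values, w)
    if row_standardize:
        inv = 1.0 / np.maximum(np.asarray(w.sum(axis=1)).ravel(), 1)
        w = sp.diags(inv) @ w
    m = len(values)
    z = values - values.mean()
    s0 = w.sum()
    scale = m / (s0 * (z @ z))

    def stat(zv):
        return scale * (zv @ (w @ zv))

    obs = float(stat(z))
    e_i = -1.0 / (m - 1)
    perm = None
    p = np.nan
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        perm = np.empty(n_perm)
        zp = z.copy()
        for b in range(n_perm):
            rng.shuffle(zp)
            perm[b] = stat(zp)
        if alternative == "greater":
            extreme = perm >= obs
        elif alternative == "less":
            extreme = perm <= obs
        elif alternative == "two-sided":
            extreme = np.abs(perm - e_i) >= abs(obs - e_i)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        p = (1 + int(extreme.sum())) / (1 + n_perm)
    return MoranResult(obs, p, n_perm or 0, seed, e_i, perm)


def local_moran(
    values,
    weights,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MoranResult:
    """Local Moran's I per unit with conditional-permutation pseudo p-values.

    A unit with no neighbours has an empty spatial lag and I_j = 0.
    """
    w = _as_matrix(weights).tocsr()
    values = _check(values, w)
    m = len(values)
    z = values - values.mean()
    ss = z @ z
    denom = ss - z**2  # sum_{l != j} z_l^2  (diagonal weights are zero)
    lag = w @ z
    with np.errstate(divide="ignore", invalid="ignore"):
        obs = np.where(denom > 0, (m - 1) * z / denom * lag, 0.0)
    k_j = np.diff(w.indptr)  # neighbour counts
    obs = np.where(k_j == 0, 0.0, obs)

    p = np.full(m, np.nan)
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        for j in range(m):
            k = k_j[j]
            if k == 0:
                p[j] = 1.0
                continue
            others = np.delete(z, j)
            # first k entries of a permutation of the others = random
            # neighbour draw without replacement, B times
            picks = np.argpartition(
                rng.random((n_perm, m - 1)), k - 1, axis=1
            )[:, :k]
            lag_perm = others[picks].sum(axis=1)
            stat_perm = (m - 1) * z[j] / denom[j] * lag_perm
            if alternative == "greater":
                extreme = stat_perm >= obs[j]
            elif alternative == "less":
                extreme = stat_perm <= obs[j]
            elif alternative == "two-sided":
                extreme = np.abs(stat_perm) >= abs(obs[j])
            else:
                raise ValueError(f"unknown alternative {alternative!r}")
            p[j] = (1 + int(extreme.sum())) / (1 + n_perm)
    return MoranResult(obs, p, n_perm or 0, seed, -1.0 / (m - 1))
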