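"""Permutation tests for spatial disparity in district median delays.

The null hypothesis is spatial randomness: each incident is equally likely
to fall in any district, with district case counts held fixed at their
observed values.  Under the null this is equivalent to shuffling the delay
values over the fixed district slots.  Three views of disparity are
provided:

* a ranked-median envelope — per rank, the permutation mean and 95%
  percentile interval of sorted district medians, with observed ranked
  medians flagged when they fall outside their rank's interval;
* a one-sided Gini-coefficient test on district medians;
* a one-sided inter-decile-range (90th - 10th percentile) test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class EnvelopeResult:
    observed_ranked: np.ndarray
    null_mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    outside: np.ndarray
    n_permutations: int
    seed: int | None


@dataclass
class DisparityResult:
    statistic_name: str
    observed: float
    p_value: float
    permuted: np.ndarray
    n_permutations: int
    seed: int | None


def _group_layout(district_ids):
    """Stable layout of district slots: events sorted by district, with
    per-district offsets, used to evaluate medians on shuffled delays."""
    labels = np.asarray(district_ids)
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    uniq, counts = np.unique(sorted_labels, return_counts=True)
    if len(uniq) < 2:
        logger.warning("permutation over a single district is the identity")
    return order, uniq, counts


def permute_assignments(district_ids, seed=None, rng=None):
    """A uniformly random district relabelling preserving each district's
    event count exactly (returned aligned with the input order)."""
    labels = np.asarray(district_ids)
    rng = np.random.default_rng(seed) if rng is None else rng
    return rng.permutation(labels)


def _grouped_median_matrix(delay_matrix: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Row-wise district medians.

    ``delay_matrix`` is (B, n) with columns laid out district-by-district in
    ``counts`` order; returns (B, n_districts).  Vectorised by padding each
    district block to the maximum count with +inf, sorting, and averaging
    the two middle order statistics of the true block size.
    """
    b, n = delay_matrix.shape
    g = len(counts)
    size = int(counts.max())
    padded = np.full((b, g, size), np.inf)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    col_idx = np.concatenate([np.arange(c) for c in counts])
    grp_idx = np.repeat(np.arange(g), counts)
    padded[:, grp_idx, col_idx] = delay_matrix
    padded.sort(axis=2)
    lo = (counts - 1) // 2
    hi = counts // 2
    rows = np.arange(g)
    return 0.5 * (padded[:, rows, lo] + padded[:, rows, hi])


def district_medians(delays, district_ids) -> pd.Series:
    s = pd.Series(np.asarray(delays, dtype=float))
    return s.groupby(pd.Series(np.asarray(district_ids))).median()


def _permuted_medians(delays, district_ids, n_perm, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    delays = np.asarray(delays, dtype=float)
    order, uniq, counts = _group_layout(district_ids)
    base = delays[order]
    mats = np.empty((n_perm, len(delays)))
    for bidx in range(n_perm):
        mats[bidx] = rng.permutation(delays)
    perm_medians = _grouped_median_matrix(mats, counts)
    obs_medians = _grouped_median_matrix(base[None, :], counts)[0]
    return obs_medians, perm_medians, uniq


def ranked_median_envelope(
    delays, district_ids, n_perm: int = 1000, seed=None
) -> EnvelopeResult:
    """Permutation envelope of ranked district median delays.

    For each of ``n_perm`` random reassignments the district medians are
    computed and sorted; per rank the mean and the 2.5th/97.5th percentiles
    summarise the null.  Observed ranked medians outside their rank's
    interval are flagged.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d < 100: envelope percentiles are unstable", n_perm)
    rng = np.random.default_rng(seed)
    obs, perm, _ = _permuted_medians(delays, district_ids, n_perm, rng)
    obs_ranked = np.sort(obs)
    perm.sort(axis=1)
    lo, hi = np.percentile(perm, [2.5, 97.5], axis=0)
    mean = perm.mean(axis=0)
    outside = (obs_ranked < lo) | (obs_ranked > hi)
    return EnvelopeResult(obs_ranked, mean, lo, hi, outside, n_perm, seed)


def gini(values) -> float:
    """Population Gini coefficient G = sum_{a,b} |v_a - v_b| / (2 n^2 vbar).

    Requires nonnegative, not-all-zero values; 0 means perfect equality.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if np.any(v < 0):
        raise ValueError("Gini requires nonnegative values")
    total = v.sum()
    if total == 0:
        raise ValueError("Gini undefined for an all-zero vector")
    n = len(v)
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * v).sum() / (n * total))


def _gini_or_zero(v: np.ndarray) -> float:
    return 0.0 if v.sum() == 0 else gini(v)


def interdecile_range(values) -> float:
    """90th minus 10th percentile (linear-interpolation quantile rule)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 10:
        raise ValueError("inter-decile range needs at least 10 values")
    q10, q90 = np.percentile(v, [10, 90])
    return float(q90 - q10)


def disparity_test(
    delays, district_ids, statistic: str = "gini", n_perm: int = 999, seed=None
) -> DisparityResult:
    """One-sided (greater-disparity) permutation test on district medians.

    p = (1 + #{permuted statistic >= observed}) / (1 + n_perm).  Districts
    with zero events cannot occur by construction (counts are held fixed).
    """
    rng = np.random.default_rng(seed)
    obs_med, perm_med, _ = _permuted_medians(delays, district_ids, n_perm, rng)
    if statistic == "gini":
        fn = _gini_or_zero
        obs = gini(obs_med)
    elif statistic == "idr":
        fn = interdecile_range
        obs = interdecile_range(obs_med)
    else:
        raise ValueError(f"unknown disparity statistic {statistic!r}")
    perm_stats = np.array([fn(row) for row in perm_med])
    p = (1 + int((perm_stats >= obs).sum())) / (1 + n_perm)
    return DisparityResult(statistic, float(obs), p, perm_stats, n_perm, seed)
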