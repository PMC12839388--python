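"""Group comparisons with star annotations (* p<0.05, ** p<0.01, **** p<0.001).

Default method is a two-sided rank-sum test; for small samples
(n <= 10 per group) the p-value is computed exactly by full enumeration
of the group assignments, otherwise by the normal approximation with tie
correction.  Strict inequality at every threshold, so a boundary p maps
to the weaker category.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import mannwhitneyu, rankdata


@dataclass
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    annotation: str
    method: str


def annotate(p_value: float) -> str:
    """Star annotation; thresholds are strict (p exactly at a threshold is weaker)."""
    if p_value < 0.001:
        return "****"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "n.s."


def _exact_ranksum_p(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by full enumeration (midranks for ties)."""
    pooled = np.concatenate([values_a, values_b])
    ranks = rankdata(pooled)
    n_a, n = len(values_a), len(pooled)
    w_obs = float(ranks[:n_a].sum())
    mu = ranks.sum() * n_a / n
    dev_obs = abs(w_obs - mu)
    hits = 0
    for combo in combinations(range(n), n_a):
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= dev_obs - 1e-9:
            hits += 1
    return w_obs, hits / comb(n, n_a)


def compare_groups(
    values_a,
    values_b,
    method: str = "ranksum",
    label_a: str = "A",
    label_b: str = "B",
    exact_max_n: int = 10,
) -> GroupComparison:
    """Compare two groups of per-nucleus summary values.

    ``method='ranksum'`` (the default and only method) uses the exact
    permutation branch when both groups have at most ``exact_max_n``
    values.  Requires >= 3 values per group.
    """
    if method != "ranksum":
        raise ValueError(f"unknown method {method!r}")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per group")
    if len(a) <= exact_max_n and len(b) <= exact_max_n:
        stat, p = _exact_ranksum_p(a, b)
        used = "ranksum-exact"
    else:
        res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
        used = "ranksum-asymptotic"
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=len(a),
        n_b=len(b),
        statistic=stat,
        p_value=min(p, 1.0),
        annotation=annotate(min(p, 1.0)),
        method=used,
    )
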