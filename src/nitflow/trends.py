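"""Monotonic-trend inference: Mann-Kendall test and Sen's slope.

Applied per successional stage (and to the whole series) to the
N2/npNO3- performance index to ask whether the reactor was improving,
degrading, or stable within each stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TrendResult", "mann_kendall", "sens_slope"]

#: below this n the normal approximation for S is poor; an exact
#: permutation p-value is used instead
EXACT_P_MAX_N = 10


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall statistics for one series."""

    n: int
    s: int
    var_s: float
    z: float
    p_value: float
    sen_slope: float


def _mk_s(values: np.ndarray) -> int:
    diff = np.sign(values[None, :] - values[:, None])
    return int(np.triu(diff, k=1).sum())


def _tie_var(values: np.ndarray) -> float:
    n = values.size
    var = n * (n - 1) * (2 * n + 5)
    _, counts = np.unique(values, return_counts=True)
    for t in counts[counts > 1]:
        var -= t * (t - 1) * (2 * t + 5)
    return var / 18.0


def _exact_p(days: np.ndarray, values: np.ndarray) -> float | None:
    """Exact two-sided p for S with untied small samples.

    S is the numerator of Kendall's tau between day and value, so the
    exact null distribution of tau gives the exact p for S.  Returns None
    (caller falls back to the normal approximation) when ties make the
    exact distribution unavailable.
    """
    if np.unique(values).size < values.size or np.unique(days).size < days.size:
        return None
    res = stats.kendalltau(days, values, method="exact")
    return float(res.pvalue)


def mann_kendall(series) -> TrendResult:
    """Mann-Kendall trend test with tie-corrected variance.

    ``series`` is a sequence of (day, value); missing values are dropped.
    S = sum_{i<j} sign(x_j - x_i) with pairs ordered by day; Var(S)
    carries the tie correction; Z applies a continuity correction toward
    zero.  The two-sided p-value uses the normal approximation, except
    for n <= 10 where value orderings are enumerated exactly.  Sen's
    slope (median pairwise slope) is attached.
    """
    arr = np.asarray([(d, v) for d, v in series], dtype=float)
    if arr.size:
        arr = arr[np.isfinite(arr[:, 1])]
    n = arr.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 non-missing points, got {n}")
    order = np.argsort(arr[:, 0], kind="stable")
    days = arr[order, 0]
    values = arr[order, 1]
    s = _mk_s(values)
    var_s = _tie_var(values)
    if var_s <= 0:  # all values tied
        z, p = 0.0, 1.0
    else:
        if s > 0:
            z = (s - 1) / np.sqrt(var_s)
        elif s < 0:
            z = (s + 1) / np.sqrt(var_s)
        else:
            z = 0.0
        p = None
        if n <= EXACT_P_MAX_N:
            p = _exact_p(days, values)
        if p is None:
            p = 2.0 * stats.norm.sf(abs(z))
        p = min(max(p, np.finfo(float).tiny), 1.0)
    slope = sens_slope(list(zip(days, values)))
    return TrendResult(n=n, s=s, var_s=float(var_s), z=float(z),
                       p_value=float(p), sen_slope=float(slope))


def sens_slope(series) -> float:
    """Sen's slope: median of (x_j - x_i)/(d_j - d_i) over all pairs
    with distinct days, in series units per day."""
    arr = np.asarray([(d, v) for d, v in series], dtype=float)
    if arr.size:
        arr = arr[np.isfinite(arr[:, 1])]
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 non-missing points")
    days = arr[:, 0]
    if np.unique(days).size < 2:
        raise ValueError("no pair with distinct days")
    # Theil-Sen estimator == median pairwise slope over distinct-day pairs
    slope, _, _, _ = stats.theilslopes(arr[:, 1], days)
    return float(slope)
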