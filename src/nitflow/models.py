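"""Standardized regression of system performance on predictor groups.

Quantifies how much variance in the N2/npNO3- performance index is
explained by operational physicochemistry (ENV: temperature, pH, DO),
alpha diversity (DIV: richness, Shannon, Pielou), and community
composition (COM: NMDS axes, or genus relative abundances), using
exhaustive best-subset selection under AIC.  Also provides distance-based
redundancy analysis (db-RDA) of the community dissimilarity matrix on
the ENV variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelResult",
    "DbRdaResult",
    "standardize",
    "fit_standardized_ols",
    "best_subset_aic",
    "dbrda_variance",
    "PREDICTOR_GROUPS",
]

#: Fixed predictor-group definitions for the performance models
PREDICTOR_GROUPS = {
    "ENV": ("temperature", "ph", "do"),
    "DIV": ("richness", "shannon", "pielou"),
    "COM": ("NMDS1", "NMDS2", "NMDS3"),
}


@dataclass
class ModelResult:
    """A fitted standardized OLS model.

    AIC uses the fixed Gaussian form n*ln(RSS/n) + 2(p+2), counting the
    intercept and the error variance as parameters; only within-run
    comparisons are meaningful.
    """

    predictor_names: list[str]
    standardized_coefficients: np.ndarray
    adjusted_r2: float
    aic: float
    p_values: np.ndarray
    overall_p: float
    r2: float
    groups: list[str] = field(default_factory=list)


@dataclass
class DbRdaResult:
    """Constrained variance fraction of a db-RDA and its axis scores."""

    constrained_fraction: float
    axis_scores: np.ndarray
    env_names: list[str]
    permutation_p: float | None = None


def standardize(variables: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Z-score every column to mean 0, (sample) variance 1.

    Raises on zero-variance columns, naming the offender.
    """
    is_df = isinstance(variables, pd.DataFrame)
    arr = variables.to_numpy(dtype=float) if is_df else \
        np.asarray(variables, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    sd = arr.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        names = ([str(variables.columns[b]) for b in bad] if is_df
                 else [f"column {b}" for b in bad])
        raise ValueError(f"zero-variance column(s): {', '.join(names)}")
    out = (arr - arr.mean(axis=0)) / sd
    if is_df:
        return pd.DataFrame(out, index=variables.index,
                            columns=variables.columns)
    return out


def _aic(n: int, rss: float, p: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * (p + 2)


def fit_standardized_ols(
    response: np.ndarray,
    predictors: pd.DataFrame | np.ndarray,
    names: list[str] | None = None,
) -> ModelResult:
    """OLS with intercept on standardized variables.

    Reports standardized coefficients, adjusted R^2, the package's fixed
    AIC, two-sided coefficient t-test p-values and the model F-test p.
    """
    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns)
        x = predictors.to_numpy(dtype=float)
    else:
        x = np.asarray(predictors, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = names or [f"x{i + 1}" for i in range(x.shape[1])]
    y = np.asarray(response, dtype=float)
    n, p = x.shape
    if n < p + 2:
        raise ValueError(f"need n >= p + 2 rows (n={n}, p={p})")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), x])) < p + 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(x, rowvar=False)
        pairs = [f"{names[i]}~{names[j]}"
                 for i in range(p) for j in range(i + 1, p)
                 if abs(corr[i, j]) > 1 - 1e-10]
        raise ValueError(
            "rank-deficient design; collinear predictors: "
            + (", ".join(pairs) if pairs else "(involving the intercept)"))
    fit = sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()
    rss = float(fit.ssr)
    r2 = float(fit.rsquared)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return ModelResult(
        predictor_names=names,
        standardized_coefficients=np.asarray(fit.params[1:], dtype=float),
        adjusted_r2=float(adj),
        aic=float(_aic(n, rss, p)),
        p_values=np.asarray(fit.pvalues[1:], dtype=float),
        overall_p=float(fit.f_pvalue) if p > 0 else 1.0,
        r2=r2,
    )


def best_subset_aic(
    response: np.ndarray,
    predictor_pool: pd.DataFrame,
    groups: dict[str, tuple[str, ...]] | None = None,
) -> ModelResult:
    """Exhaustive best-subset selection under the package AIC.

    Enumerates every non-empty subset of the pool (capped at 15
    predictors), fits each by least squares, and returns the minimum-AIC
    model refit with full statistics.  Ties break toward the subset whose
    predictors appear first in the pool.  ``groups`` (name -> member
    columns) annotates the winner with the groups it draws from.
    """
    if predictor_pool.shape[1] == 0:
        raise ValueError("empty predictor pool")
    if predictor_pool.shape[1] > 15:
        raise ValueError("pool too large for exhaustive enumeration (>15)")
    y = np.asarray(response, dtype=float)
    x = predictor_pool.to_numpy(dtype=float)
    n, p_all = x.shape
    ones = np.ones((n, 1))
    best: tuple[float, tuple[int, ...]] | None = None
    for size in range(1, p_all + 1):
        for subset in combinations(range(p_all), size):
            design = np.column_stack([ones, x[:, subset]])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                continue
            coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ coef
            aic = _aic(n, float(resid @ resid), size)
            if best is None or aic < best[0] - 1e-12:
                best = (aic, subset)
    if best is None:
        raise ValueError("no full-rank subset found")
    subset = best[1]
    result = fit_standardized_ols(y, predictor_pool.iloc[:, list(subset)])
    if groups:
        chosen = set(result.predictor_names)
        result.groups = [g for g, members in groups.items()
                         if chosen & set(members)]
    return result


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d ** 2) @ j


def dbrda_variance(
    dist,
    env: pd.DataFrame | np.ndarray,
    permutations: int = 0,
    seed: int = 0,
) -> DbRdaResult:
    """Distance-based redundancy analysis.

    Gower-centers the dissimilarity matrix, keeps the principal
    coordinates with non-negative eigenvalues, and projects them onto the
    column space of the (centered) environmental variables.  The
    constrained fraction is constrained inertia over total non-negative
    inertia.  With ``permutations`` > 0, a permutation p-value for the
    constrained fraction (rows of env shuffled) is attached.
    """
    from .community import _as_square

    d = _as_square(dist)
    n = d.shape[0]
    if isinstance(env, pd.DataFrame):
        env_names = list(env.columns)
        e = env.to_numpy(dtype=float)
    else:
        e = np.asarray(env, dtype=float)
        if e.ndim == 1:
            e = e[:, None]
        env_names = [f"env{i + 1}" for i in range(e.shape[1])]
    if e.shape[0] != n:
        raise ValueError("env rows must match the dissimilarity matrix")
    ec = e - e.mean(axis=0)
    if np.linalg.matrix_rank(ec) < ec.shape[1]:
        raise ValueError("collinear environmental variables")

    g = _gower_center(d)
    eigval, eigvec = np.linalg.eigh(g)
    keep = eigval > 1e-10
    lam = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(lam)
    total_inertia = float(lam.sum())

    q, _ = np.linalg.qr(ec)

    def constrained(coords_: np.ndarray, q_: np.ndarray) -> float:
        proj = q_.T @ coords_
        return float((proj ** 2).sum())

    frac = constrained(coords, q) / total_inertia
    perm_p = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            idx = rng.permutation(n)
            qp, _ = np.linalg.qr(ec[idx])
            if constrained(coords, qp) / total_inertia >= frac - 1e-12:
                count += 1
        perm_p = (count + 1) / (permutations + 1)
    # axis scores: fitted community coordinates in the env-constrained space
    fitted = q @ (q.T @ coords)
    return DbRdaResult(constrained_fraction=frac, axis_scores=fitted,
                       env_names=env_names, permutation_p=perm_p)
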