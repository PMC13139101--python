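"""Scale-free performance metrics and study-level summaries.

The indices live on different scales (d is unbounded, the rest sit in [0, 1]),
so estimator quality is compared with scale-free metrics:

* RMB   — relative mean bias, mean((theta_hat - theta) / theta); when theta is
          exactly 0 a small epsilon = 1e-6 replaces it, which makes the value
          explosive by construction — the companion ``raw_bias`` column reports
          mean(theta_hat) - theta so those cells stay interpretable.
* NRMSE — RMSE divided by the empirical range of the estimates.
* coverage — fraction of replicates whose CI contains theta (closed endpoints).
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UndefinedStatisticError

__all__ = ["rmb", "nrmse", "coverage", "correlation_matrix", "summarize", "INDEX_COLUMNS"]

EPSILON_THETA = 1e-6

# index -> (estimate column, CI low, CI high, estimand column)
INDEX_COLUMNS = {
    "d": ("d", "d_lo", "d_hi", "theta_d"),
    "cles": ("cles", "cles_lo", "cles_hi", "theta_cles"),
    "eta_p": ("eta_p", "etap_lo", "etap_hi", "theta_overlap"),
    "eta": ("eta", "eta_lo", "eta_hi", "theta_overlap"),
}

_CONDITION_KEYS = ["delta", "sigma", "alpha", "n"]


def _as_array(estimates) -> np.ndarray:
    x = np.asarray(estimates, dtype=float).ravel()
    if x.size == 0:
        raise InvalidArgumentError("estimates must be nonempty")
    return x


def rmb(estimates, theta: float) -> float:
    """Relative mean bias with the epsilon substitution at theta = 0."""
    x = _as_array(estimates)
    if not math.isfinite(theta):
        raise InvalidArgumentError(f"theta must be finite, got {theta}")
    denom = theta if theta != 0.0 else EPSILON_THETA
    return float(np.mean((x - theta) / denom))


def nrmse(estimates, theta: float) -> float:
    """RMSE over the empirical range; 0 for a perfect constant estimator,
    NaN when the range is zero but the error is not."""
    x = _as_array(estimates)
    rmse = float(np.sqrt(np.mean((x - theta) ** 2)))
    rng = float(x.max() - x.min())
    if rng == 0.0:
        return 0.0 if rmse == 0.0 else math.nan
    return rmse / rng


def coverage(intervals: Iterable, theta: float) -> float:
    """Fraction of intervals with lower <= theta <= upper (closed endpoints)."""
    pairs = [(iv[0], iv[1]) for iv in intervals]
    if not pairs:
        raise InvalidArgumentError("intervals must be nonempty")
    hits = sum(1 for lo, hi in pairs if lo <= theta <= hi)
    return hits / len(pairs)


def correlation_matrix(table: pd.DataFrame, absolute: bool = False) -> pd.DataFrame:
    """Pairwise Pearson correlations of the four indices over pooled replicates.

    ``absolute=True`` correlates magnitudes (|d| etc.), which removes the sign
    flip from d's group-1-minus-group-2 convention: d is negative whenever
    group 2's mean is higher while its folded transforms are not.
    """
    cols = ["d", "cles", "eta_p", "eta"]
    X = table[cols]
    if len(X) < 3:
        raise InvalidArgumentError("need at least 3 pooled rows")
    if absolute:
        X = X.abs()
    constant = [c for c in cols if X[c].nunique() <= 1]
    if constant:
        raise UndefinedStatisticError(f"zero-variance column(s): {constant}")
    return X.corr(method="pearson")


def summarize(table: pd.DataFrame, truths: dict | None = None) -> pd.DataFrame:
    """Per-condition, per-index summary: theta, RMB, raw bias, NRMSE, coverage.

    Estimands are read from the table's theta_* columns (as written by
    ``engine.run_grid``) unless ``truths`` maps (delta, sigma, alpha, n) — or
    (delta, sigma, alpha) — to a ``TrueValues``-like object, in which case
    those override. Coverage is NaN where the interval columns are all NaN
    (intervals disabled).
    """
    rows = []
    for cond_key, g in table.groupby(_CONDITION_KEYS, sort=True):
        tv = None
        if truths is not None:
            tv = truths.get(cond_key, truths.get(cond_key[:3]))
        for index, (est_col, lo_col, hi_col, theta_col) in INDEX_COLUMNS.items():
            if tv is not None:
                theta = getattr(tv, theta_col)
            else:
                theta = float(g[theta_col].iloc[0])
            est = g[est_col].to_numpy()
            lo = g[lo_col].to_numpy()
            hi = g[hi_col].to_numpy()
            if np.all(np.isnan(lo)):
                cov = math.nan
            else:
                cov = coverage(zip(lo, hi), theta)
            rows.append(
                {
                    **dict(zip(_CONDITION_KEYS, cond_key)),
                    "index": index,
                    "theta": theta,
                    "rmb": rmb(est, theta),
                    "raw_bias": float(est.mean() - theta),
                    "nrmse": nrmse(est, theta),
                    "coverage": cov,
                    "n_redraws": int(g["n_redraws"].iloc[0]) if "n_redraws" in g else 0,
                }
            )
    return pd.DataFrame(rows)
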