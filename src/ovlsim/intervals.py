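"""95% confidence intervals for the four indices.

Cohen's d gets the noncentrality-parameter interval: the two-sample t statistic
t = d_hat * sqrt(n1*n2/(n1+n2)) follows a noncentral t with df = n1+n2-2 and
noncentrality ncp = d * sqrt(n1*n2/(n1+n2)), so the bounds are the ncp values
whose noncentral-t tail probabilities at the observed t equal (1-level)/2, each
scaled back to the d scale. CLES and the parametric overlap, being deterministic
transforms of d, inherit their intervals by mapping the d bounds through the
respective transform. The nonparametric overlap gets a percentile bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import optimize, stats

from .effect_sizes import KdeConfig, cles_from_d, cohen_d, overlap_nonparametric, overlap_parametric
from .errors import (
    DegenerateSampleError,
    InvalidArgumentError,
    InvalidParameterError,
    NumericalError,
)

__all__ = [
    "Interval",
    "BootConfig",
    "ci_d_noncentral",
    "ci_transform_monotone",
    "ci_eta_bootstrap",
]


class Interval(NamedTuple):
    """A two-sided confidence interval with nominal level (e.g. 0.95)."""

    lower: float
    upper: float
    level: float


@dataclass(frozen=True)
class BootConfig:
    """Percentile-bootstrap settings: resample count and seed."""

    n_boot: int = 1000
    seed: object = None

    def __post_init__(self) -> None:
        if self.n_boot < 100:
            raise InvalidParameterError("n_boot must be >= 100")


def _invert_nct(t_obs: float, df: int, q: float) -> float:
    """Find ncp with nct.cdf(t_obs; df, ncp) == q.

    The cdf is strictly decreasing in ncp. Brackets expand geometrically from
    t_obs, seeded at the normal-approximation half-width, which keeps the
    search robust out to very large |t_obs|.
    """

    def f(ncp: float) -> float:
        return stats.nct.cdf(t_obs, df, ncp) - q

    # normal-approx SD of the ncp estimate; generous floor for tiny t
    w = max(2.0, 4.0 * math.sqrt(1.0 + t_obs * t_obs / (2.0 * df)))
    if q < 0.5:
        lo, hi = t_obs, t_obs + w  # need cdf small -> ncp above t_obs
        for _ in range(200):
            if f(hi) < 0:
                break
            hi += w
            w *= 2.0
        else:
            raise NumericalError(f"bracket expansion failed (t={t_obs}, df={df}, q={q})")
    else:
        lo, hi = t_obs - w, t_obs
        for _ in range(200):
            if f(lo) > 0:
                break
            lo -= w
            w *= 2.0
        else:
            raise NumericalError(f"bracket expansion failed (t={t_obs}, df={df}, q={q})")
    try:
        return optimize.brentq(f, lo, hi, xtol=1e-10)
    except Exception as exc:  # pragma: no cover - brentq rarely fails on a bracket
        raise NumericalError(f"noncentral-t inversion failed: {exc}") from exc


def ci_d_noncentral(y1, y2, level: float = 0.95) -> Interval:
    """Noncentrality-parameter-method CI for Cohen's d."""
    if not 0.0 < level < 1.0:
        raise InvalidParameterError(f"level must be in (0,1), got {level}")
    y1 = np.asarray(y1, dtype=float).ravel()
    y2 = np.asarray(y2, dtype=float).ravel()
    d = cohen_d(y1, y2)
    n1, n2 = y1.size, y2.size
    df = n1 + n2 - 2
    scale = math.sqrt((n1 + n2) / (n1 * n2))
    t_obs = d / scale
    a = (1.0 - level) / 2.0
    ncp_hi = _invert_nct(t_obs, df, a)        # cdf(t_obs) = a  -> upper bound
    ncp_lo = _invert_nct(t_obs, df, 1.0 - a)  # cdf(t_obs) = 1-a -> lower bound
    return Interval(ncp_lo * scale, ncp_hi * scale, level)


_TRANSFORMS = {"cles": cles_from_d, "eta_p": overlap_parametric}


def ci_transform_monotone(ci_d: Interval, transform: str) -> Interval:
    """Map a d-interval through the CLES or eta_p transform, endpoint-wise.

    The transform is evaluated at both d endpoints and the two values returned
    in sorted order. Both transforms fold at |d|, so when the d-interval
    straddles zero this literal endpoint rule cannot reach the transform's
    value at d = 0; that behaviour is intentional (see the methods note) and
    the engine exposes a ``widen_null`` switch for the corrected variant.
    """
    try:
        f = _TRANSFORMS[transform]
    except KeyError:
        raise InvalidParameterError(f"unknown transform: {transform!r}") from None
    a, b = f(ci_d.lower), f(ci_d.upper)
    return Interval(min(a, b), max(a, b), ci_d.level)


def ci_eta_bootstrap(
    y1,
    y2,
    cfg: BootConfig | None = None,
    kde: KdeConfig | None = None,
    level: float = 0.95,
) -> Interval:
    """Percentile-bootstrap CI for the nonparametric overlap.

    Each group is resampled with replacement independently, the overlap index
    recomputed, and the (1-level)/2 and 1-(1-level)/2 empirical percentiles
    (linear interpolation) returned. A degenerate resample (zero spread) is
    redrawn, up to 100 times per replicate.
    """
    if not 0.0 < level < 1.0:
        raise InvalidParameterError(f"level must be in (0,1), got {level}")
    cfg = cfg or BootConfig()
    y1 = np.asarray(y1, dtype=float).ravel()
    y2 = np.asarray(y2, dtype=float).ravel()
    if y1.size < 2 or y2.size < 2:
        raise InvalidArgumentError("both groups need at least 2 observations")
    rng = (
        cfg.seed
        if isinstance(cfg.seed, np.random.Generator)
        else np.random.default_rng(cfg.seed)
    )
    vals = np.empty(cfg.n_boot)
    for b in range(cfg.n_boot):
        for _ in range(100):
            r1 = rng.choice(y1, size=y1.size, replace=True)
            r2 = rng.choice(y2, size=y2.size, replace=True)
            try:
                vals[b] = overlap_nonparametric(r1, r2, kde)
                break
            except DegenerateSampleError:
                continue
        else:
            raise DegenerateSampleError("bootstrap resampling degenerate 100 times in a row")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [a, 1.0 - a])
    return Interval(float(lo), float(hi), level)
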