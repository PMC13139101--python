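"""True parameter values per index and simulation condition.

Each estimator is judged against its own population target theta_j:

* Cohen's d   — the population standardized mean difference under the pooled
                standardizer at equal n: theta_d = -delta / sqrt((1+sigma^2)/2)
                (group 1 minus group 2; group 1 is always standard normal).
* CLES        — the folded probability of superiority max(p, 1-p) with
                p = P(Y2 > Y1), computed by quadrature of Phi(y) f2(y).
* overlap     — the distributional overlap integral of min(f1, f2), shared by
                the parametric and nonparametric overlap estimators. Judging
                eta_p against the true overlap (rather than against a transform
                of theta_d) is what makes it unbiased under equal variances but
                biased under heteroscedasticity, where its normal-theory
                formula no longer describes the actual overlap.

The moment-matching transform guarantees group 2 has mean ``delta`` and SD
``sigma`` exactly for every slant, so theta_d needs no quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize
from scipy.special import ndtr

from .errors import InvalidParameterError, NumericalError
from .skewnormal import SkewNormalSpec, TargetMoments, sn_params_from_moments, sn_pdf

__all__ = ["Condition", "TrueValues", "true_d", "true_cles", "true_overlap", "true_values"]

_PHI_NORM = 1.0 / math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class Condition:
    """One factorial cell: group-2 targets (delta, sigma, alpha) and per-group n.

    Group 1 is fixed at the standard normal by design; ``delta`` is therefore
    both group 2's mean and the true mean difference.
    """

    delta: float
    sigma: float
    alpha: float
    n: int

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.n < 1:
            raise InvalidParameterError(f"n must be >= 1, got {self.n}")

    def group2_spec(self) -> SkewNormalSpec:
        return sn_params_from_moments(TargetMoments(self.delta, self.sigma, self.alpha))


@dataclass(frozen=True)
class TrueValues:
    """Per-index estimands for one condition."""

    theta_d: float
    theta_cles: float
    theta_overlap: float


def _integration_bounds(cond: Condition) -> tuple[float, float]:
    pad = 10.0 * max(1.0, cond.sigma)
    return min(0.0, cond.delta) - pad, max(0.0, cond.delta) + pad


def true_d(cond: Condition) -> float:
    """Population Cohen's d, group 1 minus group 2: -delta / sqrt((1+sigma^2)/2)."""
    return -cond.delta / math.sqrt((1.0 + cond.sigma * cond.sigma) / 2.0)


def true_cles(cond: Condition) -> float:
    """Folded true probability of superiority max(p, 1-p), p = P(Y2 > Y1).

    P(Y2 > Y1) = integral of Phi(y) f2(y) dy with Phi the standard normal CDF
    and f2 the condition's skew-normal density.
    """
    spec2 = cond.group2_spec()
    lo, hi = _integration_bounds(cond)
    p, err = integrate.quad(
        lambda y: ndtr(y) * float(sn_pdf(y, spec2)), lo, hi, epsabs=1e-10, limit=500
    )
    if err > 1e-6:
        raise NumericalError(f"CLES quadrature error {err} too large for {cond}")
    return max(p, 1.0 - p)


def true_overlap(cond: Condition) -> float:
    """Distributional overlap: integral of min(phi(y), f2(y)) dy.

    The integrand has kinks where the densities cross, so the crossings are
    bracketed on a fine scan grid, refined by Brent's method, and the
    quadrature runs piecewise between them (each piece is then smooth).
    """
    spec2 = cond.group2_spec()
    lo, hi = _integration_bounds(cond)

    def integrand(y: float) -> float:
        return min(_PHI_NORM * math.exp(-0.5 * y * y), float(sn_pdf(y, spec2)))

    def density_gap(y: float) -> float:
        return _PHI_NORM * math.exp(-0.5 * y * y) - float(sn_pdf(y, spec2))

    scan = np.linspace(lo, hi, 4001)
    diff = _PHI_NORM * np.exp(-0.5 * scan * scan) - sn_pdf(scan, spec2)
    sign_change = np.nonzero(np.diff(np.signbit(diff)))[0]
    crossings = []
    for i in sign_change:
        try:
            crossings.append(optimize.brentq(density_gap, scan[i], scan[i + 1], xtol=1e-13))
        except ValueError:
            # gap is numerically ~0 across the bracket (e.g. identical
            # densities); an unrefined split point is still a valid split
            crossings.append(float(scan[i]))
    points = [lo, *crossings, hi]
    total = 0.0
    for a, b in zip(points[:-1], points[1:]):
        val, err = integrate.quad(integrand, a, b, epsabs=1e-10, limit=500)
        if err > 1e-6:
            raise NumericalError(f"overlap quadrature error {err} too large for {cond}")
        total += val
    return min(total, 1.0)


def true_values(cond: Condition, theta_cles_rule: str = "true_probability") -> TrueValues:
    """All three estimands for a condition.

    ``theta_cles_rule`` selects the CLES target: the folded true probability of
    superiority (default), or ``"transform_of_theta_d"`` for Phi(|theta_d|/sqrt 2),
    the value the d-transform estimator would converge to under normality.
    """
    th_d = true_d(cond)
    if theta_cles_rule == "true_probability":
        th_cles = true_cles(cond)
    elif theta_cles_rule == "transform_of_theta_d":
        th_cles = float(ndtr(abs(th_d) / math.sqrt(2.0)))
    else:
        raise InvalidParameterError(f"unknown theta_cles_rule: {theta_cles_rule!r}")
    return TrueValues(theta_d=th_d, theta_cles=th_cles, theta_overlap=true_overlap(cond))
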