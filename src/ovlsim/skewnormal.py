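"""Skew-normal distribution: density, moments, moment-matching and sampling.

The skew-normal family SN(xi, omega, alpha) extends the normal with a slant
parameter ``alpha``; ``alpha = 0`` recovers N(xi, omega**2). Its mean and
standard deviation are

    mu    = xi + omega * gamma * sqrt(2/pi)
    sigma = omega * sqrt(1 - 2 * gamma**2 / pi),     gamma = alpha / sqrt(1 + alpha**2)

which can be inverted to pick (xi, omega) hitting a target (mu, sigma) for any
slant. This module is the data generator for the whole simulation pipeline:
every simulated group is a skew-normal sample whose population mean and SD are
set exactly by moment matching, so the mean difference, variance ratio and
skewness of a scenario are controlled independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError, InvalidParameterError

__all__ = [
    "SkewNormalSpec",
    "TargetMoments",
    "sn_pdf",
    "sn_moments",
    "sn_params_from_moments",
    "sn_sample",
]

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class SkewNormalSpec:
    """Generative triple (location ``xi``, scale ``omega``, slant ``alpha``).

    ``gamma = alpha / sqrt(1 + alpha**2)`` is derived once at construction and
    cached, since it appears in every moment formula and in the sampler.
    """

    xi: float
    omega: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise InvalidParameterError(f"omega must be > 0, got {self.omega}")
        gamma = self.alpha / math.sqrt(1.0 + self.alpha * self.alpha)
        object.__setattr__(self, "_gamma", gamma)

    @property
    def gamma(self) -> float:
        return self._gamma  # type: ignore[attr-defined]


@dataclass(frozen=True)
class TargetMoments:
    """Population mean, SD and slant a scenario prescribes for one group."""

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")


def sn_pdf(y, spec: SkewNormalSpec) -> np.ndarray:
    """Skew-normal density evaluated at ``y`` (vectorized)."""
    y = np.asarray(y, dtype=float)
    return stats.skewnorm.pdf(y, spec.alpha, loc=spec.xi, scale=spec.omega)


def sn_moments(spec: SkewNormalSpec) -> tuple[float, float]:
    """Population (mean, sd) of the skew-normal."""
    g = spec.gamma
    mean = spec.xi + spec.omega * g * _SQRT_2_OVER_PI
    sd = spec.omega * math.sqrt(1.0 - 2.0 * g * g / math.pi)
    return mean, sd


def sn_params_from_moments(target: TargetMoments) -> SkewNormalSpec:
    """Invert the moment formulas: find (xi, omega) matching (mu, sigma).

    For any finite slant ``1 - 2*gamma**2/pi > 1 - 2/pi > 0``, so the inversion
    never degenerates.
    """
    g = target.alpha / math.sqrt(1.0 + target.alpha * target.alpha)
    omega = target.sigma / math.sqrt(1.0 - 2.0 * g * g / math.pi)
    xi = target.mu - omega * g * _SQRT_2_OVER_PI
    return SkewNormalSpec(xi=xi, omega=omega, alpha=target.alpha)


def sn_sample(n: int, spec: SkewNormalSpec, seed) -> np.ndarray:
    """Draw ``n`` variates via the stochastic representation.

    Z = gamma*|U| + sqrt(1-gamma^2)*V with U, V iid N(0,1) is exactly
    SN(0, 1, alpha); the draw is rejection-free and O(n). ``seed`` may be an
    int, a ``numpy.random.SeedSequence`` or an existing ``Generator`` (the
    latter is consumed in place, which lets the engine chain draws).
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = spec.gamma
    u = rng.standard_normal(n)
    v = rng.standard_normal(n)
    z = g * np.abs(u) + math.sqrt(1.0 - g * g) * v
    return spec.xi + spec.omega * z
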