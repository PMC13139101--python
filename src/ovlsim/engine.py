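"""Monte-Carlo driver: replicate sample pairs over the factorial grid.

The default grid is the full study design: group 1 always N(0,1); group 2
skew-normal with mean difference delta in {0, 2}, SD sigma in {1, 5}, slant
alpha in {0, 10}, per-group n in {10, 50, 100, 300, 500, 1000} — 8 scenarios,
48 conditions, 2000 replicate pairs per condition.

Seeding: every replicate draws its generator from
``SeedSequence(master_seed, spawn_key=(condition-words, rep, attempt))`` where
the condition words encode the cell's parameter *values*. Records are therefore
bit-reproducible and independent of the order in which conditions are run; the
bootstrap generator is a spawned child of the replicate sequence, so the eta
interval is reproducible in isolation.
"""

from __future__ import annotations

import logging
import math
import struct
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .effect_sizes import (
    KdeConfig,
    cles_empirical,
    cles_from_d,
    cohen_d,
    overlap_nonparametric,
    overlap_parametric,
)
from .errors import DegenerateSampleError, InvalidParameterError, NumericalError
from .estimands import Condition, true_values
from .intervals import BootConfig, Interval, ci_d_noncentral, ci_eta_bootstrap, ci_transform_monotone
from .skewnormal import SkewNormalSpec, sn_sample

__all__ = ["RunConfig", "conditions", "run_condition", "run_grid", "REPLICATE_COLUMNS"]

logger = logging.getLogger(__name__)

REPLICATE_COLUMNS = [
    "delta", "sigma", "alpha", "n", "rep",
    "d", "cles", "eta_p", "eta",
    "d_lo", "d_hi", "cles_lo", "cles_hi",
    "etap_lo", "etap_hi", "eta_lo", "eta_hi",
    "seed",
]


@dataclass(frozen=True)
class RunConfig:
    """Full description of one simulation study.

    ``boot=None`` skips the bootstrap interval for eta (its bounds are NaN);
    ``compute_intervals=False`` skips all interval construction — both exist so
    correlation- or bias-only studies do not pay for inference they never read.
    """

    deltas: tuple = (0.0, 2.0)
    sigmas: tuple = (1.0, 5.0)
    alphas: tuple = (0.0, 10.0)
    ns: tuple = (10, 50, 100, 300, 500, 1000)
    n_reps: int = 2000
    master_seed: int = 1
    ci_level: float = 0.95
    boot: BootConfig | None = field(default_factory=BootConfig)
    kde: KdeConfig = field(default_factory=KdeConfig)
    cles_estimator: str = "from_d"
    theta_cles_rule: str = "true_probability"
    compute_intervals: bool = True
    widen_null: bool = False  # eta_p upper bound -> 1 when 0 is inside ci_d

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise InvalidParameterError("n_reps must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise InvalidParameterError("ci_level must be in (0,1)")
        if self.cles_estimator not in ("from_d", "empirical"):
            raise InvalidParameterError(f"unknown cles_estimator: {self.cles_estimator!r}")
        if self.theta_cles_rule not in ("true_probability", "transform_of_theta_d"):
            raise InvalidParameterError(f"unknown theta_cles_rule: {self.theta_cles_rule!r}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a config from JSON or YAML (YAML is a superset of JSON)."""
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        for key in ("deltas", "sigmas", "alphas", "ns"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if isinstance(kw.get("boot"), dict):
            kw["boot"] = BootConfig(**kw["boot"])
        if isinstance(kw.get("kde"), dict):
            kw["kde"] = KdeConfig(**kw["kde"])
        return cls(**kw)


def conditions(cfg: RunConfig) -> list[Condition]:
    """Enumerate the factorial grid in (delta, sigma, alpha, n) product order."""
    return [
        Condition(delta=d, sigma=s, alpha=a, n=n)
        for d, s, a, n in product(cfg.deltas, cfg.sigmas, cfg.alphas, cfg.ns)
    ]


def n_scenarios(cfg: RunConfig) -> int:
    """Number of distinct (delta, sigma, alpha) population contrasts."""
    return len(set(product(cfg.deltas, cfg.sigmas, cfg.alphas)))


def _condition_key(cond: Condition) -> tuple[int, ...]:
    """Stable uint32 words encoding the condition's parameter values."""
    words = struct.unpack("<6I", struct.pack("<3d", cond.delta, cond.sigma, cond.alpha))
    return (*words, cond.n)


def _replicate_once(cond, cfg, spec1, spec2, rng, boot_ss) -> dict:
    n = cond.n
    y1 = sn_sample(n, spec1, rng)
    y2 = sn_sample(n, spec2, rng)
    d = cohen_d(y1, y2)
    cles = cles_from_d(d) if cfg.cles_estimator == "from_d" else cles_empirical(y1, y2)
    rec = {
        "d": d,
        "cles": cles,
        "eta_p": overlap_parametric(d),
        "eta": overlap_nonparametric(y1, y2, cfg.kde),
    }
    if cfg.compute_intervals:
        ci_d = ci_d_noncentral(y1, y2, cfg.ci_level)
        ci_cles = ci_transform_monotone(ci_d, "cles")
        ci_etap = ci_transform_monotone(ci_d, "eta_p")
        if cfg.widen_null and ci_d.lower < 0.0 < ci_d.upper:
            ci_etap = Interval(ci_etap.lower, 1.0, ci_etap.level)
        if cfg.boot is not None:
            boot = BootConfig(n_boot=cfg.boot.n_boot, seed=np.random.default_rng(boot_ss))
            ci_eta = ci_eta_bootstrap(y1, y2, boot, cfg.kde, cfg.ci_level)
        else:
            ci_eta = Interval(math.nan, math.nan, cfg.ci_level)
    else:
        ci_d = ci_cles = ci_etap = ci_eta = Interval(math.nan, math.nan, cfg.ci_level)
    rec.update(
        d_lo=ci_d.lower, d_hi=ci_d.upper,
        cles_lo=ci_cles.lower, cles_hi=ci_cles.upper,
        etap_lo=ci_etap.lower, etap_hi=ci_etap.upper,
        eta_lo=ci_eta.lower, eta_hi=ci_eta.upper,
    )
    return rec


def run_condition(cond: Condition, cfg: RunConfig) -> pd.DataFrame:
    """All replicates for one condition; returns one row per replicate.

    Degenerate draws (zero pooled SD / zero bandwidth) are redrawn under a
    fresh attempt seed so the replicate count stays exactly ``n_reps``; the
    run aborts if more than 1% of replicates needed a redraw.
    """
    spec1 = SkewNormalSpec(0.0, 1.0, 0.0)
    spec2 = cond.group2_spec()
    key = _condition_key(cond)
    rows: list[dict] = []
    redraws = 0
    for rep in range(cfg.n_reps):
        for attempt in range(101):
            ss = np.random.SeedSequence(cfg.master_seed, spawn_key=(*key, rep, attempt))
            data_ss, boot_ss = ss.spawn(2)
            rng = np.random.default_rng(data_ss)
            try:
                rec = _replicate_once(cond, cfg, spec1, spec2, rng, boot_ss)
                break
            except DegenerateSampleError:
                redraws += 1
                continue
        else:
            raise NumericalError(f"replicate {rep} of {cond} degenerate after 100 redraws")
        rec.update(
            delta=cond.delta, sigma=cond.sigma, alpha=cond.alpha, n=cond.n,
            rep=rep, seed=int(data_ss.generate_state(1)[0]),
        )
        rows.append(rec)
    if redraws > 0.01 * cfg.n_reps:
        raise NumericalError(
            f"{redraws} redraws exceed 1% of {cfg.n_reps} replicates for {cond}"
        )
    df = pd.DataFrame(rows, columns=REPLICATE_COLUMNS)
    df["n_redraws"] = redraws
    return df


def run_grid(cfg: RunConfig | None = None) -> pd.DataFrame:
    """Run every condition in the grid and attach the per-condition estimands.

    Output columns: the replicate columns plus theta_d, theta_cles,
    theta_overlap and n_redraws (constant within a condition).
    """
    cfg = cfg or RunConfig()
    conds = conditions(cfg)
    frames = []
    for i, cond in enumerate(conds, start=1):
        logger.info("condition %d/%d: %s", i, len(conds), cond)
        df = run_condition(cond, cfg)
        tv = true_values(cond, cfg.theta_cles_rule)
        df["theta_d"] = tv.theta_d
        df["theta_cles"] = tv.theta_cles
        df["theta_overlap"] = tv.theta_overlap
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def smoke_config(**overrides) -> RunConfig:
    """A desk-scale config: tiny replicate counts, no bootstrap."""
    base = RunConfig(n_reps=20, ns=(10, 100), boot=None, compute_intervals=True)
    return replace(base, **overrides) if overrides else base
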