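"""Inverse-variance pooling of Fisher-z effects with heterogeneity statistics.

Implements the classical random-effects machinery: fixed-effect
(inverse-variance) pooling, Cochran's Q and I-squared, the
DerSimonian-Laird moment estimator of the between-study variance tau^2
(REML available as an alternative), and random-effects pooling with a Wald
confidence interval built on the z scale and back-transformed to r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from .effects import EffectRecord, inverse_fisher_z

__all__ = [
    "PooledEffect",
    "Heterogeneity",
    "pool_fixed",
    "heterogeneity",
    "pool_random",
    "tau2_dl",
    "tau2_reml",
]

TAU2_ESTIMATORS = ("dl", "reml")


@dataclass(frozen=True)
class PooledEffect:
    """Random-effects pooled correlation with heterogeneity diagnostics.

    Point estimate and CI are reported on the correlation scale
    (back-transformed); ``z_pooled`` and ``se_z`` retain the z-scale
    quantities that downstream stages (MASEM, Monte-Carlo CIs) need.
    """

    k: int
    r_pooled: float
    ci_low: float
    ci_high: float
    z_stat: float
    p: float
    Q: float
    df: int
    I2: float
    tau2: float
    z_pooled: float
    se_z: float
    alpha: float = 0.05
    tau2_estimator: str = "dl"

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "r": self.r_pooled,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "z": self.z_stat,
            "p": self.p,
            "Q": self.Q,
            "df": self.df,
            "p_Q": float(stats.chi2.sf(self.Q, self.df)) if self.df > 0 else float("nan"),
            "I2": self.I2,
            "tau2": self.tau2,
            "z_pooled": self.z_pooled,
            "se_z": self.se_z,
        }


class Heterogeneity(NamedTuple):
    Q: float
    df: int
    I2: float
    tau2: float


def _arrays(effects: Sequence[EffectRecord]):
    if len(effects) == 0:
        raise ValueError("cannot pool an empty collection of effects")
    z = np.array([e.z for e in effects], dtype=float)
    v = np.array([e.v for e in effects], dtype=float)
    return z, v


def pool_fixed(effects: Sequence[EffectRecord]) -> tuple[float, float]:
    """Fixed-effect (inverse-variance) pooled z and its variance."""
    z, v = _arrays(effects)
    w = 1.0 / v
    z_bar = float(np.sum(w * z) / np.sum(w))
    return z_bar, float(1.0 / np.sum(w))


def _q_statistic(z: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    z_bar = np.sum(w * z) / np.sum(w)
    return float(np.sum(w * (z - z_bar) ** 2))


def tau2_dl(effects: Sequence[EffectRecord]) -> float:
    """DerSimonian-Laird moment estimate of the between-study variance."""
    z, v = _arrays(effects)
    if len(z) < 2:
        return 0.0
    w = 1.0 / v
    Q = _q_statistic(z, v)
    df = len(z) - 1
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max(0.0, (Q - df) / c)


def tau2_reml(effects: Sequence[EffectRecord], upper: float = 10.0) -> float:
    """REML estimate of tau^2 by bounded one-dimensional optimisation."""
    z, v = _arrays(effects)
    if len(z) < 2:
        return 0.0

    def nll(t2: float) -> float:
        w = 1.0 / (v + t2)
        mu = np.sum(w * z) / np.sum(w)
        return 0.5 * (
            np.sum(np.log(v + t2)) + math.log(np.sum(w)) + float(np.sum(w * (z - mu) ** 2))
        )

    res = optimize.minimize_scalar(nll, bounds=(0.0, upper), method="bounded",
                                   options={"xatol": 1e-12})
    return max(0.0, float(res.x))


def heterogeneity(effects: Sequence[EffectRecord]) -> Heterogeneity:
    """Cochran's Q, its df, I-squared (percent), and DL tau^2.

    Requires at least two effects; Q is computed with fixed-effect
    weights w = 1/v around the fixed-effect mean.
    """
    z, v = _arrays(effects)
    if len(z) < 2:
        raise ValueError("heterogeneity requires at least two effects")
    Q = _q_statistic(z, v)
    df = len(z) - 1
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return Heterogeneity(Q=Q, df=df, I2=I2, tau2=tau2_dl(effects))


def pool_random(
    effects: Sequence[EffectRecord],
    alpha: float = 0.05,
    tau2_estimator: str = "dl",
) -> PooledEffect:
    """Random-effects pooling on the Fisher-z scale.

    Weights are 1/(v_i + tau^2); the Wald CI is built on the z scale with
    the normal quantile and back-transformed to r.  With a single effect
    the pooled result is that study (tau^2 = 0).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if tau2_estimator not in TAU2_ESTIMATORS:
        raise ValueError(f"unknown tau2 estimator {tau2_estimator!r}")
    z, v = _arrays(effects)
    k = len(z)
    if k >= 2:
        Q = _q_statistic(z, v)
        df = k - 1
        I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
        t2 = tau2_dl(effects) if tau2_estimator == "dl" else tau2_reml(effects)
    else:
        Q, df, I2, t2 = 0.0, 0, 0.0, 0.0

    w = 1.0 / (v + t2)
    z_star = float(np.sum(w * z) / np.sum(w))
    se_star = float(1.0 / math.sqrt(np.sum(w)))
    crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    z_stat = z_star / se_star
    return PooledEffect(
        k=k,
        r_pooled=inverse_fisher_z(z_star),
        ci_low=inverse_fisher_z(z_star - crit * se_star),
        ci_high=inverse_fisher_z(z_star + crit * se_star),
        z_stat=z_stat,
        p=float(2.0 * stats.norm.sf(abs(z_stat))),
        Q=Q,
        df=df,
        I2=I2,
        tau2=t2,
        z_pooled=z_star,
        se_z=se_star,
        alpha=alpha,
        tau2_estimator=tau2_estimator,
    )
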