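"""Publication-bias diagnostics: fail-safe N, funnel data, trim-and-fill.

The fail-safe N follows Rosenthal's file-drawer formulation on Stouffer's
combined z; the funnel export produces plot-ready (effect, se) pairs with
pseudo-confidence guide lines but no plotting dependency; trim-and-fill is
the Duval-Tweedie rank-based correction with the L0 estimator, iterated
with the same random-effects model used for the main pooling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import EffectRecord
from .meta import PooledEffect, pool_random

__all__ = [
    "FailSafeResult",
    "FunnelData",
    "TrimFillResult",
    "fail_safe_n",
    "funnel_data",
    "trim_and_fill",
]


@dataclass(frozen=True)
class FailSafeResult:
    """Rosenthal fail-safe N with its conventional 5k+10 reference bound."""

    n_fs: int
    sum_z: float
    alpha: float
    threshold: int
    k: int

    @property
    def exceeds_threshold(self) -> bool:
        """True when the file-drawer estimate clears the 5k+10 criterion."""
        return self.n_fs > self.threshold


def fail_safe_n(effects: Sequence[EffectRecord], alpha: float = 0.05) -> FailSafeResult:
    """Number of unpublished null studies needed to erase significance.

    Each study contributes the standard-normal deviate u_i = z_i*sqrt(n_i-3)
    (its Fisher-z effect over its standard error).  The combined Stouffer
    statistic stays significant at two-sided ``alpha`` until
    (sum u)^2 / (k + N) drops below the squared normal quantile; the
    smallest integer N achieving that is reported, clipped at zero.
    """
    if len(effects) == 0:
        raise ValueError("fail_safe_n requires at least one effect")
    u = np.array([e.z * math.sqrt(e.n - 3) for e in effects], dtype=float)
    k = len(effects)
    crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    raw = float(np.sum(u)) ** 2 / crit**2 - k
    n_fs = max(0, math.ceil(raw))
    return FailSafeResult(
        n_fs=n_fs, sum_z=float(np.sum(u)), alpha=alpha, threshold=5 * k + 10, k=k
    )


@dataclass(frozen=True)
class FunnelData:
    """Per-study funnel points plus pseudo-CI guide lines, both on the z scale."""

    points: pd.DataFrame
    guides: pd.DataFrame
    center: float

    def to_tsv(self, path) -> None:
        self.points.to_csv(path, sep="\t", index=False)


def funnel_data(
    effects: Sequence[EffectRecord],
    pooled: PooledEffect | None = None,
    alpha: float = 0.05,
    n_guide: int = 50,
) -> FunnelData:
    """Export funnel-plot coordinates: one (z, se) point per study.

    Guide lines trace ``center +- z_crit * se`` over the observed se range,
    the wedge inside which study effects fall absent bias and
    heterogeneity.  ``pooled`` supplies the center; if omitted it is
    re-pooled from the effects.
    """
    if len(effects) == 0:
        raise ValueError("funnel_data requires at least one effect")
    if pooled is None:
        pooled = pool_random(effects, alpha=alpha)
    points = pd.DataFrame(
        {
            "study_id": [e.study_id for e in effects],
            "z": [e.z for e in effects],
            "se": [e.se for e in effects],
        }
    )
    crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    se_grid = np.linspace(0.0, float(points["se"].max()), n_guide)
    guides = pd.DataFrame(
        {
            "se": se_grid,
            "lo": pooled.z_pooled - crit * se_grid,
            "hi": pooled.z_pooled + crit * se_grid,
        }
    )
    return FunnelData(points=points, guides=guides, center=pooled.z_pooled)


@dataclass(frozen=True)
class TrimFillResult:
    """Outcome of the trim-and-fill correction."""

    k0: int
    side: str
    imputed_effects: tuple[EffectRecord, ...]
    adjusted: PooledEffect
    unadjusted: PooledEffect
    iterations: int = 0

    @property
    def filled(self) -> bool:
        return self.k0 > 0


def _rank_first(x: np.ndarray) -> np.ndarray:
    # ranks 1..n with ties broken by position (stable), like R's ties.method="first"
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    ranks[order] = np.arange(1, len(x) + 1)
    return ranks


def trim_and_fill(
    effects: Sequence[EffectRecord],
    side: str = "auto",
    alpha: float = 0.05,
    tau2_estimator: str = "dl",
    max_iter: int = 50,
) -> TrimFillResult:
    """Duval-Tweedie trim-and-fill with the L0 missing-study estimator.

    The algorithm assumes studies are suppressed on one side of the
    funnel.  It iterates: trim the k0 most extreme effects on the
    opposite side, re-pool the remainder (random effects, same tau^2
    estimator as the main analysis), recompute the signed-rank statistic
    of deviations around the trimmed pooled estimate, and update
    k0 = max(0, round((4*S_r - k(k+1)) / (2k - 1))) until stable.  The
    trimmed studies are then mirrored about the final pooled estimate and
    the augmented set is re-pooled.

    ``side`` names where the missing studies are assumed to lie;
    ``"auto"`` places them toward the null (left of the funnel when the
    pooled effect is positive, right when negative).
    """
    k = len(effects)
    unadjusted = pool_random(effects, alpha=alpha, tau2_estimator=tau2_estimator)
    if k < 3:
        warnings.warn(
            "trim-and-fill needs at least 3 studies; returning k0 = 0", stacklevel=2
        )
        return TrimFillResult(
            k0=0, side=side, imputed_effects=(), adjusted=unadjusted,
            unadjusted=unadjusted,
        )
    if side == "auto":
        side = "left" if unadjusted.z_pooled > 0 else "right"
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left', 'right' or 'auto', got {side!r}")

    flip = -1.0 if side == "right" else 1.0
    y = np.array([e.z for e in effects], dtype=float) * flip
    order = np.argsort(y, kind="stable")
    y_sorted = y[order]
    sorted_effects = [effects[i] for i in order]

    k0, k0_prev, iters, beta = 0, -1, 0, 0.0
    while k0 != k0_prev:
        k0_prev = k0
        iters += 1
        if iters > max_iter:
            warnings.warn("trim-and-fill did not converge; using last k0", stacklevel=2)
            break
        trimmed = [
            EffectRecord(e.study_id, z=flip * e.z, v=e.v, se=e.se, n=e.n)
            for e in sorted_effects[: k - k0]
        ]
        beta = pool_random(trimmed, alpha=alpha, tau2_estimator=tau2_estimator).z_pooled
        dev = y_sorted - beta
        signed_ranks = np.sign(dev) * _rank_first(np.abs(dev))
        s_r = float(np.sum(signed_ranks[signed_ranks > 0]))
        est = (4.0 * s_r - k * (k + 1)) / (2.0 * k - 1.0)
        k0 = min(max(0, round(est)), k - 2)

    imputed: list[EffectRecord] = []
    for e in sorted_effects[k - k0 :]:
        mirrored = flip * (2.0 * beta - flip * e.z)
        imputed.append(
            EffectRecord(
                study_id=f"filled:{e.study_id}", z=mirrored, v=e.v, se=e.se, n=e.n
            )
        )
    if imputed:
        adjusted = pool_random(
            list(effects) + imputed, alpha=alpha, tau2_estimator=tau2_estimator
        )
    else:
        adjusted = unadjusted
    return TrimFillResult(
        k0=k0,
        side=side,
        imputed_effects=tuple(imputed),
        adjusted=adjusted,
        unadjusted=unadjusted,
        iterations=iters,
    )
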