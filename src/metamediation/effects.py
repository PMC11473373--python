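"""Fisher-z effect sizes for Pearson correlations.

All pooling in this package happens on the variance-stabilized Fisher-z
scale, z = arctanh(r) = 0.5*ln((1+r)/(1-r)), whose large-sample variance
1/(n-3) depends only on the sample size.  The correlation scale is used
for presentation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coding import CodingTable, StudyRecord

__all__ = [
    "fisher_z",
    "inverse_fisher_z",
    "EffectRecord",
    "to_effect",
    "effects_from_table",
    "CORRELATION_KEYS",
]

#: The three pairwise relations a study record codes.
CORRELATION_KEYS = ("pa_re", "pa_mh", "re_mh")


def fisher_z(r):
    """Fisher z transform, ``0.5*ln((1+r)/(1-r))``.

    Accepts a scalar or array with every element strictly inside (-1, 1);
    values on or outside the boundary raise ``ValueError``.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError(f"correlation magnitude must be < 1, got {r!r}")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def inverse_fisher_z(z):
    """Back-transform, ``(e^{2z}-1)/(e^{2z}+1)`` = tanh(z).

    Numerically safe for arbitrarily large ``|z|`` (saturates at +-1).
    """
    arr = np.asarray(z, dtype=float)
    out = np.tanh(arr)
    return float(out) if np.isscalar(z) or arr.ndim == 0 else out


@dataclass(frozen=True)
class EffectRecord:
    """A single Fisher-z effect with its sampling variance.

    ``v`` is exactly 1/(n-3) and ``se`` its square root.
    """

    study_id: str
    z: float
    v: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError(f"{self.study_id}: n must be >= 4, got {self.n}")
        if not math.isfinite(self.z):
            raise ValueError(f"{self.study_id}: non-finite z")

    @property
    def r(self) -> float:
        """The effect on the correlation scale."""
        return inverse_fisher_z(self.z)


def to_effect(record: StudyRecord, which: str) -> EffectRecord:
    """Convert one coded correlation of a study to a Fisher-z effect.

    ``which`` selects the relation: ``pa_re``, ``pa_mh`` or ``re_mh``.
    """
    if which not in CORRELATION_KEYS:
        raise KeyError(f"unknown relation {which!r}; expected one of {CORRELATION_KEYS}")
    v = 1.0 / (record.n - 3)
    return EffectRecord(
        study_id=record.study_id,
        z=fisher_z(record.correlation(which)),
        v=v,
        se=math.sqrt(v),
        n=record.n,
    )


def effects_from_table(table: CodingTable, which: str) -> list[EffectRecord]:
    """Fisher-z effects for one relation across all rows of a table."""
    return [to_effect(rec, which) for rec in table]
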