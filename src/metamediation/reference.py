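"""Reference inputs from the published meta-analysis this package reproduces.

Two kinds of reference data are packaged:

* the study coding table (16 independent samples, 15 studies, 17,043
  unique subjects) — see :func:`metamediation.coding.load_reference_table`;
* the pooled correlation matrices the original analysis fed into its
  path model, one per indicator polarity.

The published pooled cells differ slightly from what univariate DL
pooling of the coding table yields (the original web tool pooled the
matrix by its own scheme, and its positive stratum used k = 8 of the 9
coded samples).  The published matrices are therefore kept verbatim as
the canonical stage-2 input, while z-scale standard errors for CI
propagation are taken from pooling the packaged coding table.
"""

from __future__ import annotations

from .coding import Polarity, load_reference_table
from .masem import PooledMatrix, pool_matrix

__all__ = [
    "REFERENCE_POOLED_CELLS",
    "reference_pooled_matrix",
    "load_reference_table",
]

#: Published pooled correlation cells (r_xm, r_xy, r_my) per stratum.
REFERENCE_POOLED_CELLS = {
    Polarity.POSITIVE: {"xm": 0.263, "xy": 0.27, "my": 0.453},
    Polarity.NEGATIVE: {"xm": 0.273, "xy": -0.256, "my": -0.319},
}


def reference_pooled_matrix(polarity: Polarity | str, with_se: bool = True) -> PooledMatrix:
    """The published pooled matrix for one stratum, as a :class:`PooledMatrix`.

    Cell point estimates are the published values; the effective sample
    size and (optionally) the z-scale cell standard errors come from
    DL-pooling the packaged coding table's stratum, so Monte-Carlo CI
    propagation reflects the actual study set.
    """
    pol = Polarity.coerce(polarity)
    cells = REFERENCE_POOLED_CELLS[pol]
    own = pool_matrix(load_reference_table(), pol)
    return PooledMatrix(
        r_xm=cells["xm"],
        r_xy=cells["xy"],
        r_my=cells["my"],
        n_harmonic=own.n_harmonic,
        k=own.k,
        polarity=pol,
        se_z=dict(own.se_z) if with_se else None,
        per_cell=None,
    )
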