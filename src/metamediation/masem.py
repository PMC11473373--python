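"""Two-stage meta-analytic structural equation modeling (TSSEM).

Stage 1 pools each cell of the 3x3 correlation matrix among physical
activity (X), resilience (M), and a mental-health indicator (Y) by
univariate random-effects meta-analysis on the Fisher-z scale.  Stage 2
fits the saturated mediation path model

    M = a*X,   Y = c*X + b*M        (all variables standardized)

to the pooled matrix.  Because the model is just-identified its
standardized solution has closed forms,

    a  = r_xm
    b  = (r_my - r_xm * r_xy) / (1 - r_xm^2)
    c  = (r_xy - r_xm * r_my) / (1 - r_xm^2)
    ab = a * b,   d = ab + c = r_xy,

and its fit is trivially perfect (chi^2 ~ 0, df = 0).  A maximum-
likelihood fit of the same model is provided as an independent route; the
two must agree to high precision on any positive-definite input.

Confidence intervals for the paths propagate stage-1 uncertainty: the
Monte-Carlo method samples each pooled cell from its asymptotic normal on
the z scale and pushes draws through the closed forms; a first-order delta
method is available as a cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .coding import CodingTable, Polarity, subset_by_polarity
from .effects import effects_from_table, fisher_z, inverse_fisher_z
from .meta import PooledEffect, pool_random

__all__ = [
    "PooledMatrix",
    "FitIndices",
    "MediationResult",
    "pool_matrix",
    "fit_mediation",
    "mediation_ci",
    "proportion_mediated",
]

#: Matrix cells in (X, M, Y) order: X-M, X-Y, M-Y.
CELLS = ("xm", "xy", "my")

#: Which coded relation feeds each cell.
CELL_RELATIONS = {"xm": "pa_re", "xy": "pa_mh", "my": "re_mh"}


class NotPositiveDefiniteError(ValueError):
    """A pooled correlation matrix is not positive definite."""


@dataclass(frozen=True)
class PooledMatrix:
    """Pooled 3x3 correlation matrix for one polarity stratum.

    ``n_harmonic`` is the harmonic mean of the stratum sample sizes and is
    the effective n used for stage-2 fit statistics.  ``se_z`` carries the
    z-scale standard error of each pooled cell so CI machinery can
    propagate stage-1 uncertainty; ``per_cell`` keeps the full pooled
    results when the matrix came from a coding table.
    """

    r_xm: float
    r_xy: float
    r_my: float
    n_harmonic: float
    k: int
    polarity: Polarity | None = None
    se_z: dict | None = None
    per_cell: dict | None = None

    def __post_init__(self) -> None:
        eigmin = float(np.min(np.linalg.eigvalsh(self.matrix())))
        if eigmin <= 0:
            raise NotPositiveDefiniteError(
                f"pooled correlation triple (r_xm={self.r_xm}, r_xy={self.r_xy}, "
                f"r_my={self.r_my}) is not positive definite "
                f"(smallest eigenvalue {eigmin:.3e})"
            )

    def matrix(self) -> np.ndarray:
        """The full symmetric matrix in (X, M, Y) order."""
        return np.array(
            [
                [1.0, self.r_xm, self.r_xy],
                [self.r_xm, 1.0, self.r_my],
                [self.r_xy, self.r_my, 1.0],
            ]
        )

    def to_dict(self) -> dict:
        return {
            "r_xm": self.r_xm,
            "r_xy": self.r_xy,
            "r_my": self.r_my,
            "n_harmonic": self.n_harmonic,
            "k": self.k,
            "polarity": self.polarity.value if self.polarity else None,
            "se_z": dict(self.se_z) if self.se_z else None,
        }


@dataclass(frozen=True)
class FitIndices:
    """SEM fit block; trivially perfect for a saturated model."""

    chi2: float
    df: int
    cfi: float
    tli: float
    rmsea: float

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "cfi": self.cfi,
                "tli": self.tli, "rmsea": self.rmsea}


@dataclass(frozen=True)
class MediationResult:
    """Standardized paths of the saturated X -> M -> Y model.

    ``d = ab + c`` is the total effect and equals the pooled X-Y
    correlation exactly; ``proportion`` is the mediated share 100*ab/d.
    CI fields are ``None`` until filled by :func:`mediation_ci`.
    """

    a: float
    b: float
    c: float
    ab: float
    d: float
    proportion: float
    fit: FitIndices
    k: int
    n: float
    ci_a: tuple[float, float] | None = None
    ci_b: tuple[float, float] | None = None
    ci_c: tuple[float, float] | None = None
    ci_ab: tuple[float, float] | None = None
    method: str = "closed_form"

    def to_dict(self) -> dict:
        out = {
            "a": self.a, "b": self.b, "c": self.c, "ab": self.ab, "d": self.d,
            "proportion_mediated": self.proportion, "k": self.k, "n": self.n,
            "fit": self.fit.to_dict(), "method": self.method,
        }
        for name in ("ci_a", "ci_b", "ci_c", "ci_ab"):
            ci = getattr(self, name)
            out[name] = list(ci) if ci is not None else None
        return out

    def path_model_text(self) -> str:
        """Human-readable echo of the fitted path model for audit."""
        return "\n".join(
            [
                "saturated mediation path model (standardized):",
                f"  M = a*X           a  = {self.a: .4f}",
                f"  Y = c*X + b*M     b  = {self.b: .4f}   c = {self.c: .4f}",
                f"  indirect ab = {self.ab: .4f}   total d = ab + c = {self.d: .4f}",
                f"  proportion mediated = {self.proportion:.2f}%",
            ]
        )


def pool_matrix(
    table: CodingTable,
    polarity: Polarity | str,
    alpha: float = 0.05,
    tau2_estimator: str = "dl",
    exclude_ids: Sequence[str] = (),
) -> PooledMatrix:
    """Stage 1: pool all three correlation cells for one polarity stratum.

    Each cell is pooled independently by DL random effects on the
    Fisher-z scale and back-transformed.  ``exclude_ids`` drops named
    studies before pooling (all cells use the same study set).
    """
    stratum = subset_by_polarity(table, polarity)
    if exclude_ids:
        stratum = stratum.exclude(exclude_ids)
    if stratum.k == 0:
        raise ValueError(f"no studies in the {Polarity.coerce(polarity).value} stratum")

    per_cell: dict[str, PooledEffect] = {}
    for cell, relation in CELL_RELATIONS.items():
        per_cell[cell] = pool_random(
            effects_from_table(stratum, relation), alpha=alpha,
            tau2_estimator=tau2_estimator,
        )
    ns = np.array([rec.n for rec in stratum], dtype=float)
    return PooledMatrix(
        r_xm=per_cell["xm"].r_pooled,
        r_xy=per_cell["xy"].r_pooled,
        r_my=per_cell["my"].r_pooled,
        n_harmonic=float(len(ns) / np.sum(1.0 / ns)),
        k=stratum.k,
        polarity=Polarity.coerce(polarity),
        se_z={cell: per_cell[cell].se_z for cell in CELLS},
        per_cell=per_cell,
    )


def _closed_form_paths(r_xm: float, r_xy: float, r_my: float) -> tuple[float, float, float]:
    if abs(r_xm) >= 1.0:
        raise ValueError("X and M are collinear (|r_xm| >= 1); paths undefined")
    denom = 1.0 - r_xm**2
    a = r_xm
    b = (r_my - r_xm * r_xy) / denom
    c = (r_xy - r_xm * r_my) / denom
    return a, b, c


def _implied(a: float, b: float, c: float) -> np.ndarray:
    return np.array(
        [
            [1.0, a, c + a * b],
            [a, 1.0, b + a * c],
            [c + a * b, b + a * c, 1.0],
        ]
    )


def _ml_discrepancy(theta: np.ndarray, s: np.ndarray, logdet_s: float) -> float:
    sigma = _implied(*theta)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e12
    return logdet + float(np.trace(s @ np.linalg.inv(sigma))) - logdet_s - 3.0


def _fit_ml(s: np.ndarray) -> tuple[float, float, float, float]:
    """Fit a, b, c by maximum likelihood, starting from the null model.

    The ML solution of the saturated model makes the implied matrix match
    the observed one, so the moment residuals are driven to zero by
    Levenberg-Marquardt (robust from the a = b = c = 0 start, where
    gradient descent on the raw discrepancy can stall against the
    positive-definiteness boundary); the ML discrepancy F_ML is then
    evaluated at the solution for the fit block.
    """
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise NotPositiveDefiniteError("input matrix is not positive definite")

    iu = np.triu_indices(3, k=1)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return (_implied(*theta) - s)[iu]

    res = optimize.least_squares(
        residuals, x0=np.zeros(3), method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    a, b, c = (float(t) for t in res.x)
    f_min = max(0.0, _ml_discrepancy(res.x, s, logdet_s))
    return a, b, c, f_min


def _fit_block(f_min: float, n: float) -> FitIndices:
    # saturated model: df = 6 moments - 6 free parameters = 0
    chi2 = max(0.0, (n - 1.0) * f_min)
    return FitIndices(chi2=chi2, df=0, cfi=1.0, tli=1.0, rmsea=0.0)


def fit_mediation(matrix: PooledMatrix, method: str = "closed_form") -> MediationResult:
    """Stage 2: fit the saturated mediation model to a pooled matrix.

    ``method="closed_form"`` uses the exact standardized solution;
    ``method="ml"`` minimizes the ML discrepancy numerically.  Both report
    the saturated fit block with chi^2 evaluated at the solution.
    """
    if method == "closed_form":
        a, b, c = _closed_form_paths(matrix.r_xm, matrix.r_xy, matrix.r_my)
        sign, logdet_s = np.linalg.slogdet(matrix.matrix())
        f_min = max(0.0, _ml_discrepancy(np.array([a, b, c]), matrix.matrix(), logdet_s))
    elif method == "ml":
        a, b, c, f_min = _fit_ml(matrix.matrix())
    else:
        raise ValueError(f"unknown method {method!r}; expected 'closed_form' or 'ml'")
    ab = a * b
    d = ab + c
    return MediationResult(
        a=a, b=b, c=c, ab=ab, d=d,
        proportion=proportion_mediated(ab, d) if d != 0 else math.nan,
        fit=_fit_block(f_min, matrix.n_harmonic),
        k=matrix.k,
        n=matrix.n_harmonic,
        method=method,
    )


def _require_se(matrix: PooledMatrix) -> dict:
    if not matrix.se_z or any(cell not in matrix.se_z for cell in CELLS):
        raise ValueError(
            "matrix carries no z-scale standard errors for its cells; "
            "pool it from a coding table or supply se_z explicitly"
        )
    return matrix.se_z


def mediation_ci(
    matrix: PooledMatrix,
    method: str = "monte_carlo",
    reps: int = 100_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict[str, tuple[float, float]]:
    """Confidence intervals for the paths a, b, c and the product ab.

    Monte Carlo: draw each pooled cell from Normal(z_cell, se_z_cell^2) on
    the Fisher-z scale (cells independent, as in the univariate stage-1
    pooling), back-transform, evaluate the closed-form paths, and take the
    alpha/2 and 1-alpha/2 percentiles.  Delta: first-order normal
    intervals, with var(ab) = a^2*var(b) + b^2*var(a).
    """
    se = _require_se(matrix)
    if method == "monte_carlo":
        if reps < 1000:
            raise ValueError("monte_carlo requires reps >= 1000")
        if seed is None:
            raise ValueError("monte_carlo requires an explicit seed")
        rng = np.random.default_rng(seed)
        z0 = {cell: fisher_z(getattr(matrix, f"r_{cell}")) for cell in CELLS}
        draws = {
            cell: inverse_fisher_z(rng.normal(z0[cell], se[cell], size=reps))
            for cell in CELLS
        }
        a = draws["xm"]
        denom = 1.0 - a**2
        b = (draws["my"] - a * draws["xy"]) / denom
        c = (draws["xy"] - a * draws["my"]) / denom
        ab = a * b
        lo, hi = 100.0 * alpha / 2.0, 100.0 * (1.0 - alpha / 2.0)
        return {
            name: tuple(np.percentile(vals, [lo, hi]))
            for name, vals in (("a", a), ("b", b), ("c", c), ("ab", ab))
        }
    if method == "delta":
        return _delta_ci(matrix, se, alpha)
    raise ValueError(f"unknown CI method {method!r}")


def _delta_ci(matrix: PooledMatrix, se: dict, alpha: float) -> dict:
    r_xm, r_xy, r_my = matrix.r_xm, matrix.r_xy, matrix.r_my
    a, b, c = _closed_form_paths(r_xm, r_xy, r_my)
    # cell sds on the correlation scale (delta through tanh)
    sd = {cell: (1.0 - getattr(matrix, f"r_{cell}") ** 2) * se[cell] for cell in CELLS}
    denom = 1.0 - r_xm**2

    def grad_partial(num_other: float, r_self: float, r_other: float):
        # gradient of (r_self - r_xm*r_other)/denom wrt (r_xm, r_other, r_self)
        d_rxm = (-r_other * denom + 2.0 * r_xm * (r_self - r_xm * r_other)) / denom**2
        return d_rxm, -r_xm / denom, 1.0 / denom

    gb = grad_partial(r_xy, r_my, r_xy)  # b wrt (xm, xy, my)
    gc = grad_partial(r_my, r_xy, r_my)  # c wrt (xm, my, xy)
    var_a = sd["xm"] ** 2
    var_b = (gb[0] * sd["xm"]) ** 2 + (gb[1] * sd["xy"]) ** 2 + (gb[2] * sd["my"]) ** 2
    var_c = (gc[0] * sd["xm"]) ** 2 + (gc[1] * sd["my"]) ** 2 + (gc[2] * sd["xy"]) ** 2
    var_ab = a**2 * var_b + b**2 * var_a
    crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    out = {}
    for name, point, var in (("a", a, var_a), ("b", b, var_b), ("c", c, var_c),
                             ("ab", a * b, var_ab)):
        half = crit * math.sqrt(var)
        out[name] = (point - half, point + half)
    return out


def proportion_mediated(ab: float, d: float) -> float:
    """Mediated share of the total effect, 100*ab/d, in percent.

    Sign-safe: a negative indirect effect over a negative total effect is
    a positive share.  ``d = 0`` is undefined; ``|ab| > |d|`` (inconsistent
    mediation) warns but still returns the value.
    """
    if d == 0:
        raise ValueError("proportion mediated undefined when the total effect is 0")
    if abs(ab) > abs(d):
        warnings.warn(
            "inconsistent mediation: |ab| exceeds |d|; proportion exceeds 100%",
            stacklevel=2,
        )
    return 100.0 * ab / d
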