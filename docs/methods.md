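# Methods

## Scope and data model

The unit of analysis is an independent sample that reports all three
Pearson correlations among physical activity (X), resilience (M), and one
mental-health indicator (Y). Indicators are analyzed in two strata by
polarity: positive (well-being, life satisfaction) and negative
(depression, anxiety, negative affect). A coding table row carries the
study label, sample size n ≥ 4, indicator name and polarity, the three
correlations (strictly inside (−1, 1)), and an optional
`shares_sample_with` link marking rows drawn from the same subjects.
Linked rows contribute independently to their own polarity stratum but
are counted once in the unique-subject total; links that point outside
the current table (e.g. after subsetting to one stratum) are inert.
The packaged reference table codes 16 samples from 15 studies (17,043
unique subjects; one middle-school sample appears in both strata), with
correlations stored exactly at their published precision.

## Effect sizes and pooling

All pooling happens on the Fisher-z scale (z = arctanh r, v = 1/(n−3));
the correlation scale is presentation-only, via back-transform tanh. No
small-sample bias correction is applied to r. The random-effects model
uses inverse-variance weights 1/(vᵢ + τ²) with τ² by the
DerSimonian–Laird moment estimator by default; a bounded-REML estimator
is available behind `tau2_estimator="reml"`. Cochran's Q uses
fixed-effect weights around the fixed-effect mean; I² = max(0, (Q−df)/Q)·100.
Confidence intervals are Wald on the z scale with the normal quantile
(α = 0.05 two-sided throughout), back-transformed; with a single study
the pooled result is that study with τ² = 0. DL pooling and Q are
cross-validated in the test suite against R's metafor on the same inputs.

## Publication-bias diagnostics

**Fail-safe N** follows Rosenthal's file-drawer argument on Stouffer's
combined z with per-study deviates uᵢ = zᵢ·√(nᵢ−3). We report the
*smallest integer* N of null studies that drives the combined statistic
below the two-sided α = 0.05 quantile, i.e. ⌈(Σu)²/1.959964² − k⌉ clipped
at zero — the ceiling, not the floor, since N−1 added null studies would
leave the result still significant. This convention reproduces the
reference analysis's printed counts (1,480 and 875 for the negative
stratum) exactly. The conventional adequacy bound 5k+10 is attached to
the result.

**Funnel data** are exported as (z, se) points with pseudo-confidence
guide lines pooled ± z₀.₉₇₅·se over the observed se range; no plotting
dependency is taken.

**Trim-and-fill** implements the Duval–Tweedie iteration with the L0
missing-study estimator: center all effects on the pooled estimate of the
currently trimmed set, form signed ranks of absolute deviations (ties
broken by position), and update k0 = max(0, round((4·S_r − k(k+1))/(2k−1)))
until stable; trimmed studies are then mirrored about the final center
and the augmented set re-pooled. Two deliberate choices: (i) the pooling
model *inside* the iteration is the same random-effects (DL) model as the
main analysis, for internal consistency — with fixed-effect trimming the
high-heterogeneity strata here would spuriously impute studies; (ii)
`side="auto"` assumes suppression on the side toward the null (left of
the funnel for positive pooled effects). The implementation is verified
against metafor's `trimfill` on both the reference strata (k0 = 0
everywhere) and a constructed one-sided deletion fixture (k0 = 3
recovered). Note a structural property found while constructing that
fixture: for a strictly (z, se)-mirrored set, deleting 3 studies leaves a
surviving mirror pair that brackets the pooled center and caps the L0
estimate at 2; detectability of the full deletion requires the funnel's
se profile to be informative (precise studies near the center), which the
fixture encodes.

## Two-stage MASEM

Stage 1 pools each of the three matrix cells independently by univariate
DL random effects within a stratum (univariate TSSEM). The pooled triple
must form a positive-definite matrix (checked; failure is an error). The
effective sample size attached to the matrix is the harmonic mean of the
stratum's study sizes; it affects only fit statistics and none of the
point estimates. Multivariate GLS pooling of the matrix is out of scope.

Stage 2 fits the saturated standardized path model M = aX, Y = cX + bM.
Because the model is just-identified, the solution is closed-form
(a = r_xm; b, c the partial-regression forms) and the fit is trivially
perfect: the fit block reports χ² = (n−1)·F_ML at the solution
(numerically ~0), df = 0, CFI = TLI = 1, RMSEA = 0. An independent
maximum-likelihood route fits the same model numerically
(Levenberg–Marquardt driving the implied-moment residuals to zero, which
at the saturated optimum coincides with minimizing the ML discrepancy
F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p); closed form and ML agree to 1e−8
on random positive-definite inputs (test-enforced; observed ~1e−13).
Gradient descent on F_ML directly from the null start can stall against
the positive-definiteness boundary, which motivated the residual-based
route. Saturated-model identities d = ab + c and d = r_xy hold to
machine precision and are asserted property-wise.

The proportion mediated is 100·ab/d, sign-safe (negative ab over negative
d is a positive share), undefined at d = 0, and |ab| > |d| (inconsistent
mediation) warns but returns the value. Because the reference analysis
published its proportions computed from 3-decimal rounded paths, exact
agreement with those figures is only recoverable from the rounded
entries; the unrounded closed-form proportions differ by ~0.2 percentage
points, which is the propagation of ±0.0005 rounding in each input cell.

Path CIs propagate stage-1 uncertainty. Default: Monte Carlo with 10⁵
draws (explicit seed mandatory), sampling each pooled cell independently
from Normal(z_cell, se_z²) on the z scale — matching the independence of
the univariate stage-1 pooling — back-transforming, and pushing draws
through the closed forms; intervals are 2.5/97.5 percentiles. The
first-order delta method (var(ab) = a²σ_b² + b²σ_a², cell-wise gradients
for b and c, correlation-scale cell sds (1−r²)·se_z) is the cross-check;
the two agree within 15% of interval width on the reference inputs. The
delta form neglects the a–b covariance induced by both depending on r_xm;
the Monte-Carlo route captures it and is the default for that reason.

When the published pooled matrices are used as stage-2 input
(`reference_pooled_matrix`), their cells are kept verbatim while the
z-scale cell standard errors and effective n come from pooling the
packaged coding table — the published analysis pooled its matrix with its
own (undocumented) scheme whose cells differ from univariate DL pooling
by ≤ 0.013, and its positive stratum used 8 of the 9 coded samples
(supported here via `exclude_ids`; dropping the one adult subjective
well-being sample reproduces the published k = 8 pooled values exactly).

## Synthetic data and parameter recovery

The generator emulates the random-effects data-generating process
directly: per study, true z-scale cells are drawn Normal(arctanh ρ, τ²)
independently per cell, back-transformed, repaired to the nearest
positive-definite matrix if needed (eigenvalue clip at 1e−6,
re-normalized to unit diagonal — a rare path at realistic τ), and the
study then reports sample correlations computed from n actually
generated trivariate-normal observations, so small-sample sampling error
is exact rather than asymptotic. Defaults mirror the reference
literature: ρ = (0.263, 0.27, 0.453), τ = 0.10 on the z scale, study
sizes uniform on [400, 2400]. Everything is reproducible from one seed
(per-replicate seeds spawned via `SeedSequence`).

What the generator does *not* emulate: correlated between-study random
effects across cells (heterogeneity is independent per cell, matching
the univariate pooling actually implemented), selective publication,
indicator-level clustering, or non-normal observations. Passing recovery
tests therefore validate the pipeline under its own assumptions, not
robustness to their violation.

The recovery harness runs the full pipeline per replicate and summarizes
bias, empirical SE, and 95% CI coverage for the pooled cells, τ², and
the paths a, b, c, ab. At the default scenario with k = 20 studies and
200 replicates (Monte-Carlo CIs at 4,000 draws per replicate — chosen to
keep the experiment at desk scale; endpoint noise is well below the
coverage tolerance), the indirect effect recovers with |bias| < 0.01 and
coverage within [90%, 98%].

## Numerical and reporting conventions

Rounding in rendered tables: 3 decimals for correlations, CIs and paths,
2 for I² and the mediated proportion. The report layer always runs
trim-and-fill and reports k0, flagging adjusted rows only when k0 > 0;
the decision of whether bias is "present" is left to the reader, as the
diagnostics are advisory. Rendering is byte-deterministic for identical
bundles. The CLI (`run`, `pool`, `bias`, `masem`, `simulate`, `recover`)
is a thin wrapper over these functions; every estimator choice and seed
is logged to stderr and recorded in the output bundle.

## Known limitations

- Univariate stage-1 pooling ignores within-study correlation among the
  three effect sizes; multivariate TSSEM would share information across
  cells. The published reference results are themselves reproducible
  under the univariate scheme, which is why it is the default and only
  implemented scheme.
- The published z-statistics for the negative-stratum pooled effects are
  inconsistent with their own printed CIs (they imply far smaller
  standard errors); we report the Wald z*/se* from the random-effects
  model and make no attempt to match those figures.
- No moderator/meta-regression machinery, Hartung–Knapp adjustment,
  prediction intervals, Egger-type regression tests, or selection models.
- Fail-safe N inherits the well-known fragilities of the file-drawer
  argument; it is reported because the reference analysis reports it.
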