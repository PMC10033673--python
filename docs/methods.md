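# Methods notes

## Statistical model and measures

All per-sample statistics act on a strictly positive sample x₁,…,xₙ of a
ratio-scale trait. Non-positive values are rejected at the boundary:
logs and record-wise reciprocals require positivity, and the CV itself
is only meaningful on a non-negative ratio scale. Every SD in the
package uses the n−1 denominator, including inside ĈV, so all four
measures share one dispersion convention.

* **ĈV = s/m.** The plain CV. Under record-wise inversion yᵢ = 1/xᵢ
  both s and m change nonlinearly, so ĈV(x) ≠ ĈV(1/x) in general.
* **ĈV_L = √(exp(θ̂²) − 1)** with θ̂ the SD of zᵢ = ln xᵢ. If x is
  log-normal with log-scale parameters (ν, θ), the population CV is
  √(exp(θ²) − 1) — a function of θ alone — and ĈV_L estimates it.
  Because ln(1/x) = −ln(x) and the SD ignores sign, ĈV_L is *exactly*
  invariant under inversion, log-normal or not.
* **GCV = exp(θ̂) − 1.** Kirkwood's geometric CV; same exact inversion
  invariance, but it is a descriptive statistic, not a CV estimator.
* **CV_Q = (Q₃ − Q₁)/(Q₃ + Q₁).** At the population level
  Q₃(1/x) = 1/Q₁(x) for continuous x, which makes CV_Q exactly
  inversion-invariant. In a finite sample the identity holds whenever
  both quartile positions land on order statistics.

### Quantile convention

Sample quantiles default to linear interpolation of order statistics at
position h = (n−1)p + 1 (numpy's `"linear"`, identical to R's type 7 —
verified against R's `quantile()` during development). Under this
convention h is an integer at p = 1/4 and 3/4 exactly when
n ≡ 1 (mod 4), and then CV_Q(x) = CV_Q(1/x) to floating-point rounding.
For other n the two orientations interpolate between different pairs of
order statistics; on log-normal samples of n = 20 with θ ∈ [0.2, 1] the
mean absolute discrepancy is well below 0.02. The convention is a
parameter (`method=`) on all quartile-based operations so this
finite-sample effect can be probed under other conventions.

### Taylor ratio moments

For a ratio x/y of two random organs with moments
(μₓ, μᵧ, σₓ, σᵧ, cov), the second-order delta-method approximations are

    μ̃_{x/y} = μₓ/μᵧ − cov/μᵧ² + σᵧ²μₓ/μᵧ³
    σ̃_{x/y} = (μₓ/μᵧ)·√(σₓ²/μₓ² + σᵧ²/μᵧ² − 2cov/(μₓμᵧ))

Some printed renderings of these formulas carry two typographical slips
(σᵧ un-squared in the mean's third term; μₓ² instead of μᵧ² under σᵧ² in
the SD). The package implements the standard forms above;
`verbatim=True` reproduces the slipped forms literally for comparison.

`taylor_cv_discrepancy` returns the ratio of the approximate CVs of x/y
and y/x, (σ̃_{x/y}/σ̃_{y/x})·μ̃_{y/x}/μ̃_{x/y}. With the corrected SD
form the radicand is symmetric in x and y, so the factor reduces to
(μₓ²/μᵧ²)·μ̃_{y/x}/μ̃_{x/y}, and for independent organs to
(1 + CVₓ²)/(1 + CVᵧ²): the second-order CVs of a ratio and its inverse
agree exactly when the organ CVs are equal, and otherwise differ. When
both approximate SDs are zero the 0/0 case is defined as 1 (fully
symmetric degenerate input).

**Accuracy.** The truncation error of the second-order mean is
O(CV⁴) relative (for y ~ N(5, 0.5), E[1/y] has a 3σ⁴/μ⁵ remainder of
relative size ≈ 3·10⁻⁴), and the SD approximation errs by O(CV²)
relative (≈ 3% at organ CVs of 0.1). Monte-Carlo validation of the
formulas therefore has to be read against this floor: at 10⁶–10⁷ draws
the Monte-Carlo standard error is *smaller* than the truncation error
for organ CVs ≳ 0.03, so the Taylor values only match brute-force
moments to within sampling noise at small CVs. The property test uses
organ CVs of 0.02, where truncation (≲ 10⁻⁶ relative) is negligible
against the 3·SE band of 10⁶ draws.

## Pipeline conventions

* Minimum group size defaults to 10 records; groups below it are
  dropped before any measure is computed.
* Outlier exclusion defaults to per-group Tukey fences
  [Q₁ − 1.5·IQR, Q₃ + 1.5·IQR] on the raw primary-trait values — the
  most common convention. The reciprocal trait is recomputed from the
  *retained* records rather than screened independently: re-running the
  fence on 1/x would select a different record set and confound the
  orientation comparison. Groups left with fewer than 2 records are
  dropped with a warning; groups falling below the minimum size after
  exclusion leave the with-exclusion arm, and paired correlations use
  the group intersection.
* Ranks are ascending with average ties (real surveys can tie,
  e.g. after rounding), so rank differences can be half-integers.
* "Linear" correlation is Pearson, "rank" correlation is Spearman; both
  are computed for every measure pair under both exclusion regimes, plus
  the per-measure with-vs-without-exclusion correlation that serves as
  the robustness summary.

## Synthetic data generator

Each group g draws νg ~ U(nu_range) and θg ~ U(theta_range), then n
records exp(N(νg, θg)); the true CV of group g is √(exp(θg²) − 1).
Defaults: 30 groups of 100 records, ν ∈ [4.5, 6.0] (trait scale ≈
90–400, matching SLA in cm²/g), θ ∈ [0.2, 1.0] (true CVs ≈ 0.2–1.3, the
range seen in within-species leaf-trait data). Contamination multiplies
each record independently by `factor` (default 10) with probability
`rate` (default 0.05) — multiplicative and one-sided, so it is
*asymmetric under inversion*: a 10× outlier in x becomes a 0.1× inlier
in 1/x, which is exactly the mechanism that breaks ĈV's symmetry while
leaving CV_Q almost untouched. All streams (parameters, values,
contamination) are spawned independently from one master seed, so
enabling contamination does not perturb the base draws and the
uncontaminated records stay bit-identical.

What the generator does *not* emulate: plot/site structure within
species, between-trait or phylogenetic correlation, measurement rounding
and heteroscedastic measurement error, or non-log-normal trait shapes.
Passing tests therefore demonstrate the mathematical behaviour of the
measures under the log-normal-plus-outliers model, not the field
properties of any particular survey.

## Numerical choices

* Exact-equality assertions use a 1e-12 absolute tolerance; every
  formula involved is O(1)-conditioned at trait scale. The exponential
  in GCV amplifies log-rounding for pathologically wide samples (log
  range ≫ 10), which is outside the trait regime; the stress test uses
  a correspondingly looser bound.
* `expm1` is used for exp(·) − 1 to keep precision near θ = 0.
* Bivariate organ simulation requires both means ≥ 5 SDs above zero and
  rejects the (then negligible) non-positive draws, keeping the ratio
  x/y well-behaved.
* The with-vs-without-exclusion robustness comparison uses 200 replicate
  datasets at the generator defaults; the acceptance script's synthetic
  study uses 79 groups to match the scale of a realistic multi-species
  survey.

## Known limitations

* ĈV_L and GCV are *more* sensitive to heavy contamination than ĈV in
  some regimes (an outlier inflates the log-SD that both exponentiate);
  the package measures this rather than hiding it — see the
  with-vs-without correlations in the robustness outputs.
* CV_Q discards all information outside the interquartile range;
  distributions differing only in the tails are indistinguishable to it.
* No confidence intervals or between-group hypothesis tests are
  provided; the scope is descriptive comparison.
* Proportion-type traits (x/(x+y)) are supported only through
  `complement_proportion`; note that relative variation of a proportion
  and its complement legitimately differ — only absolute variation (SD,
  IQR) is reflection-invariant.
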