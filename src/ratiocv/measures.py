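"""Relative-variation measures for positive, ratio-scale samples.

Many functional traits are quotients of two organ measurements (specific
leaf area = leaf area / leaf dry mass), and the reciprocal quotient (leaf
mass per area) is an equally meaningful trait.  A measure of *relative*
variation should therefore give (nearly) the same answer for a trait and
its reciprocal.  This module implements four such measures,

* ``cv_hat``   — the classical coefficient of variation, s / m;
* ``cv_l_hat`` — the log-normal CV estimate, sqrt(exp(s_z**2) - 1), with
  s_z the sample SD of the log-transformed values;
* ``gcv``      — Kirkwood's geometric coefficient of variation,
  exp(s_z) - 1;
* ``cv_q``     — the quartile coefficient of variation,
  (Q3 - Q1) / (Q3 + Q1);

together with the closed-form moments of the log-normal distribution and
second-order Taylor (delta-method) approximations to the mean and SD of a
ratio of two random variables.  The Taylor formulas quantify *why* the
plain CV of x/y and of y/x can disagree, while ``cv_l_hat`` and ``gcv``
are exactly reciprocal-invariant (the log SD is unchanged by negating
every log) and ``cv_q`` is reciprocal-invariant at the population level.

All samples must be strictly positive: reciprocals and logarithms are
taken record-wise, and CV itself is only meaningful for ratio-scale,
non-negative variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InsufficientDataError

__all__ = [
    "LogTransformedSample",
    "MeasureSet",
    "QuartileSummary",
    "MomentSet",
    "LogNormalParams",
    "MEASURE_NAMES",
    "cv_hat",
    "log_transform",
    "cv_l_hat",
    "gcv",
    "quartiles",
    "cv_q",
    "measure_set",
    "lognormal_moments",
    "lognormal_cv",
    "taylor_ratio_mean",
    "taylor_ratio_sd",
    "taylor_cv_discrepancy",
]

#: Names of the four per-sample measures, in canonical order.
MEASURE_NAMES = ("cv_hat", "cv_l_hat", "gcv", "cv_q")

#: Default sample-quantile convention: linear interpolation of order
#: statistics at position h = (n - 1) p + 1 (numpy's "linear", R type 7).
DEFAULT_QUANTILE_METHOD = "linear"


def _as_sample(values, min_n: int = 2) -> np.ndarray:
    """Validate and return a 1-D float array of strictly positive values."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < min_n:
        raise InsufficientDataError(
            f"need at least {min_n} values, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise DomainError("sample contains non-finite values")
    if np.any(arr <= 0):
        raise DomainError(
            "sample contains non-positive values; all measures here require "
            "strictly positive ratio-scale data"
        )
    return arr


@dataclass(frozen=True)
class LogTransformedSample:
    """Natural logs of a positive sample with their mean and SD (ddof=1)."""

    z_values: np.ndarray = field(repr=False)
    z_mean: float
    z_sd: float


@dataclass(frozen=True)
class MeasureSet:
    """The four relative-variation statistics for one sample.

    All four are dimensionless and invariant under positive rescaling of
    the sample; ``cv_q`` lies in [0, 1) for strictly positive data.
    """

    cv_hat: float
    cv_l_hat: float
    gcv: float
    cv_q: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MEASURE_NAMES}


@dataclass(frozen=True)
class QuartileSummary:
    """First and third sample quartiles, in trait units."""

    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class MomentSet:
    """Population moments of an organ pair (x, y) feeding the Taylor formulas."""

    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    cov_xy: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_x < 0 or self.sigma_y < 0:
            raise DomainError("standard deviations must be non-negative")
        bound = self.sigma_x * self.sigma_y
        if abs(self.cov_xy) > bound * (1 + 1e-12) + 1e-300:
            raise DomainError(
                f"|cov| = {abs(self.cov_xy)} exceeds sigma_x*sigma_y = {bound}"
            )

    def swapped(self) -> "MomentSet":
        """Moments with the roles of x and y exchanged (for y/x)."""
        return MomentSet(self.mu_y, self.mu_x, self.sigma_y, self.sigma_x,
                         self.cov_xy)


@dataclass(frozen=True)
class LogNormalParams:
    """Log-scale mean ``nu`` and SD ``theta`` of a log-normal ratio."""

    nu: float
    theta: float

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise DomainError("theta must be non-negative")


# ---------------------------------------------------------------------------
# per-sample measures
# ---------------------------------------------------------------------------

def cv_hat(sample) -> float:
    """Classical coefficient of variation: sample SD (ddof=1) over mean.

    Sensitive both to outliers and to replacing the trait by its
    reciprocal; the other three measures exist to repair one or both
    defects.
    """
    arr = _as_sample(sample)
    m = arr.mean()
    if m <= 0:
        raise DomainError("CV is undefined for a non-positive mean")
    return float(arr.std(ddof=1) / m)


def log_transform(sample) -> LogTransformedSample:
    """Natural-log transform with mean and SD (ddof=1) of the logs.

    Negating every log (i.e. taking record-wise reciprocals of the
    sample) leaves the log SD unchanged, which is the source of the exact
    reciprocal-invariance of ``cv_l_hat`` and ``gcv``.
    """
    arr = _as_sample(sample)
    z = np.log(arr)
    return LogTransformedSample(
        z_values=z, z_mean=float(z.mean()), z_sd=float(z.std(ddof=1))
    )


def cv_l_hat(sample) -> float:
    """CV estimate assuming a log-normal distribution.

    sqrt(exp(theta_hat**2) - 1), where theta_hat is the sample SD of the
    logs.  Unbiased use requires log-normality, but it remains a valid
    descriptive statistic otherwise.
    """
    s = log_transform(sample).z_sd
    return math.sqrt(math.expm1(s * s))


def gcv(sample) -> float:
    """Kirkwood's geometric coefficient of variation, exp(s_z) - 1.

    A descriptive statistic, not an estimator of CV, even under
    log-normality.
    """
    return math.expm1(log_transform(sample).z_sd)


def quartiles(sample, method: str = DEFAULT_QUANTILE_METHOD) -> QuartileSummary:
    """First and third sample quartiles under a named quantile convention.

    ``method`` is any convention accepted by :func:`numpy.quantile`
    (default ``"linear"``: interpolation of order statistics at
    h = (n - 1) p + 1).  The convention matters for the finite-sample
    reciprocal-invariance of ``cv_q``: with the default, quartiles land
    exactly on order statistics whenever n = 1 (mod 4).
    """
    arr = np.asarray(sample, dtype=float).ravel()
    if arr.size < 2:
        raise InsufficientDataError("need at least 2 values for quartiles")
    if not np.all(np.isfinite(arr)):
        raise DomainError("sample contains non-finite values")
    q1, q3 = np.quantile(arr, [0.25, 0.75], method=method)
    return QuartileSummary(q1=float(q1), q3=float(q3))


def cv_q(sample, method: str = DEFAULT_QUANTILE_METHOD) -> float:
    """Quartile coefficient of variation, (Q3 - Q1) / (Q3 + Q1).

    Depends only on the central half of the distribution, so it is
    insensitive to outliers; at the population level it is exactly
    reciprocal-invariant because Q3(1/x) = 1/Q1(x).  In finite samples
    the identity is exact when both quartiles land on order statistics
    (n = 1 mod 4 under the default convention) and holds to within small
    interpolation differences otherwise.
    """
    arr = _as_sample(sample)
    q = quartiles(arr, method=method)
    return float((q.q3 - q.q1) / (q.q3 + q.q1))


def measure_set(sample, method: str = DEFAULT_QUANTILE_METHOD) -> MeasureSet:
    """All four measures for one sample."""
    arr = _as_sample(sample)
    return MeasureSet(
        cv_hat=cv_hat(arr),
        cv_l_hat=cv_l_hat(arr),
        gcv=gcv(arr),
        cv_q=cv_q(arr, method=method),
    )


# ---------------------------------------------------------------------------
# log-normal closed forms
# ---------------------------------------------------------------------------

def lognormal_moments(params: LogNormalParams) -> tuple[float, float]:
    """Mean and SD of a log-normal variable with log-scale params (nu, theta).

    mean = exp(nu + theta**2 / 2);  sd = mean * sqrt(exp(theta**2) - 1).
    """
    mean = math.exp(params.nu + 0.5 * params.theta**2)
    sd = mean * math.sqrt(math.expm1(params.theta**2))
    return mean, sd


def lognormal_cv(theta: float) -> float:
    """CV of a log-normal variable: sqrt(exp(theta**2) - 1).

    Depends on the log-scale SD ``theta`` only — not on ``nu`` — and is
    strictly increasing in theta.  Since log(y/x) = -log(x/y) has the
    same SD, the population CV of a log-normal ratio equals that of its
    reciprocal.
    """
    if theta < 0:
        raise DomainError("theta must be non-negative")
    return math.sqrt(math.expm1(theta * theta))


# ---------------------------------------------------------------------------
# Taylor (delta-method) moments of a ratio x/y
# ---------------------------------------------------------------------------

def taylor_ratio_mean(m: MomentSet, verbatim: bool = False) -> float:
    """Second-order Taylor approximation to E[x/y].

    mu_x/mu_y - cov(x,y)/mu_y**2 + sigma_y**2 * mu_x / mu_y**3.

    ``verbatim=True`` substitutes sigma_y (not squared) in the third
    term, reproducing a variant form that circulates in print; the
    default is the standard delta-method result.  Accuracy degrades as
    O(CV_y**4): see the Taylor notes in the package docs.
    """
    if m.mu_y == 0:
        raise DomainError("mu_y must be non-zero")
    spread = m.sigma_y if verbatim else m.sigma_y**2
    return (m.mu_x / m.mu_y
            - m.cov_xy / m.mu_y**2
            + spread * m.mu_x / m.mu_y**3)


def taylor_ratio_sd(m: MomentSet, verbatim: bool = False) -> float:
    """Second-order Taylor approximation to SD[x/y].

    (mu_x/mu_y) * sqrt(sigma_x**2/mu_x**2 + sigma_y**2/mu_y**2
                       - 2 cov / (mu_x mu_y)).

    ``verbatim=True`` puts mu_x**2 under sigma_y**2 in the radicand (a
    variant seen in print); the default is the standard form.
    """
    if m.mu_x == 0 or m.mu_y == 0:
        raise DomainError("mu_x and mu_y must be non-zero")
    y_denom = m.mu_x**2 if verbatim else m.mu_y**2
    rad = (m.sigma_x**2 / m.mu_x**2
           + m.sigma_y**2 / y_denom
           - 2 * m.cov_xy / (m.mu_x * m.mu_y))
    if rad < 0:
        if rad > -1e-15:
            rad = 0.0
        else:
            raise DomainError(f"inconsistent moments: negative radicand {rad}")
    return abs(m.mu_x / m.mu_y) * math.sqrt(rad)


def taylor_cv_discrepancy(m: MomentSet, verbatim: bool = False) -> float:
    """Multiplicative disagreement between the approximate CVs of x/y and y/x.

    Returns (sd~_{x/y} / sd~_{y/x}) * mean~_{y/x} / mean~_{x/y}, i.e. the
    ratio CV~(x/y) / CV~(y/x) of the Taylor-approximated coefficients of
    variation.  It equals 1 exactly iff the two approximate CVs agree —
    for independent x, y this reduces to (1 + CV_x**2) / (1 + CV_y**2),
    so the plain CV of a ratio and of its inverse coincide (to second
    order) only when the two organs have equal CVs.  When both
    approximate SDs are zero the ratio is defined as 1 (degenerate,
    fully symmetric case).
    """
    ms = m.swapped()
    sd_xy = taylor_ratio_sd(m, verbatim=verbatim)
    sd_yx = taylor_ratio_sd(ms, verbatim=verbatim)
    if sd_xy == 0.0 and sd_yx == 0.0:
        return 1.0
    if sd_yx == 0.0:
        raise DomainError("SD of y/x is zero while SD of x/y is not")
    mean_xy = taylor_ratio_mean(m, verbatim=verbatim)
    mean_yx = taylor_ratio_mean(ms, verbatim=verbatim)
    if mean_xy == 0.0:
        raise DomainError("approximate mean of x/y is zero")
    return (sd_xy / sd_yx) * mean_yx / mean_xy
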