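"""Per-sample measures: frozen hand values, domains, and invariances."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import ratiocv as rc
from ratiocv.errors import DomainError, InsufficientDataError

# element range keeps log-SDs in the regime of real ratio traits
# (s_z of a few at most); the exponential amplification in gcv makes
# absolute float-error bounds meaningless for arbitrarily wild samples
positive_samples = arrays(
    dtype=float,
    shape=st.integers(min_value=2, max_value=40),
    elements=st.floats(min_value=0.05, max_value=50.0),
)


# ---------------------------------------------------------------------------
# frozen example values (hand arithmetic)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "func, sample, expected",
    [
        (rc.cv_hat, [5, 5, 5, 5], 0.0),
        (rc.cv_hat, [1, 2, 3, 4], math.sqrt(5 / 3) / 2.5),  # 0.516398
        (rc.cv_l_hat, [2, 2, 2], 0.0),
        (rc.cv_l_hat, [1, math.e], math.sqrt(math.e**0.5 - 1)),  # 0.805432
        (rc.gcv, [7, 7], 0.0),
        (rc.gcv, [1, math.e], math.exp(math.sqrt(0.5)) - 1),  # 1.028115
        (rc.cv_q, [1, 2, 3, 4, 5], 1 / 3),
        (rc.cv_q, [1, 0.5, 1 / 3, 0.25, 0.2], 1 / 3),  # reciprocal set
        (rc.cv_q, [4, 4, 4, 4], 0.0),
    ],
)
def test_measure_hand_values(func, sample, expected):
    assert func(sample) == pytest.approx(expected, abs=1e-12)


def test_log_transform_hand_values():
    lt = rc.log_transform([1.0, math.e])
    np.testing.assert_allclose(lt.z_values, [0.0, 1.0])
    assert lt.z_mean == pytest.approx(0.5)
    assert lt.z_sd == pytest.approx(math.sqrt(0.5))
    assert rc.log_transform([1, 1, 1]).z_sd == 0.0
    # negating every log (reciprocal sample) leaves the SD unchanged
    assert rc.log_transform([1, 2, 4]).z_sd == pytest.approx(
        rc.log_transform([1, 0.5, 0.25]).z_sd, abs=1e-14
    )


@pytest.mark.parametrize(
    "sample, expected_q1, expected_q3",
    [
        ([1, 2, 3, 4, 5], 2.0, 4.0),       # h lands on order statistics
        ([1, 2, 3, 4], 1.75, 3.25),        # interpolated: h = 1.75, 3.25
        ([6, 6, 6, 6], 6.0, 6.0),
    ],
)
def test_quartiles_default_convention(sample, expected_q1, expected_q3):
    q = rc.quartiles(sample)
    assert (q.q1, q.q3) == (expected_q1, expected_q3)
    assert min(sample) <= q.q1 <= q.q3 <= max(sample)


# ---------------------------------------------------------------------------
# domains and errors
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("func", [rc.cv_hat, rc.cv_l_hat, rc.gcv, rc.cv_q])
def test_single_value_is_insufficient(func):
    with pytest.raises(InsufficientDataError):
        func([3.0])


@pytest.mark.parametrize("func", [rc.cv_hat, rc.cv_l_hat, rc.gcv, rc.cv_q])
@pytest.mark.parametrize("bad", [[1.0, -2.0], [0.0, 1.0], [1.0, np.nan]])
def test_non_positive_values_rejected(func, bad):
    with pytest.raises(DomainError):
        func(bad)


def test_negative_theta_rejected():
    with pytest.raises(DomainError):
        rc.lognormal_cv(-0.1)
    with pytest.raises(DomainError):
        rc.LogNormalParams(nu=0.0, theta=-1.0)


# ---------------------------------------------------------------------------
# log-normal closed forms
# ---------------------------------------------------------------------------

def test_lognormal_moments_values():
    assert rc.lognormal_moments(rc.LogNormalParams(0.0, 0.0)) == (1.0, 0.0)
    mean, sd = rc.lognormal_moments(rc.LogNormalParams(0.0, 1.0))
    assert mean == pytest.approx(math.exp(0.5))          # 1.64872
    assert sd == pytest.approx(math.exp(0.5) * math.sqrt(math.e - 1))  # 2.16119


def test_lognormal_cv_independent_of_nu():
    for nu in (-2.0, 0.0, 2.0):
        mean, sd = rc.lognormal_moments(rc.LogNormalParams(nu, 1.0))
        assert sd / mean == pytest.approx(rc.lognormal_cv(1.0), rel=1e-12)


def test_lognormal_cv_values_and_monotonicity():
    assert rc.lognormal_cv(0.0) == 0.0
    assert rc.lognormal_cv(0.5) == pytest.approx(0.5329403500, abs=1e-9)
    assert rc.lognormal_cv(1.0) == pytest.approx(math.sqrt(math.e - 1))
    thetas = np.linspace(0.0, 3.0, 50)
    cvs = [rc.lognormal_cv(t) for t in thetas]
    assert np.all(np.diff(cvs) > 0)


def test_cv_q_increasing_in_q3():
    # holding Q1 fixed, growing the upper quartile grows cv_q
    base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    vals = []
    for top in (5.0, 6.0, 8.0, 12.0):
        s = base.copy()
        s[-2:] = [top - 1, top]  # Q3 = top-1 at n=5; Q1 stays 2
        vals.append(rc.cv_q(s))
    assert np.all(np.diff(vals) > 0)


# ---------------------------------------------------------------------------
# invariance properties
# ---------------------------------------------------------------------------

@given(sample=positive_samples,
       c=st.floats(min_value=1e-6, max_value=1e6))
def test_scale_invariance(sample, c):
    # stress regime: 12 decades of scale on already-extreme samples; the
    # exp in gcv amplifies the ~1e-15 log rounding, so the bound here is
    # looser than the 1e-12 that holds for realistic trait samples
    for func in (rc.cv_hat, rc.cv_l_hat, rc.gcv, rc.cv_q):
        assert abs(func(c * sample) - func(sample)) <= 1e-9


@given(sample=positive_samples)
def test_exact_inversion_invariance_of_log_measures(sample):
    assert abs(rc.cv_l_hat(sample) - rc.cv_l_hat(1 / sample)) <= 1e-12
    assert abs(rc.gcv(sample) - rc.gcv(1 / sample)) <= 1e-12


@given(sample=arrays(dtype=float, shape=st.sampled_from([5, 9, 13, 17, 21]),
                     elements=st.floats(min_value=1e-3, max_value=1e4)))
def test_cv_q_inversion_exact_when_quartiles_hit_order_statistics(sample):
    # n = 1 (mod 4): h = (n-1)p + 1 is an integer at p = 1/4 and 3/4,
    # so Q1(1/x) = 1/Q3(x) holds in-sample and cv_q is reciprocal-invariant
    assert abs(rc.cv_q(sample) - rc.cv_q(1 / sample)) <= 1e-12


def test_cv_q_inversion_small_discrepancy_other_n(sample_factory):
    diffs = [abs(rc.cv_q(s) - rc.cv_q(1 / s))
             for s in (sample_factory(n=20) for _ in range(300))]
    assert np.mean(diffs) < 0.02


def test_cv_hat_not_inversion_invariant_with_outlier(sample_factory):
    """A single 10x outlier is enough to break the plain CV's symmetry."""
    s = sample_factory(n=30)
    s[0] = 10 * s.max()
    assert abs(rc.cv_hat(s) - rc.cv_hat(1 / s)) > 0.05


def test_measure_set_bundles_all_four(sample_factory):
    s = sample_factory(n=25)
    ms = rc.measure_set(s)
    assert ms.as_dict() == {
        "cv_hat": rc.cv_hat(s),
        "cv_l_hat": rc.cv_l_hat(s),
        "gcv": rc.gcv(s),
        "cv_q": rc.cv_q(s),
    }
    assert 0 <= ms.cv_q < 1


def test_monte_carlo_recovery_of_lognormal_cv(rng):
    theta = 0.5
    draws = np.exp(rng.normal(0.0, theta, size=10**6))
    target = rc.lognormal_cv(theta)  # 0.53294
    assert rc.cv_hat(draws) == pytest.approx(target, rel=5e-3)
    assert rc.cv_l_hat(draws) == pytest.approx(target, rel=5e-3)
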