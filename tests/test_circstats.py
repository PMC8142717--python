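"""Circular mean/SD against brute-force and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import special, stats

from transsaccade import (
    angular_deviation,
    circ_mean,
    circ_sd,
    circular_summary,
    within_subject_ci,
    wrap_deg,
)

angles = st.lists(
    st.floats(min_value=-180.0, max_value=180.0, allow_nan=False), min_size=2, max_size=40
)


def brute_force_mean_resultant(a):
    """Independent vector-sum oracle using real trigonometry only."""
    s = sum(np.sin(np.radians(x)) for x in a) / len(a)
    c = sum(np.cos(np.radians(x)) for x in a) / len(a)
    return np.degrees(np.arctan2(s, c)), np.hypot(s, c)


class TestCircMean:
    def test_symmetric_pair_is_zero(self):
        assert circ_mean([10.0, -10.0])[0] == pytest.approx(0.0, abs=1e-12)

    def test_identical_angles(self):
        mean, rbar = circ_mean([25.0, 25.0, 25.0])
        assert mean == pytest.approx(25.0)
        assert rbar == pytest.approx(1.0)

    def test_right_angle_pair(self):
        mean, rbar = circ_mean([0.0, 90.0])
        assert mean == pytest.approx(45.0)
        assert rbar == pytest.approx(np.cos(np.radians(45.0)), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            circ_mean([])

    @given(angles, st.floats(min_value=-720, max_value=720, allow_nan=False))
    def test_rotation_equivariance(self, a, c):
        m0, _ = circ_mean(a)
        m1, _ = circ_mean(np.asarray(a) + c)
        assert abs(wrap_deg(m1 - m0 - c)) < 1e-6

    @given(angles)
    def test_matches_brute_force(self, a):
        m, r = circ_mean(a)
        mb, rb = brute_force_mean_resultant(a)
        assert r == pytest.approx(rb, abs=1e-10)
        if r > 1e-6:
            assert abs(wrap_deg(m - mb)) < 1e-8

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(-180, 180, 57)
        expected = stats.circmean(a, high=180, low=-180)
        assert abs(wrap_deg(circ_mean(a)[0] - expected)) < 1e-9


class TestCircSD:
    def test_identical_angles_zero(self):
        assert circ_sd([25.0, 25.0, 25.0]) == pytest.approx(0.0, abs=1e-5)

    def test_right_angle_pair_closed_form(self):
        expected = np.degrees(np.sqrt(-2.0 * np.log(np.cos(np.radians(45.0)))))
        assert circ_sd([0.0, 90.0]) == pytest.approx(expected, abs=1e-10)
        assert circ_sd([0.0, 90.0]) == pytest.approx(47.71, abs=0.01)

    def test_von_mises_bessel_oracle(self):
        # sd of VM(kappa) is sqrt(-2 ln(I1(k)/I0(k)))
        kappa = 8.0
        rng = np.random.default_rng(1)
        draws = np.degrees(rng.vonmises(0.0, kappa, size=1_000_000))
        analytic = np.degrees(np.sqrt(-2 * np.log(special.i1e(kappa) / special.i0e(kappa))))
        assert circ_sd(draws) == pytest.approx(analytic, abs=0.2)

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 30, 200)
        assert circ_sd(a) == pytest.approx(
            np.degrees(stats.circstd(np.radians(a))), abs=1e-9
        )

    @given(angles, st.floats(min_value=-360, max_value=360, allow_nan=False))
    def test_rotation_and_reflection_invariance(self, a, c):
        from hypothesis import assume

        sd0 = circ_sd(a)
        assume(np.isfinite(sd0) and sd0 < 150.0)
        assert circ_sd(np.asarray(a) + c) == pytest.approx(sd0, abs=1e-6, rel=1e-6)
        assert circ_sd(-np.asarray(a)) == pytest.approx(sd0, abs=1e-9, rel=1e-9)

    def test_uniform_sd_warns_infinite(self):
        with pytest.warns(UserWarning):
            assert np.isinf(circ_sd([0.0, 180.0]))

    def test_tight_samples_agree_with_linear_stats(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-9, 9, 500)
        assert circ_mean(a)[0] == pytest.approx(a.mean(), rel=1e-3, abs=1e-3)
        assert circ_sd(a) == pytest.approx(a.std(ddof=0), rel=1e-3)

    def test_angular_deviation_alternative(self):
        rbar = np.cos(np.radians(45.0))
        assert angular_deviation([0.0, 90.0]) == pytest.approx(
            np.degrees(np.sqrt(2 * (1 - rbar))), abs=1e-9
        )


def test_circular_summary_fields():
    s = circular_summary([20.0, 30.0, 25.0])
    assert s.n == 3 and s.mean_defined
    assert s.mean_deg == pytest.approx(25.0, abs=0.1)
    assert 0 < s.sd_deg < 10 and 0.9 < s.resultant_length <= 1


class TestWithinSubjectCI:
    def test_pure_between_subject_variance_gives_zero(self):
        # participants differ by an offset but are identical across conditions
        y = np.array([[0.0, 0.0], [10.0, 10.0], [-5.0, -5.0]])
        np.testing.assert_allclose(within_subject_ci(y), 0.0, atol=1e-12)

    def test_hand_computed_normalization(self):
        # constant condition effect: normalization removes all participant
        # spread, leaving zero within-condition variance
        y = np.array([[0.0, 10.0], [2.0, 12.0], [4.0, 14.0]])
        np.testing.assert_allclose(within_subject_ci(y), 0.0, atol=1e-12)

    def test_morey_factor_two_conditions(self):
        # with C=2 the corrected variance doubles, so the half-width is
        # sqrt(2) times the uncorrected Cousineau value
        rng = np.random.default_rng(4)
        y = rng.normal(size=(6, 2))
        norm = y - y.mean(axis=1, keepdims=True) + y.mean()
        sem = norm.std(axis=0, ddof=1) / np.sqrt(6)
        expected = stats.t.ppf(0.975, 5) * sem * np.sqrt(2.0)
        np.testing.assert_allclose(within_subject_ci(y), expected, rtol=1e-12)

    def test_missing_cells_rejected(self):
        y = np.array([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError):
            within_subject_ci(y)

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            within_subject_ci(np.zeros((1, 3)))
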