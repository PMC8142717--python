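"""JZS Bayes factors, correlation tests, permutation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from transsaccade import (
    bf_from_t,
    bf_ttest,
    correlation_bf,
    permutation_test,
    within_subject_correlation,
)
from transsaccade.inference import DEFAULT_PRIOR_SCALE


def jzs_oracle(t, n, r=DEFAULT_PRIOR_SCALE):
    """Independent quadrature: noncentral-t likelihood against Cauchy prior."""
    nu = n - 1

    def num(d):
        return stats.nct.pdf(t, nu, d * np.sqrt(n)) * stats.cauchy.pdf(d, 0, r)

    numerator, _ = integrate.quad(num, -np.inf, np.inf, limit=400)
    return numerator / stats.t.pdf(t, nu)


class TestBayesFactor:
    def test_zero_t_favors_null(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        res = bf_ttest(x)
        assert res.t_stat == pytest.approx(0.0)
        assert res.bf10 < 1.0

    def test_frozen_reference_value(self):
        # n=15, t=3.0, r=sqrt(2)/2; value frozen from the quadrature oracle
        assert bf_from_t(3.0, 15) == pytest.approx(5.78405, rel=5e-5)

    def test_symmetry_in_t(self):
        assert bf_from_t(2.7, 12) == pytest.approx(bf_from_t(-2.7, 12), rel=1e-12)

    def test_monotone_in_abs_t(self):
        bfs = [bf_from_t(t, 14) for t in (0.0, 0.5, 1.5, 2.5, 4.0)]
        assert np.all(np.diff(bfs) > 0)

    @pytest.mark.parametrize("t", [0.0, 1.0, 2.5, 4.0])
    @pytest.mark.parametrize("n", [5, 12, 30])
    def test_agrees_with_independent_oracle(self, t, n):
        assert bf_from_t(t, n) == pytest.approx(jzs_oracle(t, n), rel=1e-4)

    @pytest.mark.parametrize("t,n", [(1.5, 8), (3.0, 15), (2.2, 30)])
    def test_agrees_with_pingouin(self, t, n):
        pingouin = pytest.importorskip("pingouin")
        assert bf_from_t(t, n) == pytest.approx(
            float(pingouin.bayesfactor_ttest(t, n, paired=True)), rel=1e-3
        )

    def test_prior_scale_flag(self):
        # wider prior penalizes small effects more
        assert bf_from_t(1.0, 20, prior_scale=1.0) < bf_from_t(1.0, 20, prior_scale=0.5)

    def test_bf01_reciprocal(self):
        res = bf_ttest([0.1, 0.5, -0.2, 0.3, 0.4])
        assert res.bf01 == pytest.approx(1.0 / res.bf10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            bf_ttest([1.0, 1.0, 1.0])


class TestCorrelationBF:
    def test_fisher_transform_closed_form(self):
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_null_correlations_favor_h0(self):
        rng = np.random.default_rng(0)
        r = rng.normal(0, 0.02, 12)
        res = correlation_bf(r)
        assert res.bf01 > 1.0

    def test_consistent_correlations_favor_h1(self):
        rng = np.random.default_rng(1)
        r = 0.5 + rng.normal(0, 0.02, 5)
        assert correlation_bf(r).bf10 > 1.0

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError):
            correlation_bf([0.3, 1.0])

    def test_zero_variance_path(self):
        with pytest.raises(ValueError):
            correlation_bf([0.0, 0.0, 0.0])


class TestWithinSubjectCorrelation:
    @staticmethod
    def _table(rng, n_participants=6, n_trials=40, slope=1.0, noise=0.0):
        rows = []
        for i in range(n_participants):
            x = rng.normal(size=n_trials)
            y = slope * x + noise * rng.normal(size=n_trials)
            rows.append(
                pd.DataFrame({"participant_id": f"P{i}", "x": x, "y": y})
            )
        return pd.concat(rows, ignore_index=True)

    def test_identity_gives_unit_correlation(self):
        t = self._table(np.random.default_rng(2))
        per, mean_r, _ = within_subject_correlation(t, "x", "y")
        np.testing.assert_allclose(per.to_numpy(), 1.0)

    def test_negation_gives_minus_one(self):
        t = self._table(np.random.default_rng(3), slope=-1.0)
        per, mean_r, _ = within_subject_correlation(t, "x", "y")
        np.testing.assert_allclose(per.to_numpy(), -1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(4)
        t = self._table(rng, n_participants=10, n_trials=200, slope=0.0, noise=1.0)
        per, mean_r, sd_r = within_subject_correlation(t, "x", "y")
        assert abs(mean_r) < 3.0 / np.sqrt(10 * 200)

    def test_constant_column_participant_skipped(self):
        t = self._table(np.random.default_rng(5), n_participants=3)
        t.loc[t["participant_id"] == "P0", "x"] = 7.0
        per, _, _ = within_subject_correlation(t, "x", "y")
        assert "P0" not in per.index and len(per) == 2


class TestPermutationTest:
    def test_identical_groups_do_not_exceed(self):
        res = permutation_test(np.ones(10), [True] * 4 + [False] * 6)
        assert res.observed_diff == 0.0
        assert not res.exceeds

    def test_true_group_effect_exceeds_exact_null(self):
        # aware group (4 of 14) sits 100 deg above the unaware group; the
        # exact null over C(14,4)=1001 assignments puts the observed
        # difference beyond its 95th percentile
        rng = np.random.default_rng(11)
        values = rng.normal(0, 1.0, 14)
        values[:4] += 100.0
        labels = np.array([True] * 4 + [False] * 10)
        res = permutation_test(values, labels)
        assert res.method == "exact"
        assert res.n_reps == 1001  # C(14,4) enumerated exactly
        assert res.exceeds

    def test_single_outlier_cannot_exceed(self):
        # a lone extreme aware participant is not detectable: 28.6% of
        # label assignments put the outlier in the aware group, so the
        # observed difference ties the top of its own null
        values = np.zeros(14)
        values[0] = 100.0
        labels = np.array([True] * 4 + [False] * 10)
        res = permutation_test(values, labels)
        assert not res.exceeds

    def test_sampling_path_matches_exact_percentile(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=14)
        labels = np.array([True] * 4 + [False] * 10)
        exact = permutation_test(values, labels, method="exact")
        sampled = permutation_test(values, labels, method="sampling", n_reps=20_000, seed=1)
        assert sampled.n_reps == 20_000
        assert sampled.percentile_95 == pytest.approx(exact.percentile_95, abs=0.08)

    def test_two_sided_flag(self):
        rng = np.random.default_rng(7)
        values = rng.normal(0, 0.5, 12)
        values[:3] -= 10.0  # aware group strongly below the unaware group
        labels = np.array([True] * 3 + [False] * 9)
        one = permutation_test(values, labels)
        two = permutation_test(values, labels, two_sided=True)
        assert not one.exceeds  # observed diff is negative
        assert two.exceeds

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.ones(5), [False] * 5)
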