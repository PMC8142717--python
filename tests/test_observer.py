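"""Generative observer: resource allocation and simulated responses."""

import numpy as np
import pytest
from scipy import special, stats

from transsaccade import ObserverParams, align, circ_mean, circ_sd, simulate_responses
from transsaccade.observer import kappa_pre_for_share, resource_share
from tests.conftest import make_cell_design


def aligned_errors(design, params):
    return align(simulate_responses(design, params))["error_aligned_deg"].to_numpy()


class TestResourceRule:
    def test_share_one_gives_kappa1(self):
        assert kappa_pre_for_share(1.0, 17.0, 1.3) == pytest.approx(17.0)

    def test_no_cue_share_is_one_over_n(self):
        share = resource_share([1, 2, 4], ["none", "none", "no_cue"], [False] * 3, 0.6)
        np.testing.assert_allclose(share, [1.0, 0.5, 0.25])

    def test_cue_allocation(self):
        share = resource_share([4, 4], ["valid", "invalid"], [True, False], 0.55)
        np.testing.assert_allclose(share, [0.55, 0.15])

    def test_quarter_cue_reproduces_no_cue_allocation(self):
        cued = resource_share([4, 4], ["valid", "invalid"], [True, False], 0.25)
        np.testing.assert_allclose(cued, [0.25, 0.25])

    @pytest.mark.parametrize(
        "kwargs", [{"kappa1": -1}, {"lapse": 1.2}, {"p_cue": 0.1}, {"kappa_post": np.nan}]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ObserverParams(**kwargs).validate()


class TestSimulatedResponses:
    def test_infinitely_reliable_pre_view_pins_responses_to_pre_color(self):
        d = make_cell_design(4000, seed=5)
        p = ObserverParams(kappa1=1e6, alpha=0.0, kappa_post=4.0, lapse=0.0, seed=1)
        err = aligned_errors(d, p)
        assert abs(circ_mean(err)[0]) < 0.05
        assert np.abs(err).max() < 1.0

    def test_equal_reliabilities_split_the_discrepancy(self):
        d = make_cell_design(50_000, seed=6)
        p = ObserverParams(kappa1=8.0, alpha=1.0, kappa_post=8.0, lapse=0.0, seed=2)
        err = aligned_errors(d, p)
        assert circ_mean(err)[0] == pytest.approx(12.5, abs=0.4)

    def test_pre_only_sd_matches_mixture_quadrature_oracle(self):
        # circular SD of the 0.95 VM(kappa=8) + 0.05 uniform mixture,
        # evaluated by quadrature of the mixture's first circular moment
        kappa, lapse = 8.0, 0.05
        theta = np.linspace(-np.pi, np.pi, 20_001)
        vm = np.exp(kappa * np.cos(theta)) / (2 * np.pi * special.i0(kappa))
        dens = (1 - lapse) * vm + lapse / (2 * np.pi)
        rbar = np.trapezoid(dens * np.cos(theta), theta)  # sine term vanishes
        oracle_sd = np.degrees(np.sqrt(-2 * np.log(rbar)))

        d = make_cell_design(50_000, seed=7, presentation="pre_only")
        p = ObserverParams(kappa1=kappa, alpha=1.0, kappa_post=8.0, lapse=lapse, seed=3)
        sd = circ_sd(aligned_errors(d, p))
        assert sd == pytest.approx(oracle_sd, abs=0.7)

    def test_post_only_distribution_ignores_cue_condition(self):
        p = ObserverParams(kappa1=10.0, kappa_post=6.0, lapse=0.0, seed=4)
        errs = {}
        for cue, is_cued in [("valid", True), ("no_cue", False)]:
            d = make_cell_design(
                8000, seed=8, set_size=4, cue_condition=cue,
                presentation="post_only", probed_is_cued=is_cued,
            )
            errs[cue] = aligned_errors(d, p)
        assert stats.ks_2samp(errs["valid"], errs["no_cue"]).pvalue > 0.01

    def test_quarter_cue_makes_conditions_indistinguishable(self):
        p = ObserverParams(kappa1=10.0, alpha=1.0, p_cue=0.25, kappa_post=4.0, lapse=0.0, seed=5)
        errs = {}
        for cue, is_cued in [("valid", True), ("invalid", False), ("no_cue", False)]:
            d = make_cell_design(
                8000, seed=9, set_size=4, cue_condition=cue, probed_is_cued=is_cued
            )
            errs[cue] = aligned_errors(d, p)
        assert stats.ks_2samp(errs["valid"], errs["no_cue"]).pvalue > 0.01
        assert stats.ks_2samp(errs["invalid"], errs["no_cue"]).pvalue > 0.01

    def test_post_only_residual_pre_trace_flag(self):
        # default: POST-only reports come from the post view alone (mean at
        # +25); with post_only_pure=False the pre-saccadic trace is
        # integrated and pulls the mean back toward 0
        d = make_cell_design(20_000, seed=10, set_size=1, presentation="post_only")
        pure = ObserverParams(kappa1=8.0, kappa_post=8.0, lapse=0.0, seed=6)
        mixed = ObserverParams(
            kappa1=8.0, kappa_post=8.0, lapse=0.0, seed=6, post_only_pure=False
        )
        assert circ_mean(aligned_errors(d, pure))[0] == pytest.approx(25.0, abs=0.6)
        assert circ_mean(aligned_errors(d, mixed))[0] == pytest.approx(12.5, abs=0.6)

    def test_reproducible_from_seed(self, exp1_design):
        p = ObserverParams(seed=42)
        a = simulate_responses(exp1_design, p)["response_deg"]
        b = simulate_responses(exp1_design, p)["response_deg"]
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_non_finite_parameters_rejected(self, exp1_design):
        with pytest.raises(ValueError):
            simulate_responses(exp1_design, ObserverParams(kappa1=np.inf))
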