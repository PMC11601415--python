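"""Drift-diffusion closed forms, the ballistic approximation, the
run-and-tumble simulator, and the drift/diffusion estimator chain."""

import math

import numpy as np
import pytest

from isingdm import (
    DDMParams,
    ModelParams,
    RnTParams,
    ballistic_rt,
    ddm_error,
    ddm_rt,
    ddm_rt_ratio,
    estimate_drift_diffusion,
    pe_from_error,
    rnt_first_passage,
    simulate_ensemble_arrays,
    simulate_trial,
)
from isingdm.ddm import ddm_rt_driftless
from isingdm.stats import summarize

SEED = 555


class TestClosedForms:
    def test_error_of_zero_peclet_is_half(self):
        assert ddm_error(0.0) == pytest.approx(0.5)

    def test_error_vanishes_at_large_peclet(self):
        assert ddm_error(50.0) < 1e-20
        assert ddm_error(-50.0) == pytest.approx(1.0, abs=1e-20)

    def test_error_inversion(self):
        assert pe_from_error(0.09) == pytest.approx(math.log(1 / 0.09 - 1))
        assert ddm_error(pe_from_error(0.09)) == pytest.approx(0.09, abs=1e-14)
        assert pe_from_error(0.09) == pytest.approx(2.3136, abs=1e-4)

    def test_rt_ballistic_limit(self):
        # Pe -> infinity at fixed v, L: tanh -> 1 so RT -> L/v
        assert ddm_rt(v=0.2, L=4.0, Pe=200.0) == pytest.approx(20.0, rel=1e-12)

    def test_rt_driftless_limit(self):
        # v -> 0 at fixed D, L: RT -> L^2/(2D); approach it through Pe = vL/D
        D, L = 0.5, 3.0
        limit = ddm_rt_driftless(L, D)
        assert limit == pytest.approx(L * L / (2 * D))
        for v in (1e-3, 1e-5):
            assert ddm_rt(v, L, v * L / D) == pytest.approx(limit, rel=1e-4)

    def test_params_peclet_consistency(self):
        p = DDMParams(v=0.3, D=0.15, L=2.0)
        assert p.Pe == pytest.approx(0.3 * 2.0 / 0.15)
        with pytest.raises(ValueError):
            DDMParams(v=0.1, D=0.0, L=1.0)


class TestRTRatio:
    def test_equal_errors_give_unity(self):
        assert ddm_rt_ratio(0.2, 0.2) == pytest.approx(1.0)

    def test_observed_error_pair(self):
        """The gain/loss error rates 0.09 and 0.24 fix the analytic RT
        ratio; frozen value from independent evaluation of the closed form:
        (1-2*0.09)*ln(1/0.24-1) / ((1-2*0.24)*ln(1/0.09-1)) = 0.7856412."""
        assert ddm_rt_ratio(0.09, 0.24) == pytest.approx(0.7856412, abs=1e-6)

    @pytest.mark.parametrize("pair", [(0.05, 0.3), (0.12, 0.45), (0.49, 0.01)])
    def test_antisymmetry(self, pair):
        a, b = pair
        assert ddm_rt_ratio(a, b) * ddm_rt_ratio(b, a) == pytest.approx(1.0)

    def test_half_error_handled_as_driftless_limit(self):
        r = ddm_rt_ratio(0.5, 0.24)
        # numerator is the driftless RT at unit D, L
        assert r == pytest.approx(0.5 / (math.tanh(pe_from_error(0.24) / 2)
                                         / pe_from_error(0.24)))

    def test_matches_ratio_of_explicit_rts(self):
        """Internal consistency: the error-rate formula equals the ratio of
        two mean RTs computed from (v, D, L) with the matched drifts."""
        D, L = 0.7, 3.0
        for ea, eb in [(0.09, 0.24), (0.03, 0.4)]:
            va = pe_from_error(ea) * D / L
            vb = pe_from_error(eb) * D / L
            explicit = ddm_rt(va, L, va * L / D) / ddm_rt(vb, L, vb * L / D)
            assert ddm_rt_ratio(ea, eb) == pytest.approx(explicit, rel=1e-12)

    def test_degenerate_errors_rejected(self):
        for bad in (0.0, 1.0):
            with pytest.raises(ValueError):
                ddm_rt_ratio(bad, 0.2)


class TestBallistic:
    def test_unbiased_ratio_is_unity(self):
        _, _, ratio = ballistic_rt(ModelParams(T=0.1, eta=0.0, N=100, L=5.0))
        assert ratio == pytest.approx(1.0, abs=1e-9)

    def test_bias_makes_correct_faster(self):
        rt_p, rt_m, ratio = ballistic_rt(
            ModelParams(T=0.1, eta=0.0, eps1=0.05, N=100, L=5.0)
        )
        assert rt_p < rt_m
        assert ratio < 1.0

    def test_disordered_phase_is_an_explicit_failure(self):
        with pytest.raises(ValueError, match="disordered"):
            ballistic_rt(ModelParams(T=0.45, eta=0.65, N=100, L=5.0))


class TestRnT:
    def test_rate_only_bias_keeps_correct_wrong_ratio_at_one(self):
        """Tumble-rate asymmetry biases the outcome but leaves the mean
        RTs of correct and wrong decisions equal."""
        p = RnTParams(v_plus=1.0, v_minus=1.0, k_plus=0.7, k_minus=1.3, L=5.0)
        s = summarize(rnt_first_passage(p, 6000, seed=SEED))
        assert s.error_rate < 0.5  # biased toward the positive threshold
        n_w = s.n_wrong
        se_ratio = s.rt_ratio_cw * math.sqrt(1.0 / s.n_correct + 1.0 / n_w)
        assert abs(s.rt_ratio_cw - 1.0) < 4 * se_ratio

    def test_speed_bias_makes_correct_faster(self):
        p = RnTParams(v_plus=2.0, v_minus=1.0, k_plus=1.0, k_minus=1.0, L=5.0)
        s = summarize(rnt_first_passage(p, 6000, seed=SEED))
        assert s.rt_ratio_cw < 0.97

    def test_symmetric_walk_splits_evenly(self):
        p = RnTParams(v_plus=1.0, v_minus=1.0, k_plus=1.0, k_minus=1.0, L=3.0)
        s = summarize(rnt_first_passage(p, 4000, seed=SEED))
        assert abs(s.error_rate - 0.5) < 3 * math.sqrt(0.25 / 4000)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RnTParams(v_plus=0.0, v_minus=1.0, k_plus=1.0, k_minus=1.0, L=1.0)


class TestEstimatorChain:
    def test_disordered_ensemble_reproduces_error_peclet_relation(self):
        """Oracle chain: estimate (v, D) from threshold-free paths, predict
        the error from the Peclet closed form, compare with the simulated
        error rate at absorbing thresholds (within 3 binomial SE plus the
        estimator's own uncertainty)."""
        p = ModelParams(T=0.45, eta=0.65, eps1=0.02, N=100, L=2.0)
        trajs = []
        free = p.replace(L=1000.0)
        for i in range(40):
            _, tr = simulate_trial(free, seed=2000 + i, max_time=400.0, record=True)
            trajs.append(tr)
        v, D = estimate_drift_diffusion(trajs, lag=30.0)
        predicted = ddm_error(v * p.L / D)
        dec, rts, _, _ = simulate_ensemble_arrays(p, 6000, seed=SEED)
        s = summarize((dec, rts))
        se = math.sqrt(s.error_rate * (1 - s.error_rate) / s.n_decided)
        assert abs(predicted - s.error_rate) < 3 * se + 0.02

    def test_estimator_recovers_known_drift(self):
        """The drift estimate agrees with the direct time-average
        displacement rate of the decision variable."""
        p = ModelParams(T=0.45, eta=0.65, eps1=0.02, N=100, L=1000.0)
        trajs = []
        for i in range(20):
            _, tr = simulate_trial(p, seed=4000 + i, max_time=400.0, record=True)
            trajs.append(tr)
        v, D = estimate_drift_diffusion(trajs, lag=25.0)
        # direct time-average of DV displacement per unit time
        direct = np.mean([tr.dv_path[-1] / tr.event_times[-1] for tr in trajs])
        assert v == pytest.approx(direct, abs=0.003)
        assert D > 0
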