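"""Stochastic-simulation contracts: reproducibility, trajectory geometry,
waiting-time statistics, symmetry, and agreement with mean-field theory."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from isingdm import (
    ModelParams,
    ballistic_rt,
    mf_solutions,
    simulate_ensemble,
    simulate_trial,
    stationary_velocity_histogram,
)
from isingdm.gillespie import child_seed
from isingdm.stats import summarize

SEED = 1234


class TestReproducibility:
    def test_same_seed_identical_ensembles(self):
        p = ModelParams(T=0.3, eta=0.2, eps1=0.02, N=50, L=1.0)
        a = simulate_ensemble(p, 50, seed=SEED)
        b = simulate_ensemble(p, 50, seed=SEED)
        assert a == b

    def test_single_trial_matches_ensemble_member(self):
        p = ModelParams(T=0.3, eta=0.2, eps1=0.02, N=50, L=1.0)
        ens = simulate_ensemble(p, 3, seed=SEED)
        solo = simulate_trial(p, seed=child_seed(SEED, 1))
        assert ens[1] == solo

    def test_child_seed_depends_only_on_master_and_index(self):
        assert child_seed(7, 3) == child_seed(7, 3)
        assert child_seed(7, 3) != child_seed(7, 4)
        assert child_seed(7, 3) != child_seed(8, 3)


class TestTrajectoryGeometry:
    def test_event_times_and_linear_integration(self):
        p = ModelParams(T=0.29, eta=0.44, eps1=0.01, N=100, L=2.0)
        result, traj = simulate_trial(p, seed=SEED, record=True)
        t, v, dv = traj.event_times, traj.v_path, traj.dv_path
        assert np.all(np.diff(t) > 0)
        assert np.all(np.abs(dv) <= p.L + 1e-12)
        # between events the integrator advances linearly at the held V
        dt = np.diff(t)
        # v_path[i] is V after event i and holds until event i+1
        np.testing.assert_allclose(np.diff(dv), v[:-1] * dt, rtol=1e-9, atol=1e-12)
        assert dv[-1] == pytest.approx(result.decision * p.L)
        assert result.rt == pytest.approx(t[-1])
        assert result.rt > 0

    def test_velocity_steps_are_single_flips(self):
        p = ModelParams(T=0.4, eta=0.3, N=40, L=5.0)
        _, traj = simulate_trial(p, seed=SEED, record=True, max_time=50.0)
        steps = np.abs(np.diff(traj.v_path))
        # skip the final absorbing record (repeats the held V)
        assert np.all((steps[:-1] > 0) | (steps[:-1] == 0))
        assert np.all(steps <= 1.0 / p.N + 1e-12)

    def test_timeout_flagged_with_capped_rt(self):
        p = ModelParams(T=0.4, eta=0.6, N=100, L=50.0)
        r = simulate_trial(p, seed=SEED, max_time=5.0)
        assert r.decision == 0
        assert r.rt == 5.0


class TestWaitingTimes:
    def test_exponential_waiting_times_at_constant_propensity(self):
        """At very high temperature every rate is 1/2, so the total
        propensity is N/2 at every state and waiting times must be iid
        exponential with that rate (KS test at alpha = 0.01)."""
        N = 20
        p = ModelParams(T=1e6, eta=0.0, N=N, L=1e9)
        _, traj = simulate_trial(p, seed=SEED, record=True, max_time=400.0)
        waits = np.diff(traj.event_times)
        assert waits.size > 1500
        ks = sp_stats.kstest(waits, "expon", args=(0.0, 2.0 / N))
        assert ks.pvalue > 0.01


class TestSymmetryAndMeanField:
    def test_unbiased_decisions_split_evenly(self):
        p = ModelParams(T=0.4, eta=0.6, N=100, L=1.0)
        results = simulate_ensemble(p, 4000, seed=SEED)
        dec = np.array([r.decision for r in results])
        assert np.all(dec != 0)
        frac_pos = np.mean(dec == 1)
        se = np.sqrt(0.25 / dec.size)
        assert abs(frac_pos - 0.5) < 3 * se

    @pytest.mark.parametrize(
        "T, eta",
        [(0.3, 0.05), (0.15, 0.45), (0.4, 0.6)],
        ids=["ordered", "intermittent", "disordered"],
    )
    def test_velocity_histogram_peaks_at_mean_field_solutions(self, T, eta):
        """Every detected histogram peak of the stationary velocity lies
        within 1.5 bin widths of a stable mean-field velocity."""
        p = ModelParams(T=T, eta=eta, N=100)
        bins = 51
        dens_acc = None
        for k in range(4):
            centers, dens = stationary_velocity_histogram(
                p, total_time=800.0, seed=SEED + k, bins=bins, burn_in=20.0
            )
            dens_acc = dens if dens_acc is None else dens_acc + dens
        dens = dens_acc / 4
        bw = centers[1] - centers[0]
        stable = mf_solutions(p).stable_velocities
        interior = slice(1, -1)
        is_peak = (
            (dens[interior] >= dens[:-2])
            & (dens[interior] >= dens[2:])
            & (dens[interior] > 0.2 * dens.max())
        )
        peak_positions = centers[interior][is_peak]
        assert peak_positions.size >= 1
        for v_peak in peak_positions:
            assert np.min(np.abs(stable - v_peak)) < 1.5 * bw

    def test_ordered_phase_velocity_concentrates_at_pair(self):
        """Unbiased ordered-phase runs: the signed time-average velocity of
        a single run sits near one of the two mean-field values, while the
        ensemble-average velocity vanishes."""
        p = ModelParams(T=0.3, eta=0.05, N=100)
        vp = mf_solutions(p).positive_stable()
        means = []
        for k in range(12):
            centers, dens = stationary_velocity_histogram(
                p, total_time=300.0, seed=3000 + k, bins=101, burn_in=20.0
            )
            bw = centers[1] - centers[0]
            means.append(float(np.sum(centers * dens) * bw))
        means = np.array(means)
        np.testing.assert_allclose(np.abs(means), vp, atol=0.05)
        assert abs(means.mean()) < vp  # branches of both signs occur


class TestBallisticRegime:
    def test_deep_ordered_rt_matches_ballistic_prediction(self):
        """At T=0.05 the motion is ballistic; with a threshold long enough
        to dominate the onset transient, the +1-conditioned mean RT matches
        L/V+ to within 5%."""
        p = ModelParams(T=0.05, eta=0.0, eps1=0.01, N=100, L=20.0)
        rt_plus, _, _ = ballistic_rt(p)
        results = simulate_ensemble(p, 800, seed=SEED)
        s = summarize([r for r in results])
        assert abs(s.rt_correct_mean - rt_plus) / rt_plus < 0.05

    def test_onset_transient_is_an_additive_delay(self):
        """The all-off start needs ~1 rate unit for the winning group to
        charge up, so RT(L) = delay + L/V* with an L-independent delay."""
        delays = []
        for L in (5.0, 10.0):
            p = ModelParams(T=0.05, eta=0.0, N=100, L=L)
            rt_plus, _, _ = ballistic_rt(p)
            s = summarize(simulate_ensemble(p, 500, seed=SEED))
            delays.append(s.rt_correct_mean - rt_plus)
        assert delays[0] == pytest.approx(delays[1], abs=0.2)
        assert 0.5 < delays[0] < 2.0
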