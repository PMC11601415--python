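"""Drift-diffusion and run-and-tumble analytics for the decision variable.

In the disordered phase the decision variable performs driven Brownian
motion between symmetric absorbing thresholds, i.e. the classical
drift-diffusion model (DDM).  With drift ``v``, diffusion coefficient ``D``
and threshold ``L``, everything depends on the Peclet number
``Pe = v L / D``:

    Error = 1 / (e^Pe + 1)
    RT = RT_correct = RT_wrong = (L / v) tanh(Pe / 2)

At matched ``D`` and ``L``, the ratio of mean reaction times of two
conditions is a closed function of their error rates alone:

    RT_a / RT_b = (1 - 2 Err_a) ln(1/Err_b - 1) / [(1 - 2 Err_b) ln(1/Err_a - 1)]

Deep in the ordered phase the motion is ballistic instead, with
``RT_bal(+/-) = L / |V_mf(+/-)|`` and a correct/wrong ratio
``|V_mf(-)| / V_mf(+)``.  Between the two, near the transition line, the
velocity telegraphs between the two mean-field values: run-and-tumble
motion, for which a minimal exact event-driven simulator is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gillespie import TrialResult, Trajectory, child_seed
from .meanfield import mf_solutions
from .model import ModelParams

__all__ = [
    "DDMParams",
    "RnTParams",
    "ddm_error",
    "ddm_rt",
    "ddm_rt_ratio",
    "pe_from_error",
    "ballistic_rt",
    "rnt_first_passage",
    "estimate_drift_diffusion",
]


@dataclass(frozen=True)
class DDMParams:
    """Drift-diffusion parameters; ``Pe`` is derived, never stored stale."""

    v: float
    D: float
    L: float

    def __post_init__(self) -> None:
        if self.D <= 0 or self.L <= 0:
            raise ValueError("require D > 0 and L > 0")

    @property
    def Pe(self) -> float:
        return self.v * self.L / self.D


@dataclass(frozen=True)
class RnTParams:
    """Telegraph (run-and-tumble) motion between symmetric thresholds.

    The particle runs at ``+v_plus`` (toward the positive threshold) or
    ``-v_minus``; while running toward +L it switches direction at rate
    ``k_plus``, and while running toward -L at rate ``k_minus``.
    """

    v_plus: float
    v_minus: float
    k_plus: float
    k_minus: float
    L: float

    def __post_init__(self) -> None:
        if self.v_plus <= 0 or self.v_minus <= 0:
            raise ValueError("run speeds must be positive")
        if self.k_plus < 0 or self.k_minus < 0:
            raise ValueError("tumble rates must be >= 0")
        if self.L <= 0:
            raise ValueError("threshold must be positive")


def ddm_error(Pe: float) -> float:
    """Probability of absorption at the wrong (negative) threshold."""
    if not math.isfinite(Pe):
        raise ValueError("Pe must be finite")
    # stable for large |Pe|
    if Pe >= 0:
        return math.exp(-Pe) / (1.0 + math.exp(-Pe))
    return 1.0 / (1.0 + math.exp(Pe))


def pe_from_error(error: float) -> float:
    """Inverse of :func:`ddm_error`: ``Pe = ln(1/error - 1)``."""
    if not 0.0 < error < 1.0:
        raise ValueError("error must lie strictly between 0 and 1")
    return math.log(1.0 / error - 1.0)


def ddm_rt(v: float, L: float, Pe: float) -> float:
    """Mean reaction time ``(L/v) tanh(Pe/2)``; equal for correct and wrong.

    The driftless limit is taken analytically: as ``v -> 0`` at fixed D and
    L (i.e. ``Pe -> 0`` with ``v = Pe D / L``), the mean first-passage time
    tends to ``L^2 / (2 D)``, the standard unbiased diffusion result.
    """
    if L <= 0:
        raise ValueError("threshold must be positive")
    if v == 0.0 or Pe == 0.0:
        if v == 0.0 and Pe == 0.0:
            raise ValueError(
                "driftless limit needs D: use ddm_rt_driftless(L, D) instead"
            )
        # one of them zero but not the other is inconsistent
        raise ValueError("v and Pe must vanish together (Pe = vL/D)")
    return (L / v) * math.tanh(Pe / 2.0)


def ddm_rt_driftless(L: float, D: float) -> float:
    """Mean first-passage time of unbiased diffusion: ``L^2 / (2 D)``."""
    if L <= 0 or D <= 0:
        raise ValueError("require L > 0 and D > 0")
    return L * L / (2.0 * D)


def ddm_rt_ratio(error_a: float, error_b: float) -> float:
    """Ratio RT_a / RT_b of two DDM conditions at matched D and L.

    Each condition's drift is set by its error rate; the ratio then depends
    on the two error rates only.  Error rates of exactly 1/2 are handled by
    the analytic limit ``(1 - 2 Err) -> 2 Pe / ...``: substituting
    ``tanh(Pe/2) ~ Pe/2`` gives RT -> L^2/(2D), so a 0.5-error condition
    contributes the driftless mean first-passage time.
    """
    for e in (error_a, error_b):
        if not 0.0 < e < 1.0:
            raise ValueError(f"error rate {e} must lie strictly in (0, 1)")
    rt_a = _ddm_rt_unit(error_a)
    rt_b = _ddm_rt_unit(error_b)
    return rt_a / rt_b


def _ddm_rt_unit(error: float) -> float:
    """Mean RT at unit D and L as a function of the error rate.

    ``RT = (L^2/D) tanh(Pe/2)/Pe`` with ``tanh(Pe/2) = (1-2*Err)/...``;
    continuous at Err = 1/2 where it equals 1/2 (the driftless value).
    """
    Pe = pe_from_error(error)
    if Pe == 0.0:
        return 0.5
    return math.tanh(Pe / 2.0) / Pe


def ballistic_rt(params: ModelParams) -> tuple[float, float, float]:
    """Ballistic reaction times ``L / |V_mf|`` and their correct/wrong ratio.

    Uses the biased mean-field velocities; valid deep in the ordered phase
    where trials run near-ballistically to a threshold.  Returns
    ``(RT_plus, RT_minus, RT_plus / RT_minus)``; the ratio equals
    ``|V_mf(-)| / V_mf(+)``, which is 1 without bias and < 1 for a positive
    bias toward the correct option.
    """
    sols = mf_solutions(params)
    v_plus = sols.positive_stable()
    v_minus = sols.negative_stable()
    if v_plus is None or v_minus is None:
        raise ValueError(
            "no nonzero stable mean-field pair (disordered phase): "
            "the ballistic approximation does not apply"
        )
    rt_plus = params.L / abs(v_plus)
    rt_minus = params.L / abs(v_minus)
    return rt_plus, rt_minus, abs(v_minus) / v_plus


def rnt_first_passage(
    params: RnTParams, n_trials: int, seed: int, max_time: float = 1e6
) -> list[TrialResult]:
    """Exact event-driven telegraph first-passage simulation.

    The particle starts at 0 with a fair random initial direction, runs at
    constant speed, and tumbles (reverses) instantaneously at the
    direction-dependent rate.  Returns the same trial records as the spin
    simulator; decision +1 at +L, -1 at -L, 0 on timeout.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    results = []
    for i in range(n_trials):
        cseed = child_seed(int(seed), i)
        rng = np.random.default_rng(cseed)
        x = 0.0
        t = 0.0
        up = bool(rng.random() < 0.5)  # True: moving toward +L
        n_events = 0
        decision, rt = 0, max_time
        while t < max_time:
            v = params.v_plus if up else -params.v_minus
            k = params.k_plus if up else params.k_minus
            run = rng.exponential(1.0 / k) if k > 0 else math.inf
            # crossing during this run?
            target = params.L if up else -params.L
            t_cross = (target - x) / v
            if t_cross <= run:
                if t + t_cross <= max_time:
                    decision = 1 if up else -1
                    rt = t + t_cross
                break
            if t + run >= max_time:
                x += v * (max_time - t)
                break
            t += run
            x += v * run
            up = not up
            n_events += 1
        results.append(
            TrialResult(decision=decision, rt=float(rt), n_events=n_events, seed=cseed)
        )
    return results


def estimate_drift_diffusion(
    trajectories: list[Trajectory] | Trajectory,
    lag: float = 25.0,
) -> tuple[float, float]:
    """Estimate (v, D) of the decision variable from event-resolved paths.

    The decision variable is sampled on a uniform grid of spacing ``lag``
    (piecewise-linear interpolation between events, exact because V is
    constant between events); the drift is the mean increment per unit time
    and the diffusion coefficient half the increment variance per unit
    time.  Use threshold-free trajectories to avoid absorption bias.

    The lag must sit well beyond the velocity autocorrelation time — of
    order ``1/(1 - slope)`` relaxation units, i.e. several tens of rate
    units near the transition — otherwise the temporally correlated
    velocity makes the increments sub-diffusive and D comes out low.  The
    default of 25 rate units is adequate in the disordered phase at
    moderate distance from the line; verify convergence by doubling the
    lag when in doubt.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    increments = []
    for traj in trajectories:
        t = traj.event_times
        if t.size < 2 or t[-1] < 2 * lag:
            continue
        grid = np.arange(0.0, t[-1], lag)
        dv = np.interp(grid, t, traj.dv_path)
        increments.append(np.diff(dv))
    if not increments:
        raise ValueError("no trajectory long enough for the requested lag")
    inc = np.concatenate(increments)
    v_hat = float(inc.mean() / lag)
    d_hat = float(inc.var(ddof=1) / (2.0 * lag))
    return v_hat, d_hat
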