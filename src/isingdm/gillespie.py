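"""Exact event-driven (Gillespie) simulation of the decision dynamics.

Four reaction channels — a spin turning on or off in either group — with
propensities ``(N0_I r_on_I, N1_I r_off_I, N0_II r_on_II, N1_II r_off_II)``.
Waiting times are exponential in the total propensity and the channel is
chosen proportionally.  Between events the decision-variable velocity
``V = (n_on_I - n_on_II)/N`` is constant, so the decision variable advances
linearly and a threshold crossing inside the waiting interval is resolved at
the exact linear crossing time.

Trials start from every spin "off" (``n_on_I = n_on_II = 0``) and the
decision variable at 0, and end at the first crossing of ``+L`` (decision
+1, the favored option when ``eps1 > 0``) or ``-L`` (decision -1), or at
``max_time`` (decision 0, a flagged timeout).

Because ``V`` takes only ``N + 1`` discrete values, the four per-spin rates
are precomputed into lookup tables indexed by the group-count difference,
which keeps the event loop free of transcendental calls.  Reproducibility
contract: trial ``i`` of an ensemble is driven by a child seed derived from
``(master_seed, i)`` alone, so ensembles are order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from numpy.random import SeedSequence

from .model import ModelParams

__all__ = [
    "TrialResult",
    "Trajectory",
    "simulate_trial",
    "simulate_ensemble",
    "simulate_ensemble_arrays",
    "stationary_velocity_histogram",
]

DEFAULT_MAX_TIME = 1e6
#: ensembles whose timeout fraction exceeds this trigger a warning
TIMEOUT_WARN_FRACTION = 1e-3


@dataclass(frozen=True)
class TrialResult:
    """Outcome of a single simulated decision."""

    decision: int  # +1 (positive threshold), -1 (negative), 0 (timeout)
    rt: float  # reaction time in rate units (== max_time for timeouts)
    n_events: int  # number of spin flips before the decision
    seed: int  # child seed that drove this trial


@dataclass(frozen=True)
class Trajectory:
    """Event-resolved record of one trial."""

    event_times: np.ndarray  # strictly increasing, starts at 0
    v_path: np.ndarray  # V after each event
    dv_path: np.ndarray  # decision variable at each event time


def rate_tables(params: ModelParams):
    """Per-spin flip rates for every reachable velocity, as lookup tables.

    Index ``k`` corresponds to a group-count difference ``d = k - N/2``,
    i.e. velocity ``V = d / N``.
    """
    half = params.half_n
    d = np.arange(-half, half + 1, dtype=np.float64)
    V = d / params.N
    T = params.T
    xI = (2.0 * V - params.eta + params.eps1) / T
    xII = (-2.0 * V - params.eta + params.eps2) / T
    with np.errstate(over="ignore"):
        r_on_I = _stable_logistic(xI) * params.rate_unit
        r_on_II = _stable_logistic(xII) * params.rate_unit
    return (
        r_on_I,
        params.rate_unit - r_on_I,
        r_on_II,
        params.rate_unit - r_on_II,
    )


def _stable_logistic(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    z = np.exp(x[~pos])
    out[~pos] = z / (1.0 + z)
    return out


@njit(cache=False)
def _trial_kernel(ron1, roff1, ron2, roff2, half, N, L, max_time, seed):
    np.random.seed(seed)
    n1 = 0
    n2 = 0
    t = 0.0
    dv = 0.0
    n_events = 0
    while True:
        d = n1 - n2
        V = d / N
        idx = d + half
        a1 = (half - n1) * ron1[idx]
        a2 = n1 * roff1[idx]
        a3 = (half - n2) * ron2[idx]
        a4 = n2 * roff2[idx]
        A = a1 + a2 + a3 + a4
        if A <= 0.0:
            # frozen configuration: V stays constant forever
            if V > 0.0:
                tc = t + (L - dv) / V
                if tc <= max_time:
                    return 1, tc, n_events
            elif V < 0.0:
                tc = t + (-L - dv) / V
                if tc <= max_time:
                    return -1, tc, n_events
            return 0, max_time, n_events
        dt = -np.log(np.random.random()) / A
        if V > 0.0:
            tc = (L - dv) / V
            if tc <= dt:
                if t + tc <= max_time:
                    return 1, t + tc, n_events
                return 0, max_time, n_events
        elif V < 0.0:
            tc = (-L - dv) / V
            if tc <= dt:
                if t + tc <= max_time:
                    return -1, t + tc, n_events
                return 0, max_time, n_events
        if t + dt >= max_time:
            return 0, max_time, n_events
        t += dt
        dv += V * dt
        r = np.random.random() * A
        if r < a1:
            n1 += 1
        elif r < a1 + a2:
            n1 -= 1
        elif r < a1 + a2 + a3:
            n2 += 1
        else:
            n2 -= 1
        n_events += 1


@njit(cache=False)
def _ensemble_kernel(
    ron1, roff1, ron2, roff2, half, N, L, max_time, seeds, decisions, rts, nev
):
    for i in range(seeds.size):
        dec, rt, ne = _trial_kernel(
            ron1, roff1, ron2, roff2, half, N, L, max_time, seeds[i]
        )
        decisions[i] = dec
        rts[i] = rt
        nev[i] = ne


@njit(cache=False)
def _record_kernel(
    ron1, roff1, ron2, roff2, half, N, L, max_time, seed, times, vpath, dvpath
):
    """Like _trial_kernel but records state after every event.

    Returns (decision, rt, n_events); the decision time/state is appended
    as the final record.  Recording stops with an error code (-2) if the
    preallocated capacity is exhausted.
    """
    np.random.seed(seed)
    cap = times.size
    n1 = 0
    n2 = 0
    t = 0.0
    dv = 0.0
    n_events = 0
    k = 0
    times[k] = 0.0
    vpath[k] = 0.0
    dvpath[k] = 0.0
    k += 1
    while True:
        d = n1 - n2
        V = d / N
        idx = d + half
        a1 = (half - n1) * ron1[idx]
        a2 = n1 * roff1[idx]
        a3 = (half - n2) * ron2[idx]
        a4 = n2 * roff2[idx]
        A = a1 + a2 + a3 + a4
        if A <= 0.0:
            if V > 0.0 and t + (L - dv) / V <= max_time:
                tc = t + (L - dv) / V
                if k < cap:
                    times[k] = tc
                    vpath[k] = V
                    dvpath[k] = L
                    k += 1
                return 1, tc, n_events, k
            if V < 0.0 and t + (-L - dv) / V <= max_time:
                tc = t + (-L - dv) / V
                if k < cap:
                    times[k] = tc
                    vpath[k] = V
                    dvpath[k] = -L
                    k += 1
                return -1, tc, n_events, k
            return 0, max_time, n_events, k
        dt = -np.log(np.random.random()) / A
        if V > 0.0:
            tc = (L - dv) / V
            if tc <= dt:
                if t + tc <= max_time:
                    if k < cap:
                        times[k] = t + tc
                        vpath[k] = V
                        dvpath[k] = L
                        k += 1
                    return 1, t + tc, n_events, k
                return 0, max_time, n_events, k
        elif V < 0.0:
            tc = (-L - dv) / V
            if tc <= dt:
                if t + tc <= max_time:
                    if k < cap:
                        times[k] = t + tc
                        vpath[k] = V
                        dvpath[k] = -L
                        k += 1
                    return -1, t + tc, n_events, k
                return 0, max_time, n_events, k
        if t + dt >= max_time:
            return 0, max_time, n_events, k
        t += dt
        dv += V * dt
        r = np.random.random() * A
        if r < a1:
            n1 += 1
        elif r < a1 + a2:
            n1 -= 1
        elif r < a1 + a2 + a3:
            n2 += 1
        else:
            n2 -= 1
        n_events += 1
        if k >= cap:
            return -2, t, n_events, k
        times[k] = t
        vpath[k] = (n1 - n2) / N
        dvpath[k] = dv
        k += 1


def child_seed(master_seed: int, trial_index: int) -> int:
    """Counter-based child-seed derivation: depends only on (master, index)."""
    return int(SeedSequence(master_seed, spawn_key=(trial_index,)).generate_state(1)[0])


def _child_seeds(master_seed: int, n: int, offset: int = 0) -> np.ndarray:
    return np.array(
        [child_seed(master_seed, offset + i) for i in range(n)], dtype=np.int64
    )


def simulate_trial(
    params: ModelParams,
    seed: int,
    max_time: float = DEFAULT_MAX_TIME,
    record: bool = False,
    record_capacity: int | None = None,
):
    """Run one decision trial; optionally record the event-resolved path.

    Returns a :class:`TrialResult`, or ``(TrialResult, Trajectory)`` when
    ``record`` is true.
    """
    if max_time <= 0:
        raise ValueError("max_time must be positive")
    seed = int(seed)
    if seed < 0:
        raise ValueError("seed must be non-negative")
    ron1, roff1, ron2, roff2 = rate_tables(params)
    args = (ron1, roff1, ron2, roff2, params.half_n, params.N, params.L, max_time)
    if not record:
        dec, rt, ne = _trial_kernel(*args, seed)
        return TrialResult(decision=int(dec), rt=float(rt), n_events=int(ne), seed=seed)
    cap = record_capacity
    if cap is None:
        # generous: total propensity is at most N * rate_unit
        cap = int(min(params.N * params.rate_unit * max_time * 1.5 + 10_000, 50_000_000))
    times = np.empty(cap, dtype=np.float64)
    vpath = np.empty(cap, dtype=np.float64)
    dvpath = np.empty(cap, dtype=np.float64)
    dec, rt, ne, k = _record_kernel(*args, seed, times, vpath, dvpath)
    if dec == -2:
        raise RuntimeError(
            f"trajectory capacity {cap} exhausted after {ne} events; "
            "pass a larger record_capacity"
        )
    result = TrialResult(decision=int(dec), rt=float(rt), n_events=int(ne), seed=seed)
    traj = Trajectory(
        event_times=times[:k].copy(), v_path=vpath[:k].copy(), dv_path=dvpath[:k].copy()
    )
    return result, traj


def simulate_ensemble_arrays(
    params: ModelParams,
    n_trials: int,
    seed: int,
    max_time: float = DEFAULT_MAX_TIME,
    seed_offset: int = 0,
    warn_timeouts: bool = True,
):
    """Vectorized ensemble: returns (decisions, rts, n_events, seeds) arrays."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ron1, roff1, ron2, roff2 = rate_tables(params)
    seeds = _child_seeds(int(seed), n_trials, offset=seed_offset)
    decisions = np.empty(n_trials, dtype=np.int8)
    rts = np.empty(n_trials, dtype=np.float64)
    nev = np.empty(n_trials, dtype=np.int64)
    _ensemble_kernel(
        ron1,
        roff1,
        ron2,
        roff2,
        params.half_n,
        params.N,
        params.L,
        max_time,
        seeds,
        decisions,
        rts,
        nev,
    )
    if warn_timeouts:
        frac = np.mean(decisions == 0)
        if frac > TIMEOUT_WARN_FRACTION:
            warnings.warn(
                f"{frac:.2%} of trials timed out at max_time={max_time:g}; "
                "statistics from this ensemble may be biased",
                RuntimeWarning,
                stacklevel=2,
            )
    return decisions, rts, nev, seeds


def simulate_ensemble(
    params: ModelParams,
    n_trials: int,
    seed: int,
    max_time: float = DEFAULT_MAX_TIME,
) -> list[TrialResult]:
    """Run ``n_trials`` independent trials from one master seed.

    Trial ``i`` is driven by ``child_seed(seed, i)``, so results are
    reproducible and independent of ensemble size or ordering.  Timeout
    trials are returned flagged (decision 0), never dropped.
    """
    decisions, rts, nev, seeds = simulate_ensemble_arrays(
        params, n_trials, seed, max_time
    )
    return [
        TrialResult(
            decision=int(decisions[i]),
            rt=float(rts[i]),
            n_events=int(nev[i]),
            seed=int(seeds[i]),
        )
        for i in range(n_trials)
    ]


def stationary_velocity_histogram(
    params: ModelParams,
    total_time: float,
    seed: int,
    bins: int = 51,
    burn_in: float = 0.0,
):
    """Time-weighted histogram of V from one long threshold-free run.

    Runs the spin dynamics with the absorbing thresholds disabled for
    ``total_time`` and weights each velocity value by the time spent at it.
    Returns ``(bin_centers, density)`` with the density normalized to unit
    mass over the bins.
    """
    free = params.replace(L=1.0)  # L unused: thresholds disabled via inf
    ron1, roff1, ron2, roff2 = rate_tables(free)
    cap = int(params.N * params.rate_unit * total_time * 1.5 + 10_000)
    times = np.empty(cap, dtype=np.float64)
    vpath = np.empty(cap, dtype=np.float64)
    dvpath = np.empty(cap, dtype=np.float64)
    dec, _, _, k = _record_kernel(
        ron1,
        roff1,
        ron2,
        roff2,
        params.half_n,
        params.N,
        np.inf,
        total_time,
        int(seed),
        times,
        vpath,
        dvpath,
    )
    if dec == -2:
        raise RuntimeError("velocity-histogram capacity exhausted")
    t = times[:k]
    v = vpath[:k]
    # holding times: V after event i persists until event i+1 (or total_time)
    holds = np.diff(np.append(t, total_time))
    mask = t >= burn_in
    edges = np.linspace(-0.5, 0.5, bins + 1)
    hist, _ = np.histogram(v[mask], bins=edges, weights=holds[mask])
    width = edges[1] - edges[0]
    total = hist.sum()
    if total <= 0:
        raise RuntimeError("empty velocity histogram (no time recorded)")
    density = hist / (total * width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density
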