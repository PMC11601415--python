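"""Mean-field theory of the decision-variable velocity.

At steady state the population rate equations give, per group, an "on"
fraction of half the on-rate (because on- and off-rates are complementary),
so the self-consistent velocity satisfies

    V = (1/2) [ sigma((2V - eta + eps1)/T) - sigma((-2V - eta + eps2)/T) ]

with ``sigma`` the logistic function.  For ``eps1 = eps2 = 0`` this is
equivalent to

    V = (1/2) sinh(2V/T) / (cosh(eta/T) + cosh(2V/T))

and for ``eps1 > 0, eps2 = 0`` to the product form

    V = (1/4) sinh((4V + eps1)/(2T))
        / [ cosh((eta + 2V)/(2T)) cosh((-eta + 2V + eps1)/(2T)) ].

Fixed points of this map are the steady-state velocities; their stability
under the relaxational population flow is decided by whether the slope of
the right-hand side at the fixed point is below or above 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import ModelParams, glauber_rates

__all__ = ["MFSolution", "MFSolutionSet", "mf_rhs", "mf_rhs_prime", "mf_solutions"]

#: bracketing grid density on [-1/2, 1/2]; the map has at most 5 roots,
#: all well separated except near criticality, so this is generous.
_GRID_POINTS = 2001
_POLISH_TOL = 1e-12
_MERGE_TOL = 1e-8
#: |slope - 1| below this at a root -> "marginal" (tangency / first-order line)
_MARGINAL_TOL = 1e-6


def mf_rhs(V, params: ModelParams):
    """Right-hand side of the velocity self-consistency map (vectorized)."""
    V = np.asarray(V, dtype=float)
    T = params.T
    xI = (2.0 * V - params.eta + params.eps1) / T
    xII = (-2.0 * V - params.eta + params.eps2) / T
    out = 0.5 * (_logistic_np(xI) - _logistic_np(xII))
    if out.ndim == 0:
        return float(out)
    return out


def _logistic_np(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    z = np.exp(x[~pos])
    out[~pos] = z / (1.0 + z)
    return out


def mf_rhs_prime(V, params: ModelParams):
    """Slope of the self-consistency map (analytic, vectorized).

    With ``rhs = (sigma(xI) - sigma(xII)) / 2`` and both logistic arguments
    linear in V with slopes ``+-2/T``, the derivative is
    ``[sigma'(xI) + sigma'(xII)] / T``.
    """
    V = np.asarray(V, dtype=float)
    T = params.T
    sI = _logistic_np((2.0 * V - params.eta + params.eps1) / T)
    sII = _logistic_np((-2.0 * V - params.eta + params.eps2) / T)
    out = (sI * (1.0 - sI) + sII * (1.0 - sII)) / T
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class MFSolution:
    """One fixed point of the velocity map with its stability label."""

    V: float
    stability: str  # "stable" | "unstable" | "marginal"

    @property
    def stable(self) -> bool:
        return self.stability == "stable"


@dataclass(frozen=True)
class MFSolutionSet:
    """All fixed points of the mean-field velocity map for one parameter set."""

    solutions: tuple[MFSolution, ...]
    params: ModelParams

    @property
    def velocities(self) -> np.ndarray:
        return np.array([s.V for s in self.solutions])

    @property
    def stable_velocities(self) -> np.ndarray:
        return np.array([s.V for s in self.solutions if s.stable])

    def positive_stable(self) -> float | None:
        vs = [v for v in self.stable_velocities if v > _MERGE_TOL]
        return max(vs) if vs else None

    def negative_stable(self) -> float | None:
        vs = [v for v in self.stable_velocities if v < -_MERGE_TOL]
        return min(vs) if vs else None

    def has_zero_stable(self) -> bool:
        return any(abs(s.V) <= _MERGE_TOL and s.stable for s in self.solutions)

    def has_nonzero_stable_pair(self) -> bool:
        return (
            self.positive_stable() is not None
            and self.negative_stable() is not None
        )


def mf_solutions(params: ModelParams) -> MFSolutionSet:
    """All fixed points ``V* = rhs(V*)`` on [-1/2, 1/2] with stability.

    Roots are bracketed by sign changes of ``rhs(V) - V`` on a dense uniform
    grid, polished with Brent's method, and merged when closer than 1e-8.
    A root where the slope of the map equals 1 (to within 1e-6) sits on a
    tangency (saddle-node) and is labeled ``"marginal"``.
    """
    grid = np.linspace(-0.5, 0.5, _GRID_POINTS)
    g = mf_rhs(grid, params) - grid
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = g[i], g[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0.0:
            r = brentq(
                lambda v: mf_rhs(v, params) - v,
                grid[i],
                grid[i + 1],
                xtol=_POLISH_TOL,
                rtol=8.881784197001252e-16,
            )
            roots.append(r)
    if g[-1] == 0.0:
        roots.append(grid[-1])
    if not roots:
        raise RuntimeError(
            f"no mean-field fixed point found for {params!r}; "
            "this should be impossible (V=0 is a root for eps1=eps2=0)"
        )
    merged: list[float] = []
    for r in sorted(roots):
        if not merged or abs(r - merged[-1]) > _MERGE_TOL:
            merged.append(r)
    sols = []
    for r in merged:
        slope = mf_rhs_prime(r, params)
        if abs(slope - 1.0) <= _MARGINAL_TOL:
            label = "marginal"
        elif slope < 1.0:
            label = "stable"
        else:
            label = "unstable"
        sols.append(MFSolution(V=r, stability=label))
    return MFSolutionSet(solutions=tuple(sols), params=params)


def integrate_rate_equations(
    params: ModelParams,
    n_on_I0: float,
    n_on_II0: float,
    t_final: float = 200.0,
) -> float:
    """Integrate the deterministic population rate equations; return final V.

    Serves as an independent check that fixed points of the self-consistency
    map are the long-time plateaus of the population flow
    ``d n1/dt = r_on n0 - r_off n1`` per group (fractions of the total N).
    """

    def flow(_t, y):
        v = y[0] - y[1]
        q = glauber_rates(v, params)
        return [
            q.r_on_I * (0.5 - y[0]) - q.r_off_I * y[0],
            q.r_on_II * (0.5 - y[1]) - q.r_off_II * y[1],
        ]

    sol = solve_ivp(
        flow,
        (0.0, t_final),
        [n_on_I0, n_on_II0],
        rtol=1e-10,
        atol=1e-12,
        dense_output=False,
    )
    yT = sol.y[:, -1]
    return float(yT[0] - yT[1])
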