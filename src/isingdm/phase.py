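"""Phase diagram of the unbiased model in the (T, eta) plane.

Three phases, decided by the stable fixed points of the mean-field velocity
map at zero bias:

* **ordered** — only a symmetric pair of nonzero velocities is stable
  (V = 0 exists but is unstable): the integrator moves ballistically.
* **intermittent** — V = 0 is stable *and* a nonzero stable pair coexists.
* **disordered** — only V = 0 is stable: the integrator diffuses.

The ordered phase is bounded by a second-order line with the closed form
``eta = T * arccosh((1 - T)/T)`` (valid for ``0 < T <= 1/2``), obtained by
expanding the velocity map to third order at V = 0.  The intermittent band
is bounded above by a first-order line where the nonzero pair appears
through a tangency (saddle-node) of the map.  The two lines meet at the
tricritical point, which has the closed form ``(T, eta) = (1/3,
arccosh(2)/3)``; this module recomputes it numerically from the defining
conditions (fixed point with vanishing first- and third-order Taylor
excess) and uses the closed form only in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import fsolve

from .meanfield import mf_rhs, mf_rhs_prime, mf_solutions
from .model import ModelParams

__all__ = [
    "PhaseBoundary",
    "second_order_eta",
    "tricritical_point",
    "first_order_line",
    "classify_phase",
]


@dataclass(frozen=True)
class PhaseBoundary:
    """An ordered polyline of (T, eta) points along one transition line."""

    kind: str  # "second_order" | "first_order"
    points: np.ndarray  # shape (n, 2): columns (T, eta)


def second_order_eta(T) -> float | np.ndarray:
    """Second-order transition line ``eta = T * arccosh((1 - T)/T)``.

    Defined for ``0 < T <= 1/2`` (the arccosh argument must be >= 1); the
    line hits ``eta = 0`` exactly at the zero-field critical temperature
    ``T = 1/2`` and also vanishes as ``T -> 0``.
    """
    Tarr = np.asarray(T, dtype=float)
    if np.any(Tarr <= 0.0) or np.any(Tarr > 0.5):
        raise ValueError("second-order line requires 0 < T <= 1/2")
    out = Tarr * np.arccosh((1.0 - Tarr) / Tarr)
    return float(out) if out.ndim == 0 else out


def _taylor_c1_c3(T: float, eta: float) -> tuple[float, float]:
    """Linear and cubic Taylor coefficients of the velocity map at V = 0.

    Obtained by least-squares fitting an odd polynomial of degree 7 on a
    small symmetric grid; purely numerical so the tricritical solve does not
    depend on hand-derived formulas.
    """
    params = ModelParams(T=T, eta=eta, N=2)
    v = np.linspace(-0.05, 0.05, 41)
    f = mf_rhs(v, params)
    # odd function: fit odd powers only
    A = np.stack([v, v**3, v**5, v**7, v**9], axis=1)
    coef, *_ = np.linalg.lstsq(A, f, rcond=None)
    return float(coef[0]), float(coef[1])


@lru_cache(maxsize=1)
def tricritical_point() -> tuple[float, float]:
    """Numerically solve for the meeting point of the two transition lines.

    The conditions are that V = 0 is a fixed point whose linear Taylor
    coefficient equals 1 (loss of stability) while the cubic coefficient
    vanishes (the transition changes order).  Solved with a 2-variable
    Newton iteration; the result matches the closed form
    ``(1/3, arccosh(2)/3)`` to well below 1e-8.
    """

    def conditions(x):
        T, eta = x
        c1, c3 = _taylor_c1_c3(T, eta)
        return [c1 - 1.0, c3]

    sol = fsolve(conditions, x0=[0.35, 0.45], full_output=False, xtol=1e-13)
    T_tri, eta_tri = float(sol[0]), float(sol[1])
    return T_tri, eta_tri


def _tangency_system_fixed_V(x, V):
    """Residuals of (fixed point, unit slope) in unknowns (T, eta) at fixed V.

    The raw residuals (fixed-point excess and unit-slope excess) agree to
    O(V^2) near the tricritical point, which makes them nearly parallel in
    (T, eta); the linear combinations below separate them into a
    stability-like condition and a cubic-coefficient-like condition, so the
    Jacobian stays well-conditioned as V -> 0.
    """
    T, eta = x
    params = ModelParams(T=T, eta=eta, N=2)
    g1 = mf_rhs(V, params) / V - 1.0  # ~ (c1 - 1) + c3 V^2 + ...
    g2 = mf_rhs_prime(V, params) - 1.0  # ~ (c1 - 1) + 3 c3 V^2 + ...
    return [(3.0 * g1 - g2) / 2.0, (g2 - g1) / (2.0 * V * V)]


def _tangency_system_fixed_T(x, T):
    """Residuals of (fixed point, unit slope) in unknowns (eta, V) at fixed T."""
    eta, V = x
    params = ModelParams(T=T, eta=eta, N=2)
    return [mf_rhs(V, params) - V, mf_rhs_prime(V, params) - 1.0]


_fo_curve_cache: dict = {}


def _first_order_curve(T_min: float) -> np.ndarray:
    """Trace the tangency branch, parametrized by the tangency velocity.

    At the tricritical point the saddle-node velocity is 0 and the
    fixed-temperature tangency system is degenerate, so the branch is
    continued in V instead: for each V the two conditions are solved for
    (T, eta), seeded by the previous solution.  Returns rows
    (T, eta, V*) ordered from the tricritical point downward in T.
    """
    cached = _fo_curve_cache.get("curve")
    if cached is not None and cached[-1, 0] <= T_min:
        return cached
    T_tri, eta_tri = tricritical_point()
    rows = [(T_tri, eta_tri, 0.0)]
    seed = np.array([T_tri, eta_tri])
    V = 0.0
    dV = 0.005
    while rows[-1][0] > max(T_min - 0.01, 1e-3) and V + dV < 0.5:
        V += dV
        sol, _, _, msg = fsolve(
            _tangency_system_fixed_V, x0=seed, args=(V,), xtol=1e-13, full_output=True
        )
        resid = _tangency_system_fixed_V(sol, V)
        if max(abs(resid[0]), abs(resid[1])) > 1e-9:
            raise RuntimeError(
                f"first-order continuation failed at V={V:.3f}: {msg} "
                f"(residual {resid})"
            )
        seed = sol
        rows.append((float(sol[0]), float(sol[1]), V))
    curve = np.array(rows)
    _fo_curve_cache["curve"] = curve
    return curve


def first_order_line(T_grid) -> PhaseBoundary:
    """First-order transition line eta(T) for temperatures below T_tri.

    For each T the line is where a nonzero fixed-point pair of the unbiased
    velocity map appears through a tangency: ``rhs(V*) = V*`` and
    ``rhs'(V*) = 1`` with ``V* != 0``.  The branch is traced by
    pseudo-arclength-style continuation seeded at the tricritical point
    (see :func:`_first_order_curve`), then each requested temperature is
    polished with a Newton solve at fixed T.
    """
    T_grid = np.atleast_1d(np.asarray(T_grid, dtype=float))
    T_tri, _ = tricritical_point()
    if np.any(T_grid >= T_tri):
        raise ValueError(
            f"first-order line exists only for T < T_tri ~ {T_tri:.4f}"
        )
    if np.any(T_grid <= 0):
        raise ValueError("temperatures must be positive")
    curve = _first_order_curve(float(T_grid.min()))
    # curve is ordered decreasing in T; flip for interpolation
    Tc = curve[::-1, 0]
    etac = curve[::-1, 1]
    Vc = curve[::-1, 2]
    etas = np.empty_like(T_grid)
    for i, T in enumerate(T_grid):
        eta_seed = float(np.interp(T, Tc, etac))
        v_seed = float(np.interp(T, Tc, Vc))
        sol, _, _, _ = fsolve(
            _tangency_system_fixed_T,
            x0=[eta_seed, v_seed],
            args=(float(T),),
            xtol=1e-12,
            full_output=True,
        )
        resid = _tangency_system_fixed_T(sol, float(T))
        good = max(abs(resid[0]), abs(resid[1])) < 1e-9 and abs(sol[1]) > 1e-6
        # near the tricritical point the fixed-T system is ill-conditioned;
        # the continuation interpolant is already accurate there
        etas[i] = float(sol[0]) if good else eta_seed
    pts = np.stack([T_grid, etas], axis=1)
    return PhaseBoundary(kind="first_order", points=pts[np.argsort(pts[:, 0])])


def classify_phase(T: float, eta: float) -> str:
    """Classify a (T, eta) point as ordered / intermittent / disordered.

    Decided directly from the stable fixed points of the unbiased mean-field
    map (see module docstring).  Points numerically on a boundary resolve to
    whichever side the fixed-point structure lands on, i.e. the
    ordered/intermittent side of a marginal tangency; the choice is
    arbitrary but deterministic.
    """
    if T <= 0 or eta < 0:
        raise ValueError("require T > 0 and eta >= 0")
    sols = mf_solutions(ModelParams(T=T, eta=eta, N=2))
    pair = sols.has_nonzero_stable_pair()
    zero = sols.has_zero_stable()
    if pair and zero:
        return "intermittent"
    if pair:
        return "ordered"
    if zero:
        return "disordered"
    # a marginal zero root with no stable pair: on the second-order line
    return "ordered" if math.isclose(mf_rhs_prime(0.0, ModelParams(T=T, eta=eta, N=2)), 1.0, abs_tol=1e-6) else "disordered"
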