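"""Core parameterization of the integrated Ising decision model.

The model describes a binary decision circuit as ``N`` spins split into two
equal, mutually inhibiting groups of ``N/2``.  Each spin is "on" (firing) or
"off" (resting).  A global inhibitory field ``eta`` pushes every spin toward
"off"; biases ``eps1``/``eps2`` push the spins of group I/II toward "on",
encoding learned evidence for the corresponding option.  The instantaneous
velocity of the decision variable is the difference between the "on"
fractions of the two groups, ``V = (n_on_I - n_on_II) / N``, and a decision
is made when the time integral of ``V`` reaches ``+L`` or ``-L``.

Only the population counts matter: the couplings are all-to-all (+1 within a
group, -1 across groups), so ``(n_on_I, n_on_II)`` is a sufficient statistic
for the full spin configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import yaml

__all__ = [
    "ModelParams",
    "SpinCounts",
    "RateQuartet",
    "velocity",
    "glauber_rates",
    "energy",
]

# Logistic arguments beyond this magnitude are treated as saturated (rate 0
# or 1) so that very low temperatures never overflow ``exp``.
_LOGISTIC_CLAMP = 700.0


def _logistic(x: float) -> float:
    """Numerically stable ``1 / (1 + exp(-x))``."""
    if x >= _LOGISTIC_CLAMP:
        return 1.0
    if x <= -_LOGISTIC_CLAMP:
        return 0.0
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


@dataclass(frozen=True)
class ModelParams:
    """Full coordinate of one model instance.

    Parameters
    ----------
    T:
        Noise-to-coupling ratio; plays the role of temperature.  Must be > 0.
    eta:
        Strength of the global inhibition field (>= 0).
    eps1, eps2:
        Bias fields toward option I and option II (>= 0).  The biased case
        analyzed throughout uses ``eps1 >= 0, eps2 = 0``; ``eps2`` enters
        group II mirror-symmetrically.
    N:
        Total number of spins; positive even integer, split into two equal
        groups of ``N/2``.
    L:
        Decision threshold on the integrated decision-variable axis (> 0).
    rate_unit:
        Multiplicative rate constant fixing the time units; 1 by convention.
    """

    T: float
    eta: float = 0.0
    eps1: float = 0.0
    eps2: float = 0.0
    N: int = 100
    L: float = 5.0
    rate_unit: float = field(default=1.0, compare=False)

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError(f"temperature must be positive, got T={self.T}")
        if self.eta < 0:
            raise ValueError(f"global inhibition must be >= 0, got eta={self.eta}")
        if self.eps1 < 0 or self.eps2 < 0:
            raise ValueError(
                f"biases must be >= 0, got eps1={self.eps1}, eps2={self.eps2}"
            )
        if self.N < 2 or self.N % 2:
            raise ValueError(f"N must be a positive even integer, got N={self.N}")
        if not self.L > 0:
            raise ValueError(f"threshold must be positive, got L={self.L}")

    @property
    def half_n(self) -> int:
        """Number of spins per group."""
        return self.N // 2

    # -- flat key-value serialization ------------------------------------
    _KEYS = ("T", "eta", "eps1", "eps2", "N", "L")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self._KEYS}

    @classmethod
    def from_dict(cls, d: dict, **overrides) -> "ModelParams":
        unknown = set(d) - set(cls._KEYS)
        if unknown:
            raise ValueError(f"unknown model parameter keys: {sorted(unknown)}")
        merged = {**d, **overrides}
        if "N" in merged:
            merged["N"] = int(merged["N"])
        return cls(**merged)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelParams":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls.from_dict(json.loads(text))

    def replace(self, **changes) -> "ModelParams":
        d = self.to_dict()
        d.update(changes)
        return ModelParams.from_dict(d)


class SpinCounts(NamedTuple):
    """Numbers of "on" spins in each group; each bounded by ``N/2``."""

    n_on_I: int
    n_on_II: int

    def validate(self, params: ModelParams) -> None:
        half = params.half_n
        for name, n in (("n_on_I", self.n_on_I), ("n_on_II", self.n_on_II)):
            if not 0 <= n <= half:
                raise ValueError(f"{name}={n} outside [0, {half}] for N={params.N}")


class RateQuartet(NamedTuple):
    """Per-spin flip probabilities per unit time for the four channels.

    ``r_on_X`` is the 0->1 rate and ``r_off_X`` the 1->0 rate of a spin in
    group X.  Logistic complementarity guarantees ``r_on + r_off == 1``
    within each group.
    """

    r_on_I: float
    r_off_I: float
    r_on_II: float
    r_off_II: float


def velocity(counts: SpinCounts, params: ModelParams) -> float:
    """Decision-variable velocity ``V = (n_on_I - n_on_II) / N``.

    Always recomputed from the integer counts so it cannot drift; bounded
    in ``[-1/2, 1/2]`` because each group holds ``N/2`` spins.
    """
    counts = SpinCounts(*counts)
    counts.validate(params)
    return (counts.n_on_I - counts.n_on_II) / params.N


def glauber_rates(V: float, params: ModelParams) -> RateQuartet:
    """Glauber (heat-bath) flip rates at decision velocity ``V``.

    The local field on a group-I spin is ``2V - eta + eps1`` and on a
    group-II spin ``-2V - eta + eps2``; the on-rate is the logistic of the
    field over ``T`` and the off-rate its complement.  With zero biases the
    quartet reduces to the unbiased kinetics; the bias of each group only
    modifies that group's rates.
    """
    if not -0.5 - 1e-12 <= V <= 0.5 + 1e-12:
        raise ValueError(f"velocity {V} outside [-1/2, 1/2]")
    xI = (2.0 * V - params.eta + params.eps1) / params.T
    xII = (-2.0 * V - params.eta + params.eps2) / params.T
    r_on_I = _logistic(xI)
    r_on_II = _logistic(xII)
    u = params.rate_unit
    return RateQuartet(
        r_on_I=u * r_on_I,
        r_off_I=u * (1.0 - r_on_I),
        r_on_II=u * r_on_II,
        r_off_II=u * (1.0 - r_on_II),
    )


def energy(counts: SpinCounts, params: ModelParams) -> float:
    """Diagnostic energy of a population state (dynamics use rates, not this).

    With all-to-all couplings (+1 within, -1 across groups) the pair sum over
    distinct ordered pairs collapses to counts::

        sum_{i != j} J_ij s_i s_j = nI (nI - 1) + nII (nII - 1) - 2 nI nII

    and the energy is ``-(1/N) * pair_sum + eta (nI + nII) - eps1 nI -
    eps2 nII``.
    """
    counts = SpinCounts(*counts)
    counts.validate(params)
    nI, nII = counts.n_on_I, counts.n_on_II
    pair_sum = nI * (nI - 1) + nII * (nII - 1) - 2 * nI * nII
    return (
        -pair_sum / params.N
        + params.eta * (nI + nII)
        - params.eps1 * nI
        - params.eps2 * nII
    )
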