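"""Unit and property tests for the spin-model core: velocity, Glauber
rates, energy, and parameter validation/serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isingdm import ModelParams, RateQuartet, SpinCounts, energy, glauber_rates, velocity


def params(**kw):
    base = dict(T=0.3, eta=0.1, N=100, L=5.0)
    base.update(kw)
    return ModelParams(**base)


class TestVelocity:
    @pytest.mark.parametrize(
        "n1, n2, N, expected",
        [(17, 17, 100, 0.0), (50, 0, 100, 0.5), (30, 10, 100, 0.2), (0, 50, 100, -0.5)],
    )
    def test_velocity_arithmetic(self, n1, n2, N, expected):
        assert velocity(SpinCounts(n1, n2), params(N=N)) == pytest.approx(expected)

    def test_counts_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            velocity(SpinCounts(51, 0), params(N=100))
        with pytest.raises(ValueError):
            velocity(SpinCounts(0, -1), params(N=100))


class TestGlauberRates:
    def test_symmetric_point_gives_one_half(self):
        for T in (0.05, 0.5, 3.0):
            q = glauber_rates(0.0, params(T=T, eta=0.0))
            assert all(r == pytest.approx(0.5) for r in q)

    def test_known_value_unbiased(self):
        # V=0.25, T=0.5, eta=0: group-I on-rate is logistic(1)
        q = glauber_rates(0.25, params(T=0.5, eta=0.0))
        assert q.r_on_I == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), abs=1e-12)
        assert q.r_on_II == pytest.approx(1.0 / (1.0 + math.exp(1.0)), abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(
        V=st.floats(-0.5, 0.5),
        T=st.floats(0.01, 5.0),
        eta=st.floats(0.0, 2.0),
        eps1=st.floats(0.0, 0.5),
        eps2=st.floats(0.0, 0.5),
    )
    def test_rate_complementarity(self, V, T, eta, eps1, eps2):
        q = glauber_rates(V, ModelParams(T=T, eta=eta, eps1=eps1, eps2=eps2))
        assert q.r_on_I + q.r_off_I == pytest.approx(1.0, abs=1e-12)
        assert q.r_on_II + q.r_off_II == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(
        V=st.floats(-0.5, 0.5),
        T=st.floats(0.01, 5.0),
        eta=st.floats(0.0, 2.0),
        eps1=st.floats(0.0, 0.5),
        eps2=st.floats(0.0, 0.5),
    )
    def test_group_exchange_symmetry(self, V, T, eta, eps1, eps2):
        """Swapping the groups (and their biases) mirrors V and the quartet."""
        q = glauber_rates(V, ModelParams(T=T, eta=eta, eps1=eps1, eps2=eps2))
        qm = glauber_rates(-V, ModelParams(T=T, eta=eta, eps1=eps2, eps2=eps1))
        assert q.r_on_I == pytest.approx(qm.r_on_II, abs=1e-12)
        assert q.r_off_I == pytest.approx(qm.r_off_II, abs=1e-12)

    def test_zero_temperature_limit_saturates_without_overflow(self):
        q = glauber_rates(0.25, params(T=1e-12, eta=0.0))
        assert q.r_on_I == 1.0 and q.r_off_I == 0.0
        assert q.r_on_II == 0.0 and q.r_off_II == 1.0
        # inhibition dominating: everything relaxes off
        q2 = glauber_rates(0.0, params(T=1e-12, eta=0.5))
        assert q2.r_on_I == 0.0 and q2.r_on_II == 0.0

    def test_invalid_temperature_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(T=0.0)
        with pytest.raises(ValueError):
            ModelParams(T=-1.0)


def _energy_by_enumeration(n1, n2, prm):
    """Independent oracle: explicit sum over ordered spin pairs."""
    half = prm.N // 2
    spins = [1] * n1 + [0] * (half - n1) + [1] * n2 + [0] * (half - n2)
    group = [0] * half + [1] * half
    pair_sum = 0.0
    for i in range(prm.N):
        for j in range(prm.N):
            if i == j:
                continue
            J = 1.0 if group[i] == group[j] else -1.0
            pair_sum += J * spins[i] * spins[j]
    field = prm.eta * (n1 + n2) - prm.eps1 * n1 - prm.eps2 * n2
    return -pair_sum / prm.N + field


class TestEnergy:
    def test_all_off_is_zero(self):
        assert energy(SpinCounts(0, 0), params()) == 0.0

    def test_small_system_value(self):
        # two on-spins in one group of a 4-spin system: one interacting
        # ordered pair each way, -(1/4)*2 = -0.5
        prm = ModelParams(T=1.0, eta=0.0, N=4)
        assert energy(SpinCounts(2, 0), prm) == pytest.approx(-0.5)

    @pytest.mark.parametrize("n1, n2", [(0, 0), (1, 0), (2, 3), (5, 5), (5, 1)])
    def test_matches_pair_enumeration(self, n1, n2):
        prm = ModelParams(T=0.7, eta=0.3, eps1=0.2, eps2=0.1, N=10)
        assert energy(SpinCounts(n1, n2), prm) == pytest.approx(
            _energy_by_enumeration(n1, n2, prm), abs=1e-12
        )

    def test_group_swap_symmetry_with_equal_biases(self):
        prm = ModelParams(T=0.7, eta=0.3, eps1=0.2, eps2=0.2, N=20)
        assert energy(SpinCounts(7, 2), prm) == pytest.approx(
            energy(SpinCounts(2, 7), prm)
        )


class TestModelParams:
    def test_yaml_round_trip(self):
        p = ModelParams(T=0.29, eta=0.44, eps1=0.01, N=100, L=5.0)
        assert ModelParams.from_yaml(p.to_yaml()) == p

    def test_json_round_trip(self):
        p = ModelParams(T=0.29, eta=0.44, eps2=0.02, N=64, L=2.0)
        assert ModelParams.from_json(p.to_json()) == p

    def test_serialized_keys_are_exactly_the_flat_schema(self):
        assert set(ModelParams(T=1.0).to_dict()) == {"T", "eta", "eps1", "eps2", "N", "L"}

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ModelParams.from_dict({"T": 0.5, "beta": 1.0})

    @pytest.mark.parametrize(
        "kw",
        [dict(T=0.5, N=3), dict(T=0.5, N=0), dict(T=0.5, L=0.0),
         dict(T=0.5, eta=-0.1), dict(T=0.5, eps1=-0.2)],
    )
    def test_invariants_enforced(self, kw):
        with pytest.raises(ValueError):
            ModelParams(**kw)

    def test_rate_quartet_named_fields(self):
        q = RateQuartet(0.6, 0.4, 0.3, 0.7)
        assert q.r_on_I == 0.6 and q.r_off_II == 0.7
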