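"""Witness angle, concurrence map, and entanglement entropy."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from beqbn import (
    TwoStageNetwork,
    branch_vectors,
    build_superposition,
    concurrence_from_witness,
    entropy_from_concurrence,
    estimate_entanglement,
    interference_cos,
    qlw_witness,
)

probs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def _bv(net, phases=(0.0,) * 4):
    return branch_vectors(build_superposition(net, phases=phases))


class TestWitness:
    def test_value_on_the_pd_network(self):
        # |v1|^2 = 0.905 -> angle arccos(sqrt 0.905)
        qlw = qlw_witness(_bv(TwoStageNetwork(0.5, 0.97, 0.84)))
        assert qlw == pytest.approx(math.acos(math.sqrt(0.905)), abs=1e-12)
        assert qlw == pytest.approx(0.31332210582037023, abs=1e-12)

    def test_empty_second_branch_gives_zero_angle(self):
        assert qlw_witness(_bv(TwoStageNetwork(1.0, 1.0, 0.5))) == pytest.approx(0.0, abs=1e-12)

    def test_balanced_branches_give_pi_over_four(self):
        assert qlw_witness(_bv(TwoStageNetwork(0.5, 0.5, 0.5))) == pytest.approx(
            math.pi / 4, abs=1e-12
        )

    def test_empty_first_branch_returns_limit_pi_over_two(self):
        assert qlw_witness(_bv(TwoStageNetwork(1.0, 0.0, 0.5))) == math.pi / 2

    def test_nonfinite_input_is_rejected(self):
        with pytest.raises(ValueError):
            qlw_witness((np.array([np.nan, 0, 0, 0]), np.array([0, 1, 0, 0])))

    def test_phase_invariance_over_many_random_draws(self, rng):
        nets = [TwoStageNetwork(*rng.uniform(0, 1, 3)) for _ in range(20)]
        for net in nets:
            ref = qlw_witness(_bv(net))
            for _ in range(50):  # 1000 draws total
                phases = tuple(rng.uniform(0, 2 * math.pi, 4))
                assert qlw_witness(_bv(net, phases)) == pytest.approx(ref, abs=1e-12)

    @given(p=probs, q1=probs, q2=probs)
    def test_matches_closed_form_arccos_of_branch_norm(self, p, q1, q2):
        net = TwoStageNetwork(p, q1, q2)
        c = build_superposition(net).amplitudes
        closed = math.acos(min(1.0, math.hypot(c[0], c[2])))
        assert qlw_witness(_bv(net)) == pytest.approx(closed, abs=1e-12)

    @given(p=probs, q1=probs, q2=probs)
    def test_angle_lies_in_first_quadrant(self, p, q1, q2):
        qlw = qlw_witness(_bv(TwoStageNetwork(p, q1, q2)))
        assert 0.0 <= qlw <= math.pi / 2


class TestConcurrenceMap:
    def test_oracle_value_on_the_pd_witness_angle(self):
        # independent evaluation of the fitted map at qlw = arccos(sqrt 0.905)
        c, clamped = concurrence_from_witness(0.31332210582037023)
        assert c == pytest.approx(0.44702173158575387, abs=1e-12)
        assert not clamped

    def test_zero_angle_closed_form(self):
        c, clamped = concurrence_from_witness(0.0)
        assert c == pytest.approx(math.sqrt(0.136 - 0.03 - 0.029), abs=1e-15)
        assert not clamped

    @given(qlw=st.floats(min_value=0.0, max_value=math.pi / 2, allow_nan=False))
    def test_output_always_a_valid_concurrence(self, qlw):
        c, _ = concurrence_from_witness(qlw)
        assert 0.0 <= c < 1.0
        assert c <= math.sqrt(0.335)

    def test_radicand_is_globally_positive_so_floor_never_activates(self):
        # the fitted coefficients keep the radicand >= ~1.8e-4 everywhere
        # (the naive |coefficient| sum 0.199 > 0.136 bound is not tight),
        # so the defensive floor and its flag stay inactive
        for qlw in np.linspace(0, math.pi / 2, 4001):
            c, clamped = concurrence_from_witness(qlw)
            assert c > 0.0
            assert not clamped


class TestEntropy:
    @pytest.mark.parametrize(
        "c, expected_m, expected_e",
        [(1.0, 0.5, 1.0), (0.0, 1.0, 0.0)],
    )
    def test_endpoints_exact(self, c, expected_m, expected_e):
        m, e = entropy_from_concurrence(c)
        assert m == expected_m and e == expected_e

    def test_oracle_value(self):
        _, e = entropy_from_concurrence(0.44702173158575387)
        assert e == pytest.approx(0.2979177338220576, abs=1e-12)

    def test_strictly_increasing_in_concurrence(self):
        grid = np.linspace(0.0, 1.0, 501)
        values = [entropy_from_concurrence(c)[1] for c in grid]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_mixing_invariant(self):
        for c in np.linspace(0, 1, 101):
            m, _ = entropy_from_concurrence(c)
            assert m == (1 + math.sqrt(1 - c * c)) / 2

    def test_out_of_range_concurrence_rejected(self):
        with pytest.raises(ValueError):
            entropy_from_concurrence(1.5)


class TestInterferenceCosine:
    @pytest.mark.parametrize("e, expected", [(0.0, 0.0), (1.0, -1.0), (0.296, -0.296)])
    def test_sign_flip(self, e, expected):
        assert interference_cos(e) == expected

    @given(p=probs, q1=probs, q2=probs)
    def test_full_chain_yields_destructive_cosine(self, p, q1, q2):
        est = estimate_entanglement(_bv(TwoStageNetwork(p, q1, q2)))
        assert -1.0 <= est.cos_theta <= 0.0
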