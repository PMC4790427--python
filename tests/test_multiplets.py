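"""Multiplet transforms checked against direct enumeration of neighbor
labeling states, plus the observable curve bookkeeping."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cumoflux.multiplets import (
    BONDED_CURVES,
    MULTIPLET_ONLY_CURVES,
    POSITIONAL_CURVES,
    ContainmentError,
    c3_type_transform,
    c4_type_transform,
    curves_from_trajectories,
    fe_c3_from_c4_multiplets,
    inverse_c3_transform,
    inverse_c4_transform,
    merge_singlet_triplet,
    variant_curves,
)


def brute_force_patterns(p_center, p_left, p_right):
    """Multiplet fractions for independent neighbor labeling, by enumerating
    the four (left, right) label outcomes."""
    q = d_left = d_right = s = 0.0
    for left, right in itertools.product([0, 1], repeat=2):
        w = p_center * (p_left if left else 1 - p_left) * \
            (p_right if right else 1 - p_right)
        if left and right:
            q += w
        elif left:
            d_left += w
        elif right:
            d_right += w
        else:
            s += w
    return q, d_left, d_right, s


def cumomers_from_independent(p_center, p_left, p_right):
    return (p_center, p_center * p_left, p_center * p_right,
            p_center * p_left * p_right)


probs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestTransformsAgainstEnumeration:
    @pytest.mark.parametrize("p", [(1.0, 0.0, 0.0), (1.0, 1.0, 1.0),
                                   (1.0, 0.5, 0.5), (0.6, 0.3, 0.8)])
    def test_c4_type(self, p):
        pi = cumomers_from_independent(*p)
        expected = brute_force_patterns(*p)
        assert c4_type_transform(*pi) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p", [(1.0, 0.0, 0.0), (1.0, 1.0, 1.0),
                                   (1.0, 0.5, 0.5), (0.6, 0.3, 0.8)])
    def test_c3_type_merges_doublets(self, p):
        pi = cumomers_from_independent(*p)
        q, dl, dr, s = brute_force_patterns(*p)
        t, d, s3 = c3_type_transform(*pi)
        assert (t, d, s3) == pytest.approx((q, dl + dr, s), abs=1e-12)

    @given(p_center=probs, p_left=probs, p_right=probs)
    @settings(max_examples=200, deadline=None)
    def test_sum_rule_and_nonnegativity(self, p_center, p_left, p_right):
        pi = cumomers_from_independent(p_center, p_left, p_right)
        patterns4 = c4_type_transform(*pi)
        patterns3 = c3_type_transform(*pi)
        assert sum(patterns4) == pytest.approx(pi[0], abs=1e-12)
        assert sum(patterns3) == pytest.approx(pi[0], abs=1e-12)
        assert all(x >= -1e-12 for x in patterns4 + patterns3)

    def test_containment_violation_raises(self):
        with pytest.raises(ContainmentError):
            c4_type_transform(0.2, 0.5, 0.1, 0.05)  # pair above positional
        with pytest.raises(ContainmentError):
            c3_type_transform(0.5, 0.2, 0.1, 0.3)  # triple above pair


class TestRoundTrips:
    @given(q=probs, dl=probs, dr=probs, s=probs)
    @settings(max_examples=100, deadline=None)
    def test_c4_round_trip(self, q, dl, dr, s):
        total = q + dl + dr + s
        if total > 1:
            q, dl, dr, s = (x / total for x in (q, dl, dr, s))
        back = c4_type_transform(*inverse_c4_transform(q, dl, dr, s))
        assert back == pytest.approx((q, dl, dr, s), abs=1e-12)

    @given(t=probs, d=probs, s=probs)
    @settings(max_examples=100, deadline=None)
    def test_c3_round_trip(self, t, d, s):
        total = t + d + s
        if total > 1:
            t, d, s = (x / total for x in (t, d, s))
        pi_c, pair_sum, pi_t = inverse_c3_transform(t, d, s)
        # any split of the pair sum reproduces the equal-coupling patterns
        back = c3_type_transform(pi_c, pair_sum / 2, pair_sum / 2, pi_t)
        assert back == pytest.approx((t, d, s), abs=1e-12)


class TestSpectralFormulas:
    def test_fe_c3_examples(self):
        assert fe_c3_from_c4_multiplets(0.0, 0.5) == pytest.approx(0.0)
        assert fe_c3_from_c4_multiplets(0.3, 0.3) == pytest.approx(0.5)

    @given(p_center=st.floats(0.05, 1.0), p3=probs,
           p5=st.floats(0.0, 0.99))  # p5 = 1 would leave no S or D34 signal
    @settings(max_examples=100, deadline=None)
    def test_fe_c3_recovers_independent_neighbor_probability(
            self, p_center, p3, p5):
        q, d34, d45, s = brute_force_patterns(p_center, p3, p5)
        assert fe_c3_from_c4_multiplets(d34, s) == pytest.approx(p3, abs=1e-9)

    def test_fe_c3_undefined_when_both_zero(self):
        with pytest.raises(ZeroDivisionError):
            fe_c3_from_c4_multiplets(0.0, 0.0)

    def test_merge_singlet_triplet(self):
        assert merge_singlet_triplet(0.2, 0.05) == pytest.approx(0.25)
        assert merge_singlet_triplet(0.0, 0.0) == 0.0
        got = merge_singlet_triplet(np.array([0.1, 0.2]), np.array([0.0, 0.1]))
        assert got == pytest.approx([0.1, 0.3])
        with pytest.raises(ValueError):
            merge_singlet_triplet(-0.1, 0.2)


class TestObservableSets:
    def test_variant_cardinalities(self):
        assert len(BONDED_CURVES) == 17
        assert len(POSITIONAL_CURVES) == 6
        assert len(MULTIPLET_ONLY_CURVES) == 11
        assert set(POSITIONAL_CURVES) | set(MULTIPLET_ONLY_CURVES) == set(BONDED_CURVES)

    def test_glnc2_d23_excluded(self):
        assert ("glu", 2, "D23") in BONDED_CURVES
        assert ("gln", 2, "D23") not in BONDED_CURVES

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            variant_curves("quantum")

    def test_curve_sum_rule_on_simulation(self, net, sys3, truth, plasma_fe, t_grid):
        from cumoflux.cumomer import integrate

        traj = integrate(sys3, truth, plasma_fe, t_grid)
        keys = [("glu", 4, p) for p in ("total", "S", "D43", "D45", "Q")]
        keys += [("gln", 3, p) for p in ("total", "S+T", "D")]
        curves = curves_from_trajectories(traj, net, keys)
        glu4 = (curves[("glu", 4, "S")] + curves[("glu", 4, "D43")]
                + curves[("glu", 4, "D45")] + curves[("glu", 4, "Q")])
        assert np.allclose(glu4, curves[("glu", 4, "total")], atol=1e-9)
        gln3 = curves[("gln", 3, "S+T")] + curves[("gln", 3, "D")]
        assert np.allclose(gln3, curves[("gln", 3, "total")], atol=1e-9)
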