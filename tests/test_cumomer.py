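"""Cumomer engine: enumeration counts, rhs structure, integration properties."""

import numpy as np
import pytest

from cumoflux.cumomer import (
    ConstructionError,
    CumomerState,
    build_rhs,
    enumerate_bonded_cumomers,
    initial_condition,
    integrate,
)
from cumoflux.network import Network, Pool, Product, Reaction


def single_pool_net(n_carbons):
    return Network({"m": Pool("m", "shared", n_carbons, 1.0)}, (),
                   measured_pools={})


class TestEnumeration:
    @pytest.mark.parametrize("n_carbons,expected", [(2, 3), (3, 6), (5, 12)])
    def test_single_pool_counts(self, n_carbons, expected):
        sys = enumerate_bonded_cumomers(single_pool_net(n_carbons))
        assert sys.n_states == expected

    def test_canonical_network_133(self, net):
        assert enumerate_bonded_cumomers(net).n_states == 133

    def test_states_are_bonded_runs(self, sys3):
        for s in sys3.states:
            assert s.positions[-1] - s.positions[0] == s.order - 1
            assert 1 <= s.order <= 3

    def test_bond_break_respected(self, net):
        sys = enumerate_bonded_cumomers(net)
        glc_sets = {s.positions for s in sys.states_of("glc")}
        # aldolase cleaves C3|C4: no tracked glucose set spans it
        assert (3, 4) not in glc_sets
        assert (1, 2, 3) in glc_sets and (4, 5, 6) in glc_sets
        assert len(glc_sets) == 12

    def test_input_pool_driven_only(self, sys3):
        tracked_pools = {s.pool for s in sys3.states}
        assert "glc_plasma" not in tracked_pools
        assert any(s.pool == "glc_plasma" for s in sys3.driven_states)

    def test_invalid_states_rejected(self):
        with pytest.raises(ValueError):
            CumomerState("m", (1, 3))  # not consecutive
        with pytest.raises(ValueError):
            CumomerState("m", (1, 2, 3, 4))  # order > 3

    def test_nonadjacent_source_raises(self):
        pools = {
            "s": Pool("s", "shared", 3, 1.0),
            "p": Pool("p", "shared", 2, 1.0),
        }
        rxn = Reaction("skip", "v", ("s",),
                       (Product("p", ({1: ("s", 1), 2: ("s", 3)},)),))
        net = Network(pools, (rxn,), measured_pools={})
        with pytest.raises(ConstructionError, match=r"pi_p\{1,2\}"):
            build_rhs(net, enumerate_bonded_cumomers(net))


class TestRhs:
    def test_zero_fluxes_zero_rhs(self, net):
        from cumoflux.cumomer import BoundSystem

        from cumoflux.network import FluxSet

        sys = build_rhs(net, enumerate_bonded_cumomers(net))
        zero = {k: 0.0 for k in net.resolve_fluxes(FluxSet(0, 0, 0, 0, 0, 0, 0))}
        bound = BoundSystem(sys, zero, lambda t: 0.7, 0.011)
        y = np.random.default_rng(0).uniform(0, 1, sys.n_states)
        assert np.all(bound.rhs(0.0, y) == 0.0)

    def test_order1_reduction_matches_full_system(self, net, sys3, sys1, truth):
        """The order-1 components of the full rhs depend only on order-1
        states and coincide with the positional model's rhs."""
        from cumoflux.cumomer import BoundSystem

        resolved = net.resolve_fluxes(truth)
        fe = lambda t: 0.7
        b3 = BoundSystem(sys3, resolved, fe, 0.011)
        b1 = BoundSystem(sys1, resolved, fe, 0.011)
        rng = np.random.default_rng(1)
        y3 = rng.uniform(0, 0.5, sys3.n_states)
        # copy the order-1 entries into the positional state vector
        y1 = np.empty(sys1.n_states)
        for i, s in enumerate(sys1.states):
            y1[i] = y3[sys3.index[s]]
        d3 = b3.rhs(0.0, y3)
        d1 = b1.rhs(0.0, y1)
        for i, s in enumerate(sys1.states):
            assert d1[i] == pytest.approx(d3[sys3.index[s]], abs=1e-14)

    def test_analytic_jacobian_matches_finite_differences(self, net, sys3, truth):
        from cumoflux.cumomer import BoundSystem

        bound = BoundSystem(sys3, net.resolve_fluxes(truth), lambda t: 0.7, 0.011)
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 0.5, sys3.n_states)
        J = bound.jac(0.0, y)
        eps = 1e-7
        for j in rng.choice(sys3.n_states, size=12, replace=False):
            dy = np.zeros_like(y)
            dy[j] = eps
            fd = (bound.rhs(0.0, y + dy) - bound.rhs(0.0, y - dy)) / (2 * eps)
            assert np.allclose(J[:, j], fd, atol=1e-6)


class TestIntegration:
    def test_constant_natural_abundance_input_is_stationary(self, net, sys3, truth):
        nat = 0.011
        traj = integrate(sys3, truth, lambda t: nat, [0.0, 30.0, 120.0],
                         natural_abundance=nat)
        y0 = initial_condition(sys3, nat)
        assert np.allclose(traj.values, y0[None, :], atol=1e-8)

    def test_precursor_product_closed_form(self):
        """Two-pool chain with the substrate held fully labeled: the product
        follows 1 - exp(-V t / P)."""
        pools = {
            "a": Pool("a", "input", 3, 0.0, is_input=True,
                      input_labeled_positions=(1, 2, 3)),
            "b": Pool("b", "shared", 3, 2.0),
        }
        ident = {i: ("a", i) for i in range(1, 4)}
        net = Network(
            pools,
            (Reaction("in", "v", ("a",), (Product("b", (ident,)),)),
             Reaction("out", "v", ("b",), ())),
            measured_pools={})
        sys = build_rhs(net, enumerate_bonded_cumomers(net))
        t = np.linspace(0.0, 10.0, 21)
        traj = integrate(sys, {"v": 0.7}, lambda _: 1.0, t, natural_abundance=0.0)
        expected = 1.0 - np.exp(-0.7 * t / 2.0)
        for positions in [(1,), (2,), (1, 2), (1, 2, 3)]:
            assert np.allclose(traj.get("b", positions), expected, atol=1e-8)

    def test_steady_state_bounded_by_input(self, net, sys1, truth):
        traj = integrate(sys1, truth, lambda t: 0.70, [0.0, 2000.0])
        assert traj.values[-1].max() <= 0.70 + 1e-8

    def test_steady_state_monotone_in_input_fe(self, net, sys1, truth):
        lo = integrate(sys1, truth, lambda t: 0.40, [0.0, 2000.0]).values[-1]
        hi = integrate(sys1, truth, lambda t: 0.70, [0.0, 2000.0]).values[-1]
        assert np.all(hi >= lo - 1e-9)

    def test_containment_throughout(self, net, sys3, truth, plasma_fe, t_grid):
        traj = integrate(sys3, truth, plasma_fe, t_grid)
        tol = 1e-7
        for s in sys3.states:
            if s.order == 1:
                continue
            pi = traj.get(s.pool, s.positions)
            for i in range(len(s.positions) - s.order + 2):
                sub = s.positions[:-1] if i == 0 else s.positions[1:]
                assert np.all(pi <= traj.get(s.pool, sub) + tol), s

    def test_tolerance_convergence(self, net, sys3, truth, plasma_fe, t_grid):
        coarse = integrate(sys3, truth, plasma_fe, t_grid, rtol=1e-6, atol=1e-8)
        fine = integrate(sys3, truth, plasma_fe, t_grid, rtol=5e-7, atol=4e-9)
        assert np.abs(coarse.values - fine.values).max() < 10 * 1e-6

    def test_rk45_agrees_with_lsoda(self, net, sys3, truth, plasma_fe):
        t = np.linspace(0.0, 180.0, 7)
        a = integrate(sys3, truth, plasma_fe, t, method="LSODA")
        b = integrate(sys3, truth, plasma_fe, t, method="RK45")
        assert np.abs(a.values - b.values).max() < 1e-6

    def test_bad_grid_rejected(self, sys3, truth, plasma_fe):
        with pytest.raises(ValueError):
            integrate(sys3, truth, plasma_fe, [0.0, 10.0, 5.0])
        with pytest.raises(ValueError):
            integrate(sys3, truth, plasma_fe, [0.0, 10.0], rtol=0.0)

    def test_trajectory_frame_tidy(self, net, sys1, truth, plasma_fe):
        traj = integrate(sys1, truth, plasma_fe, [0.0, 60.0])
        df = traj.to_frame()
        assert list(df.columns) == ["time_min", "pool", "positions", "fe"]
        assert len(df) == 2 * sys1.n_states
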