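import math

import numpy as np
import pytest
from scipy import sparse

from pathkin.constants import rt_kj
from pathkin.kinetics import (
    _spectral_factors,
    boltzmann_state,
    delta_state,
    rcmc_solve,
    simulate,
    solve_master_equation,
    time_grid,
    traffic_volume,
)
from pathkin.network import NetworkNode, PathEdge, ReactionPathNetwork
from pathkin.rates import RateMatrix, build_rate_matrix, eyring_rate

from conftest import random_reversible_network

T = 333.15


def _matrix(K, order, gibbs=None):
    return RateMatrix(sparse.csc_matrix(np.asarray(K, float)), order, T,
                      node_gibbs=None if gibbs is None else np.asarray(gibbs, float))


class TestMasterEquation:
    def test_symmetric_two_state_relaxes_to_half(self, two_state):
        st = solve_master_equation(two_state, delta_state(two_state, "A"), 1e6)
        np.testing.assert_allclose(st.populations, [0.5, 0.5], atol=1e-9)

    def test_two_state_boltzmann_ratio_nine(self):
        dg = rt_kj(T) * math.log(9.0)
        net = ReactionPathNetwork(
            {"A": NetworkNode(0.0), "B": NetworkNode(-dg)},
            [PathEdge("e", "A", "B", 30.0)],
            T,
        )
        rm = build_rate_matrix(net)
        st = solve_master_equation(rm, delta_state(rm, "A"), 1e6)
        np.testing.assert_allclose(st.populations, [0.1, 0.9], atol=1e-8)

    def test_irreversible_closed_form(self):
        k = 0.37
        rm = _matrix([[-k, 0.0], [k, 0.0]], ["A", "B"])
        for t in (0.1, 1.0, 5.0):
            st = solve_master_equation(rm, np.array([1.0, 0.0]), t)
            assert st["B"] == pytest.approx(1.0 - math.exp(-k * t), abs=1e-10)

    def test_input_validation(self, two_state):
        with pytest.raises(ValueError):
            solve_master_equation(two_state, np.array([0.7, 0.7]), 1.0)
        with pytest.raises(ValueError):
            solve_master_equation(two_state, np.array([1.0, 0.0, 0.0]), 1.0)
        with pytest.raises(ValueError):
            solve_master_equation(two_state, delta_state(two_state, "A"), -1.0)

    def test_conservation_along_trajectory(self):
        rng = np.random.default_rng(4)
        net = random_reversible_network(rng, 25)
        rm = build_rate_matrix(net)
        tr = simulate(rm, delta_state(rm, rm.node_order[0]), 100.0)
        np.testing.assert_allclose(tr.populations.sum(axis=1), 1.0, atol=1e-9)

    def test_equilibrium_is_boltzmann(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            net = random_reversible_network(
                rng, 12, node_spread=(0.0, 8.0), barrier=(10.0, 40.0)
            )
            rm = build_rate_matrix(net)
            lam, _, _ = _spectral_factors(rm)
            t = 60.0 / abs(np.sort(lam)[-2])
            st = solve_master_equation(rm, delta_state(rm, rm.node_order[0]), t)
            w = np.exp(-(rm.node_gibbs - rm.node_gibbs.min()) / rt_kj(T))
            np.testing.assert_allclose(st.populations, w / w.sum(), atol=1e-6)


class TestRCMC:
    def test_noop_when_all_rates_below_threshold(self, two_state):
        st, rec = rcmc_solve(two_state, delta_state(two_state, "A"), 1e-9)
        assert rec.steps == []
        ex = solve_master_equation(two_state, delta_state(two_state, "A"), 1e-9)
        np.testing.assert_allclose(st.populations, ex.populations, atol=1e-12)

    def test_steady_state_elimination_of_metastable_intermediate(self):
        # A(0) <-> I(30) -> B(-20): contracting I must leave the classic
        # steady-state effective rate k_AI*k_IB/(k_IA+k_IB) from A to B
        k_ai = eyring_rate(0.0, 40.0, T)
        k_ia = eyring_rate(30.0, 40.0, T)
        k_ib = eyring_rate(30.0, 45.0, T)
        K = np.zeros((3, 3))
        K[2, 0], K[0, 2], K[1, 2] = k_ai, k_ia, k_ib
        K[0, 0], K[2, 2] = -k_ai, -(k_ia + k_ib)
        rm = _matrix(K, ["A", "B", "I"], gibbs=[0.0, -20.0, 30.0])
        _, rec = rcmc_solve(rm, delta_state(rm, "A"), 1.0,
                            rate_threshold=1e8, safety=1.0)
        assert [(s.node, s.kind) for s in rec.steps] == [("I", "eliminate")]
        step = rec.steps[0]
        assert step.branching["B"] == pytest.approx(k_ib / (k_ia + k_ib), rel=1e-12)
        assert sum(step.branching.values()) == pytest.approx(1.0, abs=1e-9)
        red = rec.reduced_matrix
        eff = red.dense()[red.node_order.index("B"), red.node_order.index("A")]
        assert eff == pytest.approx(k_ai * k_ib / (k_ia + k_ib), rel=1e-12)

    def test_matches_oracle_on_random_networks(self):
        rng = np.random.default_rng(6)
        worst = 0.0
        for _ in range(30):
            net = random_reversible_network(rng, int(rng.integers(5, 51)))
            rm = build_rate_matrix(net)
            p0 = delta_state(rm, rm.node_order[int(rng.integers(rm.size))])
            t = 10.0 ** rng.uniform(-2.0, 2.0)
            ex = solve_master_equation(rm, p0, t)
            rc, _ = rcmc_solve(rm, p0, t)
            worst = max(worst, np.abs(ex.populations - rc.populations).max())
        assert worst <= 1e-3

    def test_threshold_robustness(self, benchmark_run):
        res, truth = benchmark_run
        rm = res.model.rate_matrix
        p0 = boltzmann_state(rm, truth["reactant_nodes"])
        t = res.model.t_final
        a, _ = rcmc_solve(rm, p0, t)
        b, _ = rcmc_solve(rm, p0, t, rate_threshold=0.5 / t)
        assert np.abs(a.populations - b.populations).max() <= 1e-3

    def test_contracted_nodes_never_reappear(self, benchmark_run):
        res, _ = benchmark_run
        seen = set()
        for step in res.record.steps:
            assert step.node not in seen
            seen.add(step.node)
        assert seen.isdisjoint(res.record.surviving)

    def test_record_serializes(self, benchmark_run, tmp_path):
        res, _ = benchmark_run
        path = tmp_path / "rec.json"
        res.record.to_json(path)
        assert path.exists() and path.stat().st_size > 100

    def test_invalid_threshold(self, two_state):
        with pytest.raises(ValueError):
            rcmc_solve(two_state, delta_state(two_state, "A"), 1.0, rate_threshold=0.0)


class TestTrafficVolume:
    def test_single_irreversible_step_unit_volumes(self):
        k = 1.0
        rm = _matrix([[-k, 0.0], [k, 0.0]], ["A", "B"])
        tr = simulate(rm, np.array([1.0, 0.0]), 40.0)
        tv = traffic_volume(rm, tr)
        assert tv["A"] == pytest.approx(1.0, abs=1e-3)
        assert tv["B"] == pytest.approx(1.0, abs=1e-3)

    def test_chain_intermediate_counts_in_and_out(self):
        rm = _matrix([[-1.0, 0, 0], [1.0, -2.0, 0], [0, 2.0, 0]], ["A", "I", "B"])
        tv = traffic_volume(rm, simulate(rm, np.array([1.0, 0, 0]), 40.0))
        assert tv["I"] == pytest.approx(2.0, abs=2e-3)

    def test_parallel_bypass_lowers_intermediate_volume(self):
        chain = _matrix([[-1.0, 0, 0], [1.0, -2.0, 0], [0, 2.0, 0]], ["A", "I", "B"])
        bypass = _matrix([[-1.5, 0, 0], [1.0, -2.0, 0], [0.5, 2.0, 0]], ["A", "I", "B"])
        v_chain = traffic_volume(chain, simulate(chain, np.array([1.0, 0, 0]), 40.0))
        v_byp = traffic_volume(bypass, simulate(bypass, np.array([1.0, 0, 0]), 40.0))
        assert v_byp["I"] < v_chain["I"]

    def test_contraction_route_agrees_with_oracle(self, benchmark_run):
        res, _ = benchmark_run
        rm = res.model.rate_matrix
        p0 = res.model.initial_state
        oracle = traffic_volume(rm, simulate(rm, p0, res.model.t_final))
        contracted = traffic_volume(rm, res.record)
        rel = np.abs(contracted.per_node / oracle.per_node - 1.0)
        assert rel.max() <= 0.05

    def test_nonnegative_and_relabeling_invariant(self):
        rng = np.random.default_rng(9)
        net = random_reversible_network(rng, 10)
        rm = build_rate_matrix(net)
        tv = traffic_volume(rm, simulate(rm, delta_state(rm, rm.node_order[0]), 10.0))
        assert (tv.per_node >= 0).all()
        renamed = ReactionPathNetwork(
            {"Z" + k: v for k, v in net.nodes.items()},
            [PathEdge(e.id, "Z" + e.eq_a, "Z" + e.eq_b, e.ts_gibbs) for e in net.edges],
            net.temperature,
        )
        rm2 = build_rate_matrix(renamed)
        tv2 = traffic_volume(
            rm2, simulate(rm2, delta_state(rm2, "Z" + net.node_order()[0]), 10.0)
        )
        np.testing.assert_allclose(
            tv2.per_node["Z" + tv.per_node.index].values, tv.per_node.values, rtol=1e-9
        )

    def test_group_totals_sum_members(self, benchmark_run):
        res, truth = benchmark_run
        totals = res.traffic.group_totals(truth["node_group"])
        manual = sum(res.traffic[n] for n in truth["group_nodes"]["carbocation"])
        assert totals["carbocation"] == pytest.approx(manual, rel=1e-12)

    def test_requires_trajectory(self, two_state):
        with pytest.raises(TypeError):
            traffic_volume(two_state, object())


def test_time_grid_shape_and_errors():
    g = time_grid(100.0, max_rate=1e6)
    assert g[0] == 0.0 and g[-1] == 100.0 and np.all(np.diff(g) > 0)
    assert g[1] <= 0.01 / 1e6
    with pytest.raises(ValueError):
        time_grid(-1.0)
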