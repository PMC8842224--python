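import numpy as np
import pytest

from adenofep.cycle_closure import (
    SIGMA_FLOOR,
    corrected_edge_values,
    cycle_hysteresis,
    cycle_report,
    enumerate_cycles,
    solve_node_dg,
)
from adenofep.fep_engine import EdgeEstimate
from adenofep.fepmap import PerturbationNetwork


def make_network(nodes, tree_edges, closure_edges=()):
    edges = {tuple(sorted(e)): 1.0 for e in tree_edges}
    edges.update({tuple(sorted(e)): 0.5 for e in closure_edges})
    return PerturbationNetwork(
        nodes=sorted(nodes),
        smiles={},
        edges=edges,
        tree_edges={tuple(sorted(e)) for e in tree_edges},
    )


def estimates_from(values, sem=0.1):
    return {
        e: EdgeEstimate(edge=e, replicates=(v,), mean=v, sem=sem)
        for e, v in values.items()
    }


class TestEnumerateCycles:
    def test_tree_has_empty_basis(self):
        net = make_network("abc", [("a", "b"), ("b", "c")])
        assert enumerate_cycles(net) == []

    def test_triangle_single_cycle(self):
        net = make_network("abc", [("a", "b"), ("b", "c")], [("a", "c")])
        cycles = enumerate_cycles(net)
        assert len(cycles) == 1
        assert len(cycles[0]) == 3

    def test_basis_size_on_full_map(self, network18):
        assert len(enumerate_cycles(network18)) == 11

    def test_disconnected_rejected(self):
        net = PerturbationNetwork(
            nodes=["a", "b", "c"],
            smiles={},
            edges={("a", "b"): 1.0},
            tree_edges={("a", "b")},
        )
        with pytest.raises(ValueError):
            enumerate_cycles(net)


class TestCycleHysteresis:
    VALUES = {("a", "b"): 1.0, ("b", "c"): 2.0, ("a", "c"): 3.0}

    def test_consistent_cycle_closes(self):
        walk = [("a", "b"), ("b", "c"), ("c", "a")]
        assert cycle_hysteresis(walk, self.VALUES) == pytest.approx(0.0)

    def test_inconsistent_cycle(self):
        values = {**self.VALUES, ("a", "c"): 2.5}
        walk = [("a", "b"), ("b", "c"), ("c", "a")]
        assert cycle_hysteresis(walk, values) == pytest.approx(0.5)

    def test_reversal_negates(self):
        values = {**self.VALUES, ("a", "c"): 2.5}
        fwd = [("a", "b"), ("b", "c"), ("c", "a")]
        rev = [("a", "c"), ("c", "b"), ("b", "a")]
        assert cycle_hysteresis(rev, values) == pytest.approx(
            -cycle_hysteresis(fwd, values)
        )

    def test_open_walk_rejected(self):
        with pytest.raises(ValueError, match="not closed"):
            cycle_hysteresis([("a", "b"), ("b", "c")], self.VALUES)


class TestSolveNodeDg:
    def test_chain_propagation(self):
        net = make_network("ab", [("a", "b")])
        est = estimates_from({("a", "b"): -1.2})
        nodes = solve_node_dg(net, est, "a", -10.0)
        assert nodes.dg["a"] == -10.0
        assert nodes.dg["b"] == pytest.approx(-11.2, abs=1e-10)
        assert nodes.stderr["a"] == 0.0

    def test_consistent_triangle_exact_recovery(self):
        truth = {"a": -9.0, "b": -10.5, "c": -8.2}
        net = make_network("abc", [("a", "b"), ("b", "c")], [("a", "c")])
        est = estimates_from(
            {e: truth[e[1]] - truth[e[0]] for e in net.edges}
        )
        nodes = solve_node_dg(net, est, "a", truth["a"])
        for n, v in truth.items():
            assert nodes.dg[n] == pytest.approx(v, abs=1e-10)

    def test_matches_constrained_normal_equations_oracle(self):
        # independent oracle: full KKT system with an explicit Lagrange
        # constraint pinning the anchor, solved densely
        rng = np.random.default_rng(42)
        for trial in range(5):
            n = rng.integers(4, 9)
            names = [f"n{k}" for k in range(n)]
            tree = [(names[k], names[k + 1]) for k in range(n - 1)]
            extra_pool = [
                (names[i], names[j])
                for i in range(n)
                for j in range(i + 2, n)
            ]
            k_extra = min(len(extra_pool), int(rng.integers(1, 4)))
            picks = rng.choice(len(extra_pool), size=k_extra, replace=False)
            closure = [extra_pool[p] for p in picks]
            net = make_network(names, tree, closure)
            means = {e: float(rng.normal(0, 2)) for e in net.edges}
            sems = {e: float(rng.uniform(0.05, 0.5)) for e in net.edges}
            est = {
                e: EdgeEstimate(edge=e, replicates=(means[e],), mean=means[e], sem=sems[e])
                for e in net.edges
            }
            anchor, anchor_value = names[0], -10.0

            idx = {m: k for k, m in enumerate(sorted(names))}
            edges = sorted(net.edges)
            a_full = np.zeros((len(edges), n))
            b = np.array([means[e] for e in edges])
            w = np.array([1.0 / max(sems[e], SIGMA_FLOOR) for e in edges])
            for row, (u, v) in enumerate(edges):
                a_full[row, idx[u]] = -1.0
                a_full[row, idx[v]] = 1.0
            aw = a_full * w[:, None]
            kkt = np.zeros((n + 1, n + 1))
            kkt[:n, :n] = aw.T @ aw
            kkt[n, idx[anchor]] = 1.0
            kkt[idx[anchor], n] = 1.0
            rhs = np.concatenate([aw.T @ (b * w), [anchor_value]])
            x = np.linalg.solve(kkt, rhs)

            nodes = solve_node_dg(net, est, anchor, anchor_value)
            for m in names:
                assert nodes.dg[m] == pytest.approx(x[idx[m]], abs=1e-8)

    def test_bad_anchor_rejected(self, network18):
        est = estimates_from({e: 0.0 for e in network18.edges})
        with pytest.raises(ValueError, match="anchor"):
            solve_node_dg(network18, est, "nope", 0.0)


class TestCorrectedEdges:
    def _noisy_instance(self, seed=0):
        rng = np.random.default_rng(seed)
        names = list("abcdef")
        tree = [(names[k], names[k + 1]) for k in range(5)]
        closure = [("a", "c"), ("b", "e"), ("a", "f")]
        net = make_network(names, tree, closure)
        est = estimates_from(
            {e: float(rng.normal(0, 1.5)) for e in net.edges}, sem=0.2
        )
        return net, est

    def test_consistent_input_zero_residuals(self):
        truth = {"a": 0.0, "b": 1.0, "c": -2.0}
        net = make_network("abc", [("a", "b"), ("b", "c")], [("a", "c")])
        est = estimates_from({e: truth[e[1]] - truth[e[0]] for e in net.edges})
        nodes = solve_node_dg(net, est, "a", 0.0)
        corr = corrected_edge_values(net, nodes, est)
        for entry in corr.values():
            assert entry["residual"] == pytest.approx(0.0, abs=1e-10)

    def test_corrected_hysteresis_zero_on_all_cycles(self):
        net, est = self._noisy_instance()
        nodes = solve_node_dg(net, est, "a", -10.0)
        report = cycle_report(net, est, nodes)
        assert any(abs(h) > 1e-6 for h in report.hysteresis_raw)  # genuinely noisy
        for h in report.hysteresis_corrected:
            assert abs(h) < 1e-9

    def test_inflated_sem_moves_edge_toward_cycle_consensus(self):
        # a deliberately inconsistent closure edge gets pulled toward the
        # value implied by the rest of the cycle; the more uncertain it
        # is, the further it moves
        net = make_network("abc", [("a", "b"), ("b", "c")], [("a", "c")])
        means = {("a", "b"): 1.0, ("b", "c"): 1.0, ("a", "c"): 3.0}
        consensus = 2.0  # value of a->c implied by the tree path

        def corrected_ac(sem_ac):
            est = {
                e: EdgeEstimate(edge=e, replicates=(m,), mean=m, sem=0.1 if e != ("a", "c") else sem_ac)
                for e, m in means.items()
            }
            nodes = solve_node_dg(net, est, "a", 0.0)
            return corrected_edge_values(net, nodes)[("a", "c")]["corrected"]

        tight = corrected_ac(0.1)
        loose = corrected_ac(1.0)
        assert abs(loose - consensus) < abs(tight - consensus)


class TestGaugeProperties:
    def test_anchor_value_shift_is_uniform(self, network18):
        rng = np.random.default_rng(5)
        est = estimates_from(
            {e: float(rng.normal(0, 1)) for e in network18.edges}, sem=0.2
        )
        anchor = network18.nodes[0]
        base = solve_node_dg(network18, est, anchor, -10.0)
        shifted = solve_node_dg(network18, est, anchor, -7.5)
        for n in network18.nodes:
            assert shifted.dg[n] - base.dg[n] == pytest.approx(2.5, abs=1e-9)
            assert shifted.stderr[n] == pytest.approx(base.stderr[n], abs=1e-12)

    def test_anchor_change_is_pure_gauge(self, network18):
        rng = np.random.default_rng(6)
        est = estimates_from(
            {e: float(rng.normal(0, 1)) for e in network18.edges}, sem=0.2
        )
        n1, n2 = network18.nodes[0], network18.nodes[5]
        sol1 = solve_node_dg(network18, est, n1, 0.0)
        sol2 = solve_node_dg(network18, est, n2, 0.0)
        offsets = {n: sol1.dg[n] - sol2.dg[n] for n in network18.nodes}
        vals = list(offsets.values())
        assert max(vals) - min(vals) < 1e-9
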