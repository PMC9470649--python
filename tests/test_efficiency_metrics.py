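import numpy as np
import pytest

from rotornet.efficiency_metrics import (
    EfficiencyCurve,
    default_q_grid,
    efficiency_curve,
    local_efficiency,
    window_derivative,
)
from rotornet.mi_graph import MIMatrix, adjacency_at_fraction


def local_efficiency_oracle(adj):
    """Exhaustive oracle: pure-python BFS inside each neighbour-induced
    subgraph, summing inverse path lengths over ordered neighbour pairs."""
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        idx = {v: a for a, v in enumerate(nbrs)}
        total = 0.0
        for s in nbrs:
            # BFS from s restricted to nbrs
            dist = {s: 0}
            queue = [s]
            while queue:
                u = queue.pop(0)
                for v in nbrs:
                    if adj[u, v] and v not in dist:
                        dist[v] = dist[u] + 1
                        queue.append(v)
            for t in nbrs:
                if t != s and t in dist:
                    total += 1.0 / dist[t]
        out[i] = total / (k * (k - 1))
    return out, out.mean()


def _er_graph(rng, n, p):
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    return a | a.T


class TestLocalEfficiency:
    def test_complete_graph_is_one(self):
        for n in (3, 5, 9):
            adj = ~np.eye(n, dtype=bool)
            per_node, mean = local_efficiency(adj)
            np.testing.assert_allclose(per_node, 1.0)
            assert mean == 1.0

    def test_star_graph_is_zero(self):
        n = 7
        adj = np.zeros((n, n), dtype=bool)
        adj[0, 1:] = adj[1:, 0] = True
        per_node, mean = local_efficiency(adj)
        np.testing.assert_array_equal(per_node, 0.0)
        assert mean == 0.0

    def test_empty_graph_is_zero(self):
        _, mean = local_efficiency(np.zeros((6, 6), dtype=bool))
        assert mean == 0.0

    def test_five_node_example_against_oracle(self):
        edges = [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3), (3, 4)]
        adj = np.zeros((5, 5), dtype=bool)
        for i, j in edges:
            adj[i, j] = adj[j, i] = True
        per_node, mean = local_efficiency(adj)
        oracle_nodes, oracle_mean = local_efficiency_oracle(adj)
        np.testing.assert_allclose(per_node, oracle_nodes, atol=1e-15)
        assert mean == pytest.approx(oracle_mean, abs=1e-15)

    def test_matches_oracle_on_random_graphs(self, rng):
        """Exact agreement with the exhaustive BFS oracle on 200 random
        Erdos-Renyi graphs spanning all densities."""
        for trial in range(200):
            n = int(rng.integers(3, 13))
            p = rng.random()
            adj = _er_graph(rng, n, p)
            per_node, mean = local_efficiency(adj)
            oracle_nodes, oracle_mean = local_efficiency_oracle(adj)
            np.testing.assert_allclose(per_node, oracle_nodes, atol=1e-12)
            assert mean == pytest.approx(oracle_mean, abs=1e-12)

    def test_matches_networkx_cross_check(self, rng):
        import networkx as nx

        for _ in range(20):
            adj = _er_graph(rng, 10, 0.4)
            _, mean = local_efficiency(adj)
            g = nx.from_numpy_array(adj)
            assert mean == pytest.approx(nx.local_efficiency(g), abs=1e-12)

    def test_permutation_invariance_of_mean(self, rng):
        adj = _er_graph(rng, 12, 0.3)
        perm = rng.permutation(12)
        per_node, mean = local_efficiency(adj)
        per_node_p, mean_p = local_efficiency(adj[np.ix_(perm, perm)])
        assert mean_p == pytest.approx(mean, abs=1e-15)
        np.testing.assert_allclose(per_node_p, per_node[perm], atol=1e-15)

    def test_invalid_input_rejected(self):
        asym = np.zeros((4, 4), dtype=bool)
        asym[0, 1] = True
        with pytest.raises(ValueError):
            local_efficiency(asym)
        looped = np.eye(4, dtype=bool)
        with pytest.raises(ValueError):
            local_efficiency(looped)


class TestEfficiencyCurve:
    def _random_mi(self, rng, n=48):
        a = np.triu(rng.random((n, n)), 1)
        return MIMatrix(values=a + a.T, n_samples=100)

    def test_values_in_unit_interval_and_last_is_one(self, rng):
        mi = self._random_mi(rng)
        curve = efficiency_curve(mi)
        assert curve.q_grid[-1] == 100.0
        assert np.all(curve.mean_local_efficiency >= 0.0)
        assert np.all(curve.mean_local_efficiency <= 1.0)
        assert curve.mean_local_efficiency[-1] == 1.0  # complete graph

    def test_tied_matrix_curve_reproduced_by_oracle(self):
        """With an all-equal MI matrix the curve is fully determined by the
        lexicographic tie rule; replay it point by point with the BFS oracle
        on explicitly constructed top-k graphs."""
        n = 20
        mi = MIMatrix(values=np.ones((n, n)), n_samples=10)
        q_grid = np.arange(10.0, 101.0, 10.0)
        curve = efficiency_curve(mi, q_grid)
        iu, ju = np.triu_indices(n, 1)
        n_pairs = iu.size
        for q, got in zip(q_grid, curve.mean_local_efficiency):
            k = int(np.ceil(q / 100.0 * n_pairs))
            adj = np.zeros((n, n), dtype=bool)
            adj[iu[:k], ju[:k]] = True
            adj |= adj.T
            _, expected = local_efficiency_oracle(adj)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_default_grid(self):
        q = default_q_grid()
        assert q[0] == 2.0 and q[-1] == 100.0 and len(q) == 50

    def test_invalid_grids_rejected(self, rng):
        mi = self._random_mi(rng)
        with pytest.raises(ValueError):
            efficiency_curve(mi, np.array([10.0, 20.0]))
        with pytest.raises(ValueError):
            efficiency_curve(mi, np.linspace(0.0, 100.0, 20))


class TestWindowDerivative:
    def _curve_from_poly(self, coeffs, q=None):
        q = default_q_grid() if q is None else q
        vals = np.polynomial.polynomial.polyval(q, coeffs)
        vals = np.clip(vals, 0.0, 1.0)
        poly = np.polynomial.Polynomial.fit(q, vals, 3)
        return EfficiencyCurve(
            q_grid=q, mean_local_efficiency=vals, poly=poly, fit_residual=0.0
        )

    def test_constant_curve_gives_zero(self):
        curve = self._curve_from_poly([0.5])
        assert window_derivative(curve) == pytest.approx(0.0, abs=1e-12)

    def test_linear_curve_recovers_slope(self):
        b = 0.004
        curve = self._curve_from_poly([0.1, b])
        assert window_derivative(curve) == pytest.approx(b, abs=1e-10)

    def test_cubic_closed_form_and_quadrature(self):
        coeffs = np.array([0.0, 0.01, -1e-4, 1e-6])
        curve = self._curve_from_poly(coeffs)
        p = np.polynomial.Polynomial(coeffs)
        expected = (p(80.0) - p(40.0)) / 40.0
        got = window_derivative(curve, (40.0, 80.0))
        assert got == pytest.approx(expected, abs=1e-10)
        # independent check: numeric quadrature of the analytic derivative
        from scipy.integrate import quad

        integral, _ = quad(lambda q: p.deriv()(q), 40.0, 80.0)
        assert got == pytest.approx(integral / 40.0, abs=1e-10)

    def test_degenerate_window_rejected(self):
        curve = self._curve_from_poly([0.1, 0.001])
        with pytest.raises(ValueError):
            window_derivative(curve, (80.0, 40.0))
        with pytest.raises(ValueError):
            window_derivative(curve, (40.0, 120.0))
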