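import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rotornet.catheter_sampling import CatheterPlacement, build_geometry, sample_electrodes
from rotornet.mi_graph import (
    MIMatrix,
    adjacency_at_fraction,
    mi_matrix,
    mutual_information,
)


def mi_oracle(x, y):
    """Independent oracle: enumerate the 2x2 joint counts and evaluate the
    sample-average form (1/N) sum_i ln p(x_i, y_i) / (p(x_i) p(y_i))."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    n = x.size
    joint = {}
    for a, b in zip(x, y):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    px = {v: np.mean(x == v) for v in (0, 1)}
    py = {v: np.mean(y == v) for v in (0, 1)}
    total = 0.0
    for xi, yi in zip(x, y):
        pj = joint[(xi, yi)] / n
        total += np.log(pj / (px[xi] * py[yi]))
    return total / n


class TestMutualInformation:
    def test_self_information_is_entropy_of_fair_coin(self):
        x = np.tile([0, 1], 500)
        assert mutual_information(x, x) == pytest.approx(np.log(2), abs=1e-12)

    def test_constant_signal_gives_zero(self, rng):
        x = np.zeros(200, dtype=int)
        y = rng.integers(0, 2, 200)
        assert mutual_information(x, y) == 0.0

    def test_known_eight_sample_pair(self):
        x = np.array([0, 0, 1, 1, 0, 1, 0, 1])
        y = np.array([0, 1, 1, 1, 0, 0, 0, 1])
        # joint counts n00=3, n01=1, n10=1, n11=3
        expected = (
            2 * (3 / 8) * np.log((3 / 8) / (0.5 * 0.5))
            + 2 * (1 / 8) * np.log((1 / 8) / (0.5 * 0.5))
        )
        assert mutual_information(x, y) == pytest.approx(expected, abs=1e-12)
        assert mutual_information(x, y) == pytest.approx(mi_oracle(x, y), abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_sample_average_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 64))
        x = rng.integers(0, 2, n)
        y = rng.integers(0, 2, n)
        assert mutual_information(x, y) == pytest.approx(mi_oracle(x, y), abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_nonnegativity_relabel_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, 50)
        y = rng.integers(0, 2, 50)
        mi = mutual_information(x, y)
        assert mi == mutual_information(y, x)
        assert mi >= 0.0
        assert mi == pytest.approx(mutual_information(1 - x, 1 - y), abs=1e-12)

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0, 1, 1])
        with pytest.raises(ValueError):
            mutual_information([], [])

    def test_independence_limit(self):
        rng = np.random.default_rng(99)
        x = rng.integers(0, 2, 100_000)
        y = rng.integers(0, 2, 100_000)
        assert mutual_information(x, y) <= 0.01


class TestMIMatrix:
    def test_identical_rows_give_ln2_offdiagonal(self):
        row = np.tile([0, 1], 100)
        sig = np.tile(row, (48, 1))
        mi = mi_matrix(sig)
        off = mi.values[~np.eye(48, dtype=bool)]
        np.testing.assert_allclose(off, np.log(2), atol=1e-12)

    def test_diagonal_is_entropy(self, rng):
        sig = rng.integers(0, 2, (48, 300))
        mi = mi_matrix(sig)
        for i in range(0, 48, 7):
            p = sig[i].mean()
            h = 0.0
            for pv in (p, 1 - p):
                if pv > 0:
                    h -= pv * np.log(pv)
            assert mi.values[i, i] == pytest.approx(h, abs=1e-12)

    def test_matches_pairwise_function(self, rng):
        sig = rng.integers(0, 2, (48, 120))
        mi = mi_matrix(sig)
        for i, j in [(0, 1), (5, 40), (17, 17), (30, 2)]:
            assert mi.values[i, j] == pytest.approx(
                mutual_information(sig[i], sig[j]), abs=1e-12
            )

    def test_exactly_symmetric(self, rng):
        sig = rng.integers(0, 2, (48, 500))
        mi = mi_matrix(sig)
        np.testing.assert_array_equal(mi.values, mi.values.T)

    def test_independent_rows_vanish_with_length(self):
        rng = np.random.default_rng(3)
        sig = rng.integers(0, 2, (8, 100_000))
        mi = mi_matrix(sig)
        off = mi.values[~np.eye(8, dtype=bool)]
        assert off.max() <= 0.01

    def test_spiral_fixture_same_spline_neighbors_elevated(self, spiral_movie):
        geom = build_geometry("grid")
        sig = sample_electrodes(spiral_movie, geom, CatheterPlacement((9.45, 9.45)))
        mi = mi_matrix(sig)
        vals = mi.values.copy()
        np.fill_diagonal(vals, np.nan)
        neighbor_pairs = [(r * 8 + c, r * 8 + c + 1) for r in range(6) for c in range(7)]
        neighbor_mi = np.mean([vals[i, j] for i, j in neighbor_pairs])
        assert neighbor_mi > np.nanmedian(vals)


class TestAdjacency:
    def _random_mi(self, rng, n=48):
        a = rng.random((n, n))
        a = np.triu(a, 1)
        a = a + a.T
        return MIMatrix(values=a, n_samples=100)

    def test_full_fraction_gives_complete_graph(self, rng):
        mi = self._random_mi(rng)
        adj = adjacency_at_fraction(mi, 100.0)
        assert adj.n_edges == 1128
        expected = ~np.eye(48, dtype=bool)
        np.testing.assert_array_equal(adj.matrix, expected)

    def test_ten_percent_gives_113_edges_of_top_rank(self, rng):
        mi = self._random_mi(rng)
        adj = adjacency_at_fraction(mi, 10.0)
        assert adj.n_edges == 113  # ceil(0.10 * 1128)
        assert adj.matrix.sum() == 2 * 113
        # brute-force oracle: sort all 1128 pair values, keep the top 113
        iu, ju = np.triu_indices(48, 1)
        vals = mi.values[iu, ju]
        cutoff = np.sort(vals)[::-1][112]
        picked = mi.values[adj.matrix]
        assert picked.min() >= cutoff

    def test_total_ties_resolved_lexicographically(self):
        mi = MIMatrix(values=np.ones((48, 48)), n_samples=10)
        adj = adjacency_at_fraction(mi, 10.0)
        iu, ju = np.triu_indices(48, 1)
        expected = np.zeros((48, 48), dtype=bool)
        expected[iu[:113], ju[:113]] = True
        expected |= expected.T
        np.testing.assert_array_equal(adj.matrix, expected)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=15, deadline=None)
    def test_monotone_nesting_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        mi = self._random_mi(rng, n=16)
        qs = [5.0, 20.0, 55.0, 100.0]
        adjs = [adjacency_at_fraction(mi, q) for q in qs]
        for small, big in zip(adjs, adjs[1:]):
            assert not (small.matrix & ~big.matrix).any()  # edge sets nested
        scaled = MIMatrix(values=mi.values * 7.5, n_samples=mi.n_samples)
        for q, adj in zip(qs, adjs):
            np.testing.assert_array_equal(
                adjacency_at_fraction(scaled, q).matrix, adj.matrix
            )

    def test_out_of_range_fraction_rejected(self, rng):
        mi = self._random_mi(rng)
        for q in (0.0, -5.0, 100.1):
            with pytest.raises(ValueError):
                adjacency_at_fraction(mi, q)
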