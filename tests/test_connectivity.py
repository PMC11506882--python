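import math
from collections import Counter

import numpy as np
import pytest

from cstgat import (
    CausalMatrix,
    DiscretizationParams,
    TEParams,
    build_graph,
    causal_matrix,
    discretize,
    functional_connectivity,
    granger_causality,
    ground_truth_adjacency,
    mutual_information,
    shannon_entropy,
    simulate_var,
    te_matrix,
    transfer_entropy,
)


def brute_force_te(source, target, k, l, lag=1):
    """Independent oracle: enumerate (x_{i+1}, x_i^{(k)}, y^{(l)}) tuples with
    explicit dictionaries of joint counts and evaluate the TE sum directly."""
    x, y = list(target), list(source)
    n = len(x)
    start = max(k - 1, lag + l - 2)
    joint, c_xky, c_fxk, c_xk = Counter(), Counter(), Counter(), Counter()
    obs = []
    for i in range(start, n - 1):
        xf = x[i + 1]
        xk = tuple(x[i - j] for j in range(k))
        yl = tuple(y[i + 1 - lag - j] for j in range(l))
        obs.append((xf, xk, yl))
        joint[(xf, xk, yl)] += 1
        c_xky[(xk, yl)] += 1
        c_fxk[(xf, xk)] += 1
        c_xk[xk] += 1
    m = len(obs)
    te = 0.0
    for (xf, xk, yl), cnt in joint.items():
        p = cnt / m
        p_cond_full = cnt / c_xky[(xk, yl)]
        p_cond_own = c_fxk[(xf, xk)] / c_xk[xk]
        te += p * math.log2(p_cond_full / p_cond_own)
    return max(te, 0.0)


class TestDiscretize:
    def test_equal_width_midpoint_split(self):
        out = discretize(np.array([0.0, 1.0, 2.0, 3.0]), DiscretizationParams(n_bins=2))
        assert out.tolist() == [0, 0, 1, 1]

    def test_constant_series_degenerates(self):
        for strategy in ("equal-width", "equal-frequency"):
            out = discretize(np.full(10, 3.3), DiscretizationParams(n_bins=4, strategy=strategy))
            assert out.tolist() == [0] * 10

    def test_equal_frequency_balances_counts(self, rng):
        x = rng.normal(size=1000)
        out = discretize(x, DiscretizationParams(n_bins=4, strategy="equal-frequency"))
        assert np.bincount(out).tolist() == [250, 250, 250, 250]

    def test_edge_tie_goes_to_lower_bin(self):
        # interior edge of [0, 3] with 2 bins is 1.5 exactly
        out = discretize(np.array([0.0, 1.5, 3.0]), DiscretizationParams(n_bins=2))
        assert out.tolist() == [0, 0, 1]


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "symbols,expected",
        [([5, 5, 5, 5], 0.0), ([0, 1, 0, 1], 1.0), ([0, 0, 0, 1], 0.8112781244591328)],
    )
    def test_known_values(self, symbols, expected):
        assert shannon_entropy(np.array(symbols)) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_log_alphabet(self, rng):
        s = rng.integers(0, 5, 400)
        h = shannon_entropy(s)
        assert 0.0 <= h <= np.log2(5)


class TestTransferEntropy:
    def test_constant_target_gives_zero(self, rng):
        src = rng.integers(0, 2, 500)
        tgt = np.zeros(500, dtype=int)
        p = TEParams(k=1, l=1, lag=1)
        assert transfer_entropy(src, tgt, p) == 0.0

    def test_copy_chain_closed_form(self):
        rng = np.random.default_rng(2024)
        src = rng.integers(0, 2, 100_000)
        tgt = np.empty_like(src)
        tgt[0] = 0
        tgt[1:] = src[:-1]
        p = TEParams(k=1, l=1, lag=1)
        assert transfer_entropy(src, tgt, p) == pytest.approx(1.0, abs=0.02)
        assert transfer_entropy(tgt, src, p) < 0.02

    @pytest.mark.parametrize("k,l", [(1, 1), (1, 2), (2, 1), (2, 2)])
    def test_matches_brute_force_oracle(self, k, l, rng):
        for _ in range(12):
            n = int(rng.integers(50, 2000))
            src = rng.integers(0, 3, n)
            tgt = rng.integers(0, 3, n)
            p = TEParams(k=k, l=l, lag=1)
            assert transfer_entropy(src, tgt, p) == pytest.approx(
                brute_force_te(src, tgt, k, l), abs=1e-12
            )

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError, match="equal length"):
            transfer_entropy(np.zeros(10, int), np.zeros(11, int), TEParams())

    def test_too_short_error(self):
        with pytest.raises(ValueError, match="too short"):
            transfer_entropy(np.zeros(3, int), np.zeros(3, int), TEParams(k=1, l=1, lag=1))

    def test_noise_on_source_never_helps(self, single_edge_spec, default_te_params):
        """Data-processing sanity: corrupting the source with noise of
        growing variance does not increase mean TE (monotone trend)."""
        noise_levels = [0.0, 1.0, 3.0]
        means = []
        for sd in noise_levels:
            vals = []
            for seed in range(50):
                x = simulate_var(single_edge_spec, 2048, seed=seed)
                rng = np.random.default_rng(10_000 + seed)
                src = x[0] + rng.normal(0, sd, x.shape[1])
                d = default_te_params.discretization
                vals.append(
                    transfer_entropy(discretize(src, d), discretize(x[1], d), default_te_params)
                )
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]


class TestTEMatrix:
    def test_constant_channels_zero_matrix(self):
        w = np.ones((2, 256))
        m = te_matrix(w)
        assert np.array_equal(m.values, np.zeros((2, 2)))

    def test_entries_equal_pairwise_calls(self, rng, default_te_params):
        w = rng.normal(size=(3, 400))
        m = te_matrix(w, default_te_params)
        d = default_te_params.discretization
        syms = [discretize(w[i], d) for i in range(3)]
        for s in range(3):
            for t in range(3):
                if s != t:
                    assert m.values[s, t] == transfer_entropy(syms[s], syms[t], default_te_params)
        assert np.all(np.diag(m.values) == 0)

    def test_single_edge_is_largest_entry_in_most_seeds(self, single_edge_spec):
        truth = ground_truth_adjacency(single_edge_spec)
        hits = 0
        for seed in range(30):
            x = simulate_var(single_edge_spec, 4096, seed=seed)
            v = te_matrix(x).values
            np.fill_diagonal(v, -np.inf)
            hits += np.unravel_index(np.argmax(v), v.shape) == tuple(np.argwhere(truth)[0])
        assert hits >= 28

    def test_channel_permutation_permutes_matrix(self, rng, default_te_params):
        w = rng.normal(size=(4, 300))
        perm = np.array([2, 0, 3, 1])
        m = te_matrix(w, default_te_params).values
        mp = te_matrix(w[perm], default_te_params).values
        assert np.allclose(mp, m[np.ix_(perm, perm)])


class TestComparisonMethods:
    def test_granger_independent_noise_near_zero(self, rng):
        x = rng.normal(size=4096)
        y = rng.normal(size=4096)
        assert granger_causality(x, y, order=2) < 0.01

    def test_granger_recovers_direction(self, rng):
        x = rng.normal(size=4096)
        y = np.zeros(4096)
        y[1:] = 0.9 * x[:-1]
        y += 0.1 * rng.normal(size=4096)
        assert granger_causality(x, y, 2) > granger_causality(y, x, 2)

    def test_granger_constant_source_zero(self, rng):
        y = rng.normal(size=512)
        assert granger_causality(np.ones(512), y, 2) == pytest.approx(0.0, abs=1e-10)

    def test_mi_identity_equals_entropy(self, rng):
        x = rng.normal(size=2000)
        d = DiscretizationParams(n_bins=8)
        assert mutual_information(x, x, d) == pytest.approx(shannon_entropy(discretize(x, d)), abs=1e-12)

    def test_mi_independent_small(self, rng):
        x = rng.integers(0, 2, 100_000).astype(float)
        y = rng.integers(0, 2, 100_000).astype(float)
        assert mutual_information(x, y, DiscretizationParams(n_bins=2)) < 0.01

    def test_mi_symmetric(self, rng):
        x, y = rng.normal(size=(2, 1500))
        d = DiscretizationParams(n_bins=6)
        assert mutual_information(x, y, d) == pytest.approx(mutual_information(y, x, d), abs=1e-12)

    @pytest.mark.parametrize("transform,expected", [(lambda x: 2 * x + 3, 1.0), (lambda x: -x, 1.0)])
    def test_fc_affine_and_sign(self, rng, transform, expected):
        x = rng.normal(size=500)
        assert functional_connectivity(x, transform(x)) == pytest.approx(expected, abs=1e-12)

    def test_fc_independent_small(self, rng):
        x, y = rng.normal(size=(2, 10_000))
        assert functional_connectivity(x, y) < 0.05

    def test_fc_zero_variance_returns_zero(self, rng):
        assert functional_connectivity(np.ones(100), rng.normal(size=100)) == 0.0

    def test_symmetric_methods_yield_symmetric_matrices(self, single_edge_spec):
        x = simulate_var(single_edge_spec, 2048, seed=0)
        for method in ("FC", "MI"):
            m = causal_matrix(x, method=method)
            assert m.symmetric
            assert np.array_equal(m.values, m.values.T)
        for method in ("TE", "GC"):
            assert not causal_matrix(x, method=method).symmetric


class TestBuildGraph:
    def _matrix(self, values):
        return CausalMatrix(values=np.asarray(values, dtype=float), method="TE")

    def test_threshold_above_max_gives_empty_graph(self):
        m = self._matrix([[0, 0.5], [0.2, 0]])
        g = build_graph(m, sparsify="threshold", parameter=1.0, self_loops=False)
        assert g.adjacency.sum() == 0

    def test_top_k_in_keeps_column_maxima(self):
        m = self._matrix([[0, 0.5, 0.1], [0.2, 0, 0.4], [0.3, 0.6, 0]])
        g = build_graph(m, sparsify="top_k_in", parameter=1, self_loops=False)
        assert {(2, 0), (2, 1), (1, 2)} == set(map(tuple, np.argwhere(g.adjacency)))

    def test_density_one_keeps_all_offdiagonal(self, rng):
        v = rng.random((4, 4))
        np.fill_diagonal(v, 0)
        g = build_graph(self._matrix(v), sparsify="density", parameter=1.0, self_loops=False)
        assert g.adjacency.sum() == 12

    def test_self_loops_added_after_sparsify(self):
        m = self._matrix([[0, 0.5], [0.2, 0]])
        g = build_graph(m, sparsify="top_k_in", parameter=1, self_loops=True)
        assert np.all(np.diag(g.adjacency) == 1)
        assert np.all(np.diag(g.edge_weights) == 0)

    def test_weights_retained_only_on_kept_edges(self):
        m = self._matrix([[0, 0.5, 0.1], [0.2, 0, 0.4], [0.3, 0.6, 0]])
        g = build_graph(m, sparsify="top_k_in", parameter=1, self_loops=False)
        assert g.edge_weights[2, 1] == 0.6
        assert g.edge_weights[0, 1] == 0.0

    def test_invalid_parameters_rejected(self):
        m = self._matrix(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="top_k_in"):
            build_graph(m, sparsify="top_k_in", parameter=3)
        with pytest.raises(ValueError, match="density"):
            build_graph(m, sparsify="density", parameter=1.5)
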