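import numpy as np
import pytest

from mariagait import tica_net as tn


def _weights(n_maps=2, tile_k=2, rf_s=3, n_channels=1, seed=0):
    return tn.init_tiled_weights(n_maps, tile_k, rf_s, n_channels, seed=seed)


def _structure(patch=(6, 6, 1), n_maps=2, tile_k=2, rf_s=3):
    return tn.TilingStructure(patch, n_maps, tile_k, rf_s)


# ---------------------------------------------------------------------------
# tiled convolution

def _conv_oracle(x, weights):
    """Brute-force sliding dot product honoring the mod-k tying rule."""
    H, W, C = x.shape
    s, L = weights.rf_s, weights.n_maps
    Ho, Wo = H - s + 1, W - s + 1
    out = np.zeros((Ho, Wo, L))
    for l in range(L):
        for u in range(Ho):
            for v in range(Wo):
                out[u, v, l] = np.sum(x[u:u + s, v:v + s, :]
                                      * weights.bank(l, u, v))
    return out


class TestTiledConvForward:
    def test_k1_equals_standard_convolution(self, rng):
        for i in range(20):
            w = tn.init_tiled_weights(2, 1, 3, 2, seed=i)
            x = rng.standard_normal((6, 7, 2))
            got = tn.tiled_conv_forward(x, w)
            assert np.max(np.abs(got - _conv_oracle(x, w))) < 1e-10

    def test_k2_matches_oracle(self, rng):
        for i in range(20):
            w = tn.init_tiled_weights(3, 2, 3, 1, seed=100 + i)
            x = rng.standard_normal((8, 8, 1))
            got = tn.tiled_conv_forward(x, w)
            assert np.max(np.abs(got - _conv_oracle(x, w))) < 1e-10

    def test_zero_input_zero_maps(self):
        w = _weights()
        out = tn.tiled_conv_forward(np.zeros((6, 6, 1)), w)
        assert np.all(out == 0)

    def test_1d_tying_toy_case(self):
        # k=2, rf 1, banks w0=[1], w1=[2], input [1,0,0,1] -> [1,0,0,2]
        banks = np.zeros((1, 2, 2, 1, 1, 1))
        banks[0, 0, 0] = 1.0
        banks[0, 0, 1] = 2.0
        w = tn.TiledWeights(banks=banks, tile_k=2, rf_s=1, n_maps=1)
        x = np.array([1.0, 0.0, 0.0, 1.0]).reshape(1, 4, 1)
        assert tn.tiled_conv_forward(x, w).ravel().tolist() == [1, 0, 0, 2]

    def test_dense_projection_reduction(self, rng):
        # tile as large as the input and rf covering it: one unit per map,
        # equal to a plain matrix-vector product
        w = tn.init_tiled_weights(3, 4, 4, 2, seed=5)
        x = rng.standard_normal((4, 4, 2))
        got = tn.tiled_conv_forward(x, w).ravel()
        W = np.array([w.banks[l, 0, 0].ravel() for l in range(3)])
        assert np.allclose(got, W @ x.ravel(), atol=1e-12)

    def test_rf_larger_than_input_rejected(self):
        w = _weights(rf_s=5)
        with pytest.raises(ValueError):
            tn.tiled_conv_forward(np.zeros((4, 4, 1)), w)

    def test_tying_invariant_effective_rows(self):
        w = _weights(n_maps=2, tile_k=2, rf_s=2)
        shape = (6, 6, 1)
        for l in range(2):
            a = w.effective_row(l, 0, 1, shape)
            b = w.effective_row(l, 2, 3, shape)
            # same bank, shifted support: nonzero values identical
            assert np.array_equal(np.sort(a[a != 0]), np.sort(b[b != 0]))
            # zero outside the receptive field
            grid = a.reshape(shape)
            assert np.all(grid[2:, :, :] == 0)

    def test_batched_matches_single(self, rng):
        w = _weights()
        xs = rng.standard_normal((4, 6, 6, 1))
        batched = tn.tiled_conv_forward(xs, w)
        for i in range(4):
            assert np.allclose(batched[i], tn.tiled_conv_forward(xs[i], w))


class TestBankGradient:
    def test_matches_finite_differences(self, rng):
        w = _weights(n_maps=2, tile_k=2, rf_s=2)
        x = rng.standard_normal((2, 5, 5, 1))
        d_out = rng.standard_normal((2, 4, 4, 2))
        grad = tn.tiled_conv_bank_gradient(x, w, d_out)
        h = 1e-6
        flat_idx = [(0, 0, 1, 1, 0, 0), (1, 1, 0, 0, 1, 0)]
        for idx in flat_idx:
            wp = tn.TiledWeights(w.banks.copy(), w.tile_k, w.rf_s, w.n_maps)
            wp.banks[idx] += h
            wm = tn.TiledWeights(w.banks.copy(), w.tile_k, w.rf_s, w.n_maps)
            wm.banks[idx] -= h
            fd = (np.sum(d_out * tn.tiled_conv_forward(x, wp))
                  - np.sum(d_out * tn.tiled_conv_forward(x, wm))) / (2 * h)
            assert grad[idx] == pytest.approx(fd, rel=1e-5)


# ---------------------------------------------------------------------------
# pooling topology

class TestPoolingTopology:
    def test_matrix_row_sums(self):
        topo = tn.PoolingTopology(grid=(4, 4), n_maps=2, radius=1)
        V = topo.matrix()
        assert V.shape == (32, 32)
        assert np.all(V.sum(axis=1) == 9)  # 3x3 wrap-around neighborhood
        assert np.all((V == 0) | (V == 1))

    def test_apply_matches_matrix(self, rng):
        topo = tn.PoolingTopology(grid=(4, 5), n_maps=3, radius=1)
        e = rng.random((4, 5, 3))
        via_matrix = (topo.matrix() @ e.ravel()).reshape(4, 5, 3)
        assert np.allclose(topo.apply(e), via_matrix)

    def test_symmetric_operator(self):
        topo = tn.PoolingTopology(grid=(5, 5), n_maps=2, radius=1)
        V = topo.matrix()
        assert np.array_equal(V, V.T)

    def test_within_map_only(self):
        topo = tn.PoolingTopology(grid=(3, 3), n_maps=2, radius=1)
        e = np.zeros((3, 3, 2))
        e[1, 1, 0] = 1.0
        out = topo.apply(e)
        assert np.all(out[:, :, 1] == 0)
        assert out[:, :, 0].sum() == 9.0


# ---------------------------------------------------------------------------
# TICA activation / objective / gradient

class TestTicaActivation:
    def test_identity_pooling_absolute_value(self, rng):
        W = rng.standard_normal((4, 6))
        x = rng.standard_normal(6)
        p = tn.tica_activation(x, W, np.eye(4), epsilon=0.0)
        assert np.allclose(p, np.abs(W @ x))

    def test_hand_computed_example(self):
        W = np.eye(2)
        V = np.array([[1.0, 1.0], [0.0, 1.0]])
        p = tn.tica_activation(np.array([3.0, 4.0]), W, V, epsilon=0.0)
        assert np.allclose(p, [5.0, 4.0])

    def test_zero_input_sqrt_epsilon(self):
        W = np.eye(3)
        p = tn.tica_activation(np.zeros(3), W, np.eye(3), epsilon=0.04)
        assert np.allclose(p, 0.2)

    def test_tiled_weights_input(self, rng):
        w = _weights()
        topo = tn.PoolingTopology(grid=(4, 4), n_maps=2)
        x = rng.standard_normal((6, 6, 1))
        p = tn.tica_activation(x, w, topo, epsilon=1e-8)
        r = tn.tiled_conv_forward(x, w).ravel()
        expected = np.sqrt(1e-8 + topo.matrix() @ (r * r))
        assert np.allclose(p, expected)
        assert np.all(p >= 0)


class TestTicaObjective:
    def test_single_sample_is_activation_sum(self, rng):
        W = rng.standard_normal((4, 6))
        V = np.eye(4)
        x = rng.standard_normal(6)
        f = tn.tica_objective(x[None, :], W, V, epsilon=0.0)
        assert f == pytest.approx(tn.tica_activation(x, W, V, 0.0).sum())

    def test_positive_homogeneity(self, rng):
        W = rng.standard_normal((4, 6))
        V = np.eye(4)
        X = rng.standard_normal((5, 6))
        f1 = tn.tica_objective(X, W, V, epsilon=0.0)
        f3 = tn.tica_objective(3.0 * X, W, V, epsilon=0.0)
        assert f3 == pytest.approx(3.0 * f1)

    def test_zero_batch_zero_objective(self):
        W = np.eye(3)
        assert tn.tica_objective(np.zeros((4, 3)), W, np.eye(3), 0.0) == 0.0

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            tn.tica_objective(np.zeros((0, 3)), np.eye(3), np.eye(3))


class TestTicaGradient:
    def test_dense_matches_finite_differences(self, rng):
        eps, h = 1e-8, 1e-6
        for draw in range(10):
            r = np.random.default_rng(draw)
            T, m, n = 6, 5, 7
            X = r.standard_normal((T, n))
            W = r.standard_normal((m, n))
            V = (r.random((m, m)) < 0.4).astype(float)
            V[np.arange(m), np.arange(m)] = 1.0
            g = tn.tica_gradient(X, W, V, eps)
            fd = np.zeros_like(W)
            for i in range(m):
                for j in range(n):
                    Wp, Wm = W.copy(), W.copy()
                    Wp[i, j] += h
                    Wm[i, j] -= h
                    fd[i, j] = (tn.tica_objective(X, Wp, V, eps)
                                - tn.tica_objective(X, Wm, V, eps)) / (2 * h)
            assert np.linalg.norm(g - fd) / np.linalg.norm(fd) < 1e-5

    def test_bank_gradient_matches_finite_differences(self, rng):
        eps, h = 1e-8, 1e-6
        w = _weights(n_maps=2, tile_k=2, rf_s=3)
        patches = rng.standard_normal((8, 6, 6, 1))
        structure = _structure((6, 6, 1))
        V = structure.default_topology().matrix()
        g = tn.tica_gradient(patches, w, V, eps)

        def f(banks):
            return tn.tica_objective(
                patches.reshape(8, -1), structure.expand(banks), V, eps)

        fd = np.zeros_like(g)
        it = np.nditer(w.banks, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            bp, bm = w.banks.copy(), w.banks.copy()
            bp[idx] += h
            bm[idx] -= h
            fd[idx] = (f(bp) - f(bm)) / (2 * h)
        assert np.linalg.norm(g - fd) / np.linalg.norm(fd) < 1e-5

    def test_zero_batch_zero_gradient(self):
        g = tn.tica_gradient(np.zeros((4, 3)), np.eye(3), np.eye(3), 1e-8)
        assert np.allclose(g, 0.0)

    def test_doubled_batch_doubles_gradient(self, rng):
        X = rng.standard_normal((5, 6))
        W = rng.standard_normal((4, 6))
        V = np.eye(4)
        g1 = tn.tica_gradient(X, W, V, 1e-8)
        g2 = tn.tica_gradient(np.vstack([X, X]), W, V, 1e-8)
        assert np.allclose(g2, 2.0 * g1)

    def test_epsilon_zero_rejected(self):
        with pytest.raises(ValueError):
            tn.tica_gradient(np.ones((2, 3)), np.eye(3), np.eye(3), 0.0)


# ---------------------------------------------------------------------------
# projections

class TestProjections:
    def test_localize_zeroes_exterior(self, rng):
        st = _structure()
        W = rng.standard_normal((st.n_units, st.n_inputs))
        loc = tn.localize(W, st)
        for l in range(st.n_maps):
            for u in range(st.grid[0]):
                for v in range(st.grid[1]):
                    i = st.unit(l, u, v)
                    idx = st.rf_indices(u, v)
                    mask = np.ones(st.n_inputs, dtype=bool)
                    mask[idx] = False
                    assert np.all(loc[i, mask] == 0)
                    assert np.array_equal(loc[i, idx], W[i, idx])

    def test_localize_idempotent(self, rng):
        st = _structure()
        W = rng.standard_normal((st.n_units, st.n_inputs))
        once = tn.localize(W, st)
        assert np.array_equal(tn.localize(once, st), once)

    def test_tie_two_rows_mean(self):
        # 1-D-like: 2x2 patch, rf 1, k 1 -> all four units in one class
        st = tn.TilingStructure((2, 2, 1), n_maps=1, tile_k=1, rf_s=1)
        W = np.diag([1.0, 3.0, 5.0, 7.0])
        tied = tn.tie_weights(W, st)
        for u in range(2):
            for v in range(2):
                i = st.unit(0, u, v)
                assert tied[i, st.rf_indices(u, v)] == pytest.approx(4.0)

    def test_tie_idempotent(self, rng):
        st = _structure()
        W = st.localize(rng.standard_normal((st.n_units, st.n_inputs)))
        tied = tn.tie_weights(W, st)
        assert np.allclose(tn.tie_weights(tied, st), tied)

    def test_tied_output_satisfies_invariant(self, rng):
        st = _structure()
        W = st.localize(rng.standard_normal((st.n_units, st.n_inputs)))
        tied = tn.tie_weights(W, st)
        assert st.constraint_violations(tied)["tying"] == 0.0

    def test_lowdin_diagonal_example(self):
        got = tn._lowdin(np.diag([2.0, 3.0]))
        assert np.allclose(got, np.eye(2), atol=1e-12)

    def test_orthonormal_fixed_point(self, rng):
        A = np.linalg.qr(rng.standard_normal((5, 5)))[0][:3]
        assert np.max(np.abs(tn._lowdin(A) - A)) < 1e-10

    def test_orthogonalize_output_orthonormal(self, rng):
        st = _structure()
        W = st.tie_weights(st.localize(
            rng.standard_normal((st.n_units, st.n_inputs))))
        orth = tn.orthogonalize_local_rf(W, st)
        assert st.constraint_violations(orth)["orthonormality"] < 1e-8

    def test_rank_deficient_group_rejected(self):
        st = _structure((4, 4, 1), n_maps=2, tile_k=2, rf_s=2)
        W = np.zeros((st.n_units, st.n_inputs))
        # both maps share an identical row at every location -> singular Gram
        for l in range(2):
            for u in range(st.grid[0]):
                for v in range(st.grid[1]):
                    W[st.unit(l, u, v), st.rf_indices(u, v)] = 1.0
        with pytest.raises(ValueError, match="rank-deficient"):
            tn.orthogonalize_local_rf(W, st)

    def test_projection_chain_preserves_all_constraints(self, rng):
        st = _structure()
        W = st.project(rng.standard_normal((st.n_units, st.n_inputs)))
        v = st.constraint_violations(W)
        assert v["locality"] == 0.0
        assert v["tying"] < 1e-6
        assert v["orthonormality"] < 1e-8


# ---------------------------------------------------------------------------
# pretraining

class TestPretrainTica:
    def test_max_outer_zero_returns_projection(self, rng):
        patches = rng.standard_normal((20, 6, 6, 1))
        w0 = _weights()
        res = tn.pretrain_tica(patches, w0,
                               config=tn.TICAConfig(max_outer=0))
        st = _structure()
        expected = st.contract_mean(st.project(st.expand(w0.banks)))
        assert np.allclose(res.weights.banks, expected)
        assert len(res.objective_trace) == 1

    def test_trace_strictly_decreasing(self, rng):
        patches = rng.standard_normal((60, 8, 8, 1))
        w0 = tn.init_tiled_weights(2, 2, 4, 1, seed=3)
        res = tn.pretrain_tica(patches, w0,
                               config=tn.TICAConfig(max_outer=30))
        assert len(res.objective_trace) > 1
        assert np.all(np.diff(res.objective_trace) < 0)

    def test_constraints_hold_after_every_accepted_step(self, rng):
        patches = rng.standard_normal((60, 8, 8, 1))
        w0 = tn.init_tiled_weights(2, 2, 4, 1, seed=4)
        res = tn.pretrain_tica(patches, w0,
                               config=tn.TICAConfig(max_outer=15))
        assert res.constraint_violations
        for v in res.constraint_violations:
            assert v["locality"] == 0.0
            assert v["tying"] < 1e-6
            assert v["orthonormality"] < 1e-8

    def test_deterministic(self, rng):
        patches = rng.standard_normal((30, 6, 6, 1))
        cfg = tn.TICAConfig(max_outer=10)
        r1 = tn.pretrain_tica(patches, _weights(seed=2), config=cfg)
        r2 = tn.pretrain_tica(patches, _weights(seed=2), config=cfg)
        assert np.array_equal(r1.weights.banks, r2.weights.banks)
        assert np.array_equal(r1.objective_trace, r2.objective_trace)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            tn.pretrain_tica(np.zeros((0, 6, 6, 1)), _weights())

    def test_multichannel_patches(self, rng):
        patches = rng.standard_normal((30, 6, 6, 2))
        w0 = tn.init_tiled_weights(2, 2, 3, 2, seed=1)
        res = tn.pretrain_tica(patches, w0,
                               config=tn.TICAConfig(max_outer=5))
        assert res.weights.banks.shape == (2, 2, 2, 3, 3, 2)


class TestExtractPatches:
    def test_shapes_and_determinism(self, rng):
        images = rng.standard_normal((4, 20, 20, 3))
        p1 = tn.extract_patches(images, 8, 50, seed=7)
        p2 = tn.extract_patches(images, 8, 50, seed=7)
        assert p1.shape == (50, 8, 8, 3)
        assert np.array_equal(p1, p2)

    def test_patch_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            tn.extract_patches(rng.standard_normal((2, 5, 5, 1)), 8, 10)


class TestWeightsIO:
    def test_round_trip(self, tmp_path):
        w = _weights(seed=11)
        path = tmp_path / "w.h5"
        tn.save_weights(path, w, trace=np.array([3.0, 2.0]),
                        config=tn.TICAConfig())
        loaded = tn.load_weights(path)
        assert np.array_equal(loaded.banks, w.banks)
        assert (loaded.tile_k, loaded.rf_s, loaded.n_maps) == (2, 3, 2)
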