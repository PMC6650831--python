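"""Patch harvesting, affinity graph, LPP filter learning, feature maps."""
import numpy as np
import pytest
import scipy.linalg

from conftest import correlate_reflect_oracle
from lepnlm import (
    ConfigurationError,
    FilterBank,
    InputError,
    LepNetConfig,
    LepNetModel,
    PatchMatrix,
    build_affinity,
    convolve_bank,
    harvest_patches,
    leaky_relu,
    lepnet_features,
    lepnet_train,
    make_phantom,
    solve_lep_filters,
    PhantomSpec,
)
from lepnlm.lepnet import lpp_matrices


def _patch_matrix(data, patch_shape):
    data = np.asarray(data, dtype=float)
    data = data - data.mean(axis=0, keepdims=True)
    return PatchMatrix(data=data, patch_shape=patch_shape,
                       sources=np.zeros((data.shape[1], 3), dtype=np.int64))


class TestHarvestPatches:
    def test_single_full_size_patch(self):
        img = np.arange(49, dtype=float).reshape(7, 7)
        P = harvest_patches([img], patch_shape=(7, 7), max_patches=100, seed=0)
        assert P.data.shape == (49, 1)
        assert P.data[:, 0].sum() == pytest.approx(0.0, abs=1e-12)

    def test_constant_image_yields_zero_columns(self):
        P = harvest_patches([np.full((16, 16), 9.0)], patch_shape=(5, 5),
                            max_patches=200, seed=0)
        assert np.allclose(P.data, 0.0)

    def test_columns_reproducible_from_sources(self):
        rng = np.random.default_rng(1)
        imgs = [rng.uniform(0, 255, (32, 32)) for _ in range(2)]
        P = harvest_patches(imgs, patch_shape=(5, 5), max_patches=500, seed=2)
        assert P.data.shape == (25, 500)
        assert len(np.unique(P.sources, axis=0)) == 500
        for j in [0, 17, 123, 499]:
            i, r, c = P.sources[j]
            assert 0 <= r <= 27 and 0 <= c <= 27
            patch = imgs[i][r : r + 5, c : c + 5].ravel()
            assert np.allclose(P.data[:, j], patch - patch.mean(), atol=1e-12)

    def test_image_smaller_than_patch_rejected(self):
        with pytest.raises(InputError):
            harvest_patches([np.zeros((4, 4))], patch_shape=(7, 7),
                            max_patches=100, seed=0)


class TestBuildAffinity:
    def test_two_identical_patches(self):
        P = _patch_matrix(np.array([[1.0, 1.0], [-1.0, -1.0]]), (1, 2))
        G = build_affinity(P, K=1, t=1.0)
        assert np.allclose(G.W.toarray(), [[0, 1], [1, 0]])
        assert np.allclose(G.L @ np.ones(2), 0.0)

    def test_laplacian_annihilates_constants(self):
        rng = np.random.default_rng(3)
        P = _patch_matrix(rng.normal(size=(9, 40)), (3, 3))
        G = build_affinity(P, K=5)
        n = P.n_patches
        assert np.allclose(G.L @ np.ones(n), 0.0, atol=1e-10)
        W = G.W.toarray()
        assert np.allclose(W, W.T)
        assert np.all(W >= 0)

    def test_matches_brute_force_on_hand_points(self):
        # distinct pairwise distances, so the K-NN graph is unambiguous
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.2],
                        [5.0, 5.0], [5.0, 6.0]])
        P = PatchMatrix(data=pts.T.copy(), patch_shape=(1, 2),
                        sources=np.zeros((5, 3), dtype=np.int64))
        X = P.data.T
        G = build_affinity(P, K=2, t=1.0)
        n = len(X)
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        expected = np.zeros((n, n))
        for i in range(n):
            nbrs = np.argsort(d2[i])
            nbrs = [j for j in nbrs if j != i][:2]
            for j in nbrs:
                w = np.exp(-d2[i, j] / 1.0)
                expected[i, j] = w
                expected[j, i] = w
        assert np.allclose(G.W.toarray(), expected, atol=1e-12)

    def test_k_out_of_range_rejected(self):
        P = _patch_matrix(np.random.default_rng(0).normal(size=(4, 5)), (2, 2))
        with pytest.raises(InputError):
            build_affinity(P, K=5)


class TestSolveLepFilters:
    def test_recovers_exact_low_dimensional_subspace(self):
        rng = np.random.default_rng(7)
        raw = rng.normal(size=(9, 3))
        raw -= raw.mean(axis=0, keepdims=True)  # zero-mean basis patterns
        basis, _ = np.linalg.qr(raw)
        coef = rng.normal(size=(3, 40))
        P = PatchMatrix(data=basis @ coef, patch_shape=(3, 3),
                        sources=np.zeros((40, 3), dtype=np.int64))
        G = build_affinity(P, K=4)
        bank = solve_lep_filters(P, G, n_filters=3)
        span = bank.kernels.reshape(3, 9).T
        angles = scipy.linalg.subspace_angles(span, basis)
        assert np.max(angles) < 1e-6

    def test_eigenvalues_nondecreasing_and_kernels_normalized(self):
        rng = np.random.default_rng(11)
        P = _patch_matrix(rng.normal(size=(16, 60)), (4, 4))
        G = build_affinity(P, K=6)
        bank = solve_lep_filters(P, G, n_filters=5)
        assert np.all(np.diff(bank.eigenvalues) >= -1e-12)
        for k in bank.kernels:
            assert np.linalg.norm(k) == pytest.approx(1.0)
            assert k.flat[np.argmax(np.abs(k))] > 0

    def test_matches_dense_generalized_eig_oracle(self):
        """Six-patch toy pencil: the symmetric solver's eigenpairs must
        agree with an independent dense QZ decomposition."""
        rng = np.random.default_rng(13)
        P = _patch_matrix(rng.normal(size=(4, 6)), (2, 2))
        G = build_affinity(P, K=2)
        A, B, U = lpp_matrices(P, G)
        w_oracle, v_oracle = scipy.linalg.eig(A, B)
        order = np.argsort(w_oracle.real)
        w_oracle = w_oracle.real[order]
        v_oracle = v_oracle.real[:, order]

        bank = solve_lep_filters(P, G, n_filters=2)
        assert np.allclose(bank.eigenvalues, w_oracle[:2], atol=1e-8)
        for i in range(2):
            ours = bank.kernels[i].ravel()
            theirs = U @ v_oracle[:, i]
            theirs = theirs / np.linalg.norm(theirs)
            assert min(np.linalg.norm(ours - theirs),
                       np.linalg.norm(ours + theirs)) < 1e-7

    def test_kernels_have_zero_mean(self):
        """Mean-removed patches make the constant direction unreachable,
        so every learned kernel is orthogonal to it."""
        rng = np.random.default_rng(17)
        P = _patch_matrix(rng.normal(size=(9, 80)), (3, 3))
        G = build_affinity(P, K=6)
        bank = solve_lep_filters(P, G, n_filters=4)
        assert np.allclose(bank.kernels.sum(axis=(1, 2)), 0.0, atol=1e-8)


class TestConvolveBank:
    def test_delta_kernel_is_identity(self):
        img = np.random.default_rng(0).uniform(0, 255, (10, 10))
        delta = np.zeros((3, 3))
        delta[1, 1] = 1.0
        bank = FilterBank(kernels=delta[None], eigenvalues=np.zeros(1))
        assert np.allclose(convolve_bank(img, bank)[0], img)

    def test_zero_mean_kernel_annihilates_constants(self):
        k = np.array([[1.0, -1.0], [0.5, -0.5]]) / np.sqrt(2.5)
        k3 = np.zeros((3, 3))
        k3[:2, :2] = k
        bank = FilterBank(kernels=k3[None], eigenvalues=np.zeros(1))
        out = convolve_bank(np.full((8, 8), 42.0), bank)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 255, (5, 5))
        kernel = rng.normal(size=(3, 3))
        bank = FilterBank(kernels=kernel[None], eigenvalues=np.zeros(1))
        assert np.allclose(convolve_bank(img, bank)[0],
                           correlate_reflect_oracle(img, kernel), atol=1e-10)


class TestLeakyRelu:
    @pytest.mark.parametrize("x,a,expected", [(5.0, 3.0, 5.0), (-6.0, 3.0, -2.0),
                                              (0.0, 3.0, 0.0)])
    def test_branches(self, x, a, expected):
        assert leaky_relu(x, a) == expected

    def test_zero_slope_rejected(self):
        with pytest.raises(ConfigurationError):
            leaky_relu(1.0, 0.0)


class TestTrainAndFeatures:
    def test_model_shape_contract(self, trained_model):
        assert len(trained_model.banks) == 2
        assert trained_model.bank1.kernels.shape == (4, 7, 7)
        assert trained_model.bank2.kernels.shape == (4, 7, 7)
        assert trained_model.n_features == 16
        for bank in trained_model.banks:
            for k in bank.kernels:
                assert np.linalg.norm(k) == pytest.approx(1.0)

    def test_training_deterministic(self):
        imgs = [make_phantom(PhantomSpec(48, 48, seed=s)) for s in (1, 2)]
        cfg = LepNetConfig(n_filters=(2, 2), max_patches=400, k_neighbors=6, seed=5)
        m1 = lepnet_train(imgs, cfg)
        m2 = lepnet_train(imgs, cfg)
        for b1, b2 in zip(m1.banks, m2.banks):
            assert np.array_equal(b1.kernels, b2.kernels)

    def test_first_layer_matches_standalone_dense_oracle(self):
        """Layer-1 kernels agree with an independently coded dense LPP
        (brute-force K-NN, dense Laplacian, QZ solve) on the same sample."""
        rng = np.random.default_rng(23)
        imgs = [rng.uniform(0, 255, (24, 24)) for _ in range(2)]
        cfg = LepNetConfig(patch_shape=(3, 3), n_filters=(2, 2),
                           max_patches=120, k_neighbors=4, seed=9)
        model = lepnet_train(imgs, cfg)

        P = harvest_patches(imgs, (3, 3), 120, seed=9)
        X = P.data.T
        n = len(X)
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        t = np.mean([np.sort(d2[i])[1 : 5] for i in range(n)])
        W = np.zeros((n, n))
        for i in range(n):
            for j in [q for q in np.argsort(d2[i]) if q != i][:4]:
                W[i, j] = W[j, i] = np.exp(-d2[i, j] / t)
        D = np.diag(W.sum(axis=1))
        L = D - W
        U, s, _ = np.linalg.svd(P.data, full_matrices=False)
        U = U[:, s > 1e-10 * s[0]]
        Ar = U.T @ P.data @ L @ P.data.T @ U
        Br = U.T @ P.data @ D @ P.data.T @ U
        w, v = scipy.linalg.eig(Ar, Br)
        order = np.argsort(w.real)
        oracle_span = U @ v.real[:, order[:2]]
        span = model.bank1.kernels.reshape(2, 9).T
        angles = scipy.linalg.subspace_angles(span, oracle_span)
        assert np.max(angles) < 1e-6

    def test_feature_field_shape_and_order(self, trained_model):
        img = make_phantom(PhantomSpec(seed=31))
        F = lepnet_features(img, trained_model)
        assert F.maps.shape == (16, 64, 64)
        assert F.vector_length == 16

    def test_two_stage_composition_matches_oracle(self):
        rng = np.random.default_rng(29)
        img = rng.uniform(0, 255, (9, 9))
        k1 = rng.normal(size=(2, 3, 3))
        k2 = rng.normal(size=(2, 3, 3))
        model = LepNetModel(
            banks=[FilterBank(k1, np.zeros(2), 1), FilterBank(k2, np.zeros(2), 2)],
            leaky_a=3.0, patch_shape=(3, 3))
        F = lepnet_features(img, model)
        assert F.maps.shape == (4, 9, 9)
        idx = 0
        for i in range(2):
            first = correlate_reflect_oracle(img, k1[i])
            for j in range(2):
                second = correlate_reflect_oracle(first, k2[j])
                expected = np.where(second >= 0, second, second / 3.0)
                assert np.allclose(F.maps[idx], expected, atol=1e-10)
                idx += 1

    def test_features_linear_without_activation(self, trained_model):
        rng = np.random.default_rng(37)
        i1 = rng.uniform(0, 255, (32, 32))
        i2 = rng.uniform(0, 255, (32, 32))
        f1 = lepnet_features(i1, trained_model, activation=False).maps
        f2 = lepnet_features(i2, trained_model, activation=False).maps
        f12 = lepnet_features(2.0 * i1 - 0.5 * i2, trained_model,
                              activation=False).maps
        assert np.allclose(f12, 2.0 * f1 - 0.5 * f2, atol=1e-8)

    def test_save_load_roundtrip(self, trained_model, tmp_path):
        path = tmp_path / "model.npz"
        trained_model.save(path)
        loaded = LepNetModel.load(path)
        assert loaded.leaky_a == trained_model.leaky_a
        assert loaded.patch_shape == trained_model.patch_shape
        for b1, b2 in zip(trained_model.banks, loaded.banks):
            assert np.array_equal(b1.kernels, b2.kernels)
        assert loaded.manifest == trained_model.manifest
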