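"""MPCA: unfolding, fitting, projection, eigentensors, serialisation."""

import numpy as np
import pytest

from cinempca.core import CinempcaError
from cinempca.mpca import (
    eigentensor,
    features_matrix,
    fold,
    load_model,
    mpca_fit,
    mpca_project,
    mpca_reconstruct,
    save_model,
    unfold,
)


class TestUnfold:
    def test_documented_ordering_2x2x2(self):
        t = np.arange(1, 9).reshape(2, 2, 2)
        m1 = unfold(t, 1)
        assert m1.shape == (2, 4)
        # rows index mode 1; remaining axes flatten row-major (j, k)
        assert np.array_equal(m1, [[1, 2, 3, 4], [5, 6, 7, 8]])
        assert sorted(m1.ravel()) == list(range(1, 9))

    @pytest.mark.parametrize("mode", [1, 2, 3])
    def test_fold_inverts_unfold(self, mode):
        t = np.random.default_rng(0).normal(size=(4, 3, 5))
        assert np.array_equal(fold(unfold(t, mode), mode, t.shape), t)

    def test_single_frame_mode1_is_the_frame(self):
        t = np.random.default_rng(1).normal(size=(6, 5, 1))
        assert np.array_equal(unfold(t, 1), t[:, :, 0])

    def test_invalid_mode(self):
        with pytest.raises(CinempcaError):
            unfold(np.zeros((2, 2, 2)), 4)


class TestFit:
    def test_full_threshold_reconstructs_exactly(self):
        x = np.random.default_rng(2).normal(size=(12, 5, 4, 3))
        model = mpca_fit(x, variance_threshold=1.0)
        assert model.feature_shape == (5, 4, 3)
        for sample in x[:4]:
            rec = mpca_reconstruct(model, mpca_project(model, sample))
            assert np.abs(rec - sample).max() < 1e-8

    def test_total_variance_conserved_at_full_threshold(self):
        x = np.random.default_rng(3).normal(size=(15, 4, 4, 3))
        model = mpca_fit(x, variance_threshold=1.0)
        feats = features_matrix(model, x)
        total_data = ((x - x.mean(0)) ** 2).sum()
        assert (feats**2).sum() == pytest.approx(total_data, rel=1e-6)

    def test_pca_equivalence_on_singleton_modes(self):
        """Tensors of shape 1 x 1 x K reduce MPCA to PCA on the K-vectors."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 1, 1, 8)) * np.array([3, 2, 1.5, 1, 1, 0.5, 0.3, 0.1])
        model = mpca_fit(x, variance_threshold=1.0)
        vecs = x[:, 0, 0, :]
        xc = vecs - vecs.mean(0)
        pca_eigs = np.sort(np.linalg.eigvalsh(xc.T @ xc))[::-1]
        assert np.abs(model.mode_eigenvalues[2][:8] - pca_eigs).max() < 1e-8
        # scores agree up to sign per component
        scores = features_matrix(model, x)  # (30, 8)
        pca_vecs = np.linalg.eigh(xc.T @ xc)[1][:, ::-1]
        ref = xc @ pca_vecs
        for j in range(8):
            assert min(
                np.abs(scores[:, j] - ref[:, j]).max(),
                np.abs(scores[:, j] + ref[:, j]).max(),
            ) < 1e-8

    def test_rank_one_data_concentrates_in_first_feature(self):
        rng = np.random.default_rng(5)
        u = rng.normal(size=6)
        v = rng.normal(size=5)
        w = rng.normal(size=4)
        coeffs = rng.normal(size=20)
        x = coeffs[:, None, None, None] * np.einsum("i,j,k->ijk", u, v, w)
        model = mpca_fit(x, variance_threshold=0.97)
        assert model.feature_shape == (1, 1, 1)
        feats = features_matrix(model, x)
        total = ((x - x.mean(0)) ** 2).sum()
        assert (feats**2).sum() >= 0.999 * total

    def test_captured_variation_monotone(self):
        x = np.random.default_rng(6).normal(size=(10, 6, 5, 4))
        model = mpca_fit(x, variance_threshold=0.8, max_iter=10, tol=0.0)
        psi = model.psi_history
        assert len(psi) >= 3
        assert np.all(np.diff(psi) >= -1e-8 * psi.max())

    def test_orthonormal_projections(self):
        x = np.random.default_rng(7).normal(size=(10, 6, 5, 4))
        model = mpca_fit(x, variance_threshold=0.9)
        for u in model.projections:
            assert np.abs(u.T @ u - np.eye(u.shape[1])).max() < 1e-8

    def test_fit_is_deterministic(self):
        x = np.random.default_rng(8).normal(size=(10, 4, 4, 3))
        a = mpca_fit(x, variance_threshold=0.9)
        b = mpca_fit(x, variance_threshold=0.9)
        for ua, ub in zip(a.projections, b.projections):
            assert np.array_equal(ua, ub)

    def test_too_few_samples(self):
        with pytest.raises(CinempcaError):
            mpca_fit(np.zeros((1, 3, 3, 3)))

    def test_zero_variance_data_warns(self):
        x = np.ones((5, 3, 3, 2))
        with pytest.warns(UserWarning):
            model = mpca_fit(x)
        assert np.all(features_matrix(model, x) == 0)


class TestProject:
    @pytest.fixture()
    def model_and_data(self):
        x = np.random.default_rng(9).normal(size=(14, 6, 5, 4))
        return mpca_fit(x, variance_threshold=0.95), x

    def test_training_mean_projects_to_zero(self, model_and_data):
        model, x = model_and_data
        assert np.abs(mpca_project(model, x.mean(0))).max() < 1e-9

    def test_linearity(self, model_and_data):
        model, x = model_and_data
        a, b = 0.3, -1.2
        mix = a * x[0] + b * x[1] + (1 - a - b) * model.mean_tensor
        lhs = mpca_project(model, mix)
        rhs = a * mpca_project(model, x[0]) + b * mpca_project(model, x[1])
        assert np.abs(lhs - rhs).max() < 1e-9

    def test_feature_equals_eigentensor_inner_product(self, model_and_data):
        model, x = model_and_data
        feats = mpca_project(model, x[3])
        centred = x[3] - model.mean_tensor
        p, q, r = model.feature_shape
        for idx in [(0, 0, 0), (p - 1, q - 1, r - 1), (p // 2, 0, r - 1)]:
            e = eigentensor(model, idx).dense()
            assert feats[idx] == pytest.approx((centred * e).sum(), abs=1e-9)

    def test_shape_mismatch(self, model_and_data):
        model, _ = model_and_data
        with pytest.raises(CinempcaError):
            mpca_project(model, np.zeros((3, 3, 3)))


class TestEigentensor:
    def test_unit_norm_and_orthogonality(self):
        x = np.random.default_rng(10).normal(size=(12, 5, 4, 3))
        model = mpca_fit(x, variance_threshold=1.0)
        e0 = eigentensor(model, (0, 0, 0)).dense()
        e1 = eigentensor(model, (1, 1, 1)).dense()
        assert np.linalg.norm(e0) == pytest.approx(1.0, abs=1e-10)
        assert (e0 * e1).sum() == pytest.approx(0.0, abs=1e-10)

    def test_parameter_economy_at_native_dims(self):
        """A 32 x 32 x 20 input has 20 480 dense parameters per eigenvector
        but only I + J + K = 84 per eigentensor."""
        x = np.random.default_rng(11).normal(size=(4, 32, 32, 20))
        model = mpca_fit(x, variance_threshold=0.5, max_iter=1)
        i, j, k = model.input_shape
        assert i * j * k == 20480
        et = eigentensor(model, (0, 0, 0))
        assert sum(f.size for f in et.factors) == i + j + k == 84

    def test_out_of_range_index(self):
        x = np.random.default_rng(12).normal(size=(6, 4, 3, 3))
        model = mpca_fit(x, variance_threshold=0.9)
        with pytest.raises(CinempcaError):
            eigentensor(model, model.feature_shape)


def test_serialisation_round_trips_bit_exactly(tmp_path):
    x = np.random.default_rng(13).normal(size=(8, 5, 4, 3))
    model = mpca_fit(x, variance_threshold=0.9)
    path = tmp_path / "model.npz"
    save_model(model, path)
    loaded = load_model(path)
    assert np.array_equal(loaded.mean_tensor, model.mean_tensor)
    for ua, ub in zip(loaded.projections, model.projections):
        assert np.array_equal(ua, ub)
    for ea, eb in zip(loaded.mode_eigenvalues, model.mode_eigenvalues):
        assert np.array_equal(ea, eb)
    assert loaded.variance_threshold == model.variance_threshold
    assert loaded.n_train == model.n_train
    assert np.array_equal(
        features_matrix(loaded, x), features_matrix(model, x)
    )
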