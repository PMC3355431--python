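"""Quaternion PCA: centering, covariance, Householder reduction, eigen-lift,
component selection, projection."""

import numpy as np
import pytest
from scipy.linalg import eigh_tridiagonal

from conftest import rand_hermitian, rand_quaternion_array
from quatpalm.qpca import (
    QPCAModel,
    center_training,
    eig_from_tridiagonal,
    fit_qpca,
    householder_tridiagonalize,
    project,
    select_components,
    small_covariance,
    stack_columns,
)
from quatpalm.quaternion import (
    QuaternionArray,
    complex_adjoint,
    conj_transpose,
    hamilton_product,
    qeye,
    qmat_mul,
    qvec_distance,
)


def tridiag_eigvals(B):
    if B.shape[0] == 1:
        return np.array([B[0, 0]])
    return eigh_tridiagonal(np.diag(B).copy(), np.diag(B, 1).copy())[0]


class TestCentering:
    def test_identical_columns_center_to_zero(self, rng):
        col = rand_quaternion_array(rng, (5,))
        S = stack_columns([col, col])
        assert center_training(S).E.norm() == pytest.approx(0.0, abs=1e-12)

    def test_scalar_example(self):
        S = QuaternionArray(np.array([[1.0, 3.0]]))
        tm = center_training(S)
        assert tm.mean.a[0] == 2.0
        assert np.array_equal(tm.E.a, [[-1.0, 1.0]])

    def test_row_means_vanish(self, rng):
        S = rand_quaternion_array(rng, (6, 5))
        E = center_training(S).E
        for ch in (E.a, E.b, E.c, E.d):
            assert np.allclose(ch.mean(axis=1), 0.0, atol=1e-10)

    def test_requires_two_columns(self, rng):
        with pytest.raises(ValueError):
            center_training(rand_quaternion_array(rng, (4, 1)))


class TestSmallCovariance:
    def test_zero_input(self):
        C = small_covariance(QuaternionArray.zeros((5, 3)))
        assert C.norm() == 0.0

    def test_hermitian(self, rng):
        E = rand_quaternion_array(rng, (6, 4))
        C = small_covariance(E)
        assert (C - conj_transpose(C)).norm() < 1e-10

    def test_real_input_matches_numpy_covariance(self, rng):
        X = rng.normal(size=(7, 5))
        Xc = X - X.mean(axis=1, keepdims=True)
        C = small_covariance(QuaternionArray.from_real(Xc))
        # ordinary sample covariance of the columns: Xcᵀ Xc / (n−1)
        assert np.allclose(C.a, Xc.T @ Xc / 4)
        assert C.b.max() == 0 and C.c.max() == 0 and C.d.max() == 0


class TestHouseholder:
    def test_1x1(self):
        B, P = householder_tridiagonalize(QuaternionArray.from_real([[5.0]]))
        assert B == pytest.approx(np.array([[5.0]]))
        assert P.a[0, 0] == pytest.approx(1.0)

    def test_2x2_phase_rotation_example(self):
        # [[2, i], [−i, 3]]: off-diagonal rotates to |i| = 1
        C = QuaternionArray(
            np.array([[2.0, 0.0], [0.0, 3.0]]),
            b=np.array([[0.0, 1.0], [-1.0, 0.0]]),
        )
        B, P = householder_tridiagonalize(C)
        assert np.allclose(B, [[2.0, 1.0], [1.0, 3.0]])
        w_adj = np.linalg.eigvalsh(complex_adjoint(C))[0::2]
        assert np.allclose(np.sort(tridiag_eigvals(B)), w_adj, atol=1e-10)

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_reconstruction_and_unitarity(self, rng, n):
        C = rand_hermitian(rng, n)
        B, P = householder_tridiagonalize(C)
        assert np.allclose(B, B.T)
        assert np.allclose(np.triu(B, 2), 0) and np.all(np.diag(B, 1) >= 0)
        rec = qmat_mul(qmat_mul(conj_transpose(P), QuaternionArray.from_real(B)), P)
        assert (rec - C).norm() < 1e-8
        assert (qmat_mul(conj_transpose(P), P) - qeye(n)).norm() < 1e-8

    def test_eigenvalues_match_complex_adjoint_oracle(self, rng):
        C = rand_hermitian(rng, 8)
        B, _ = householder_tridiagonalize(C)
        w = np.sort(tridiag_eigvals(B))
        w_adj = np.sort(np.linalg.eigvalsh(complex_adjoint(C)))[0::2]
        assert np.allclose(w, w_adj, atol=1e-8)

    def test_rejects_non_hermitian(self, rng):
        A = rand_quaternion_array(rng, (4, 4))
        with pytest.raises(ValueError):
            householder_tridiagonalize(A)


class TestEigenLift:
    def test_zero_data_gives_zero_spectrum(self):
        E = QuaternionArray.zeros((6, 3))
        C = small_covariance(E)
        B, P = householder_tridiagonalize(C)
        _, D = eig_from_tridiagonal(B, P, E)
        assert np.allclose(D, 0.0)

    def test_descending_order_and_small_matrix_residual(self, rng):
        E = center_training(rand_quaternion_array(rng, (10, 6))).E
        C = small_covariance(E)
        B, P = householder_tridiagonalize(C)
        _, D = eig_from_tridiagonal(B, P, E)
        assert np.all(np.diff(D) <= 1e-12)
        # residual check on the small matrix: C·V_C = V_C·diag(D_C)
        w, VB = np.linalg.eigh(B)
        VC = qmat_mul(conj_transpose(P), QuaternionArray.from_real(VB))
        lhs = qmat_mul(C, VC)
        rhs = QuaternionArray(*(ch * w[None, :] for ch in
                                (VC.a, VC.b, VC.c, VC.d)))
        assert (lhs - rhs).norm() < 1e-8


class TestSelectComponents:
    @pytest.mark.parametrize(
        "D, ratio, expected",
        [
            ([9.0, 1.0], 0.90, 1),
            ([5.0, 3.0, 2.0], 0.90, 3),
            ([5.0, 3.0, 2.0, 0.0], 1.0, 3),
            ([1.0], 0.5, 1),
        ],
    )
    def test_examples(self, D, ratio, expected):
        assert select_components(np.array(D), ratio) == expected

    def test_nondecreasing_in_ratio(self, rng):
        D = np.sort(rng.random(10))[::-1]
        ps = [select_components(D, r) for r in np.linspace(0.05, 1.0, 20)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_all_zero_spectrum_raises(self):
        with pytest.raises(ValueError):
            select_components(np.zeros(4), 0.9)


class TestFitAndProject:
    def test_default_ratio(self, rng):
        model = fit_qpca([rand_quaternion_array(rng, (12,)) for _ in range(5)])
        assert model.energy_ratio == 0.9

    def test_identical_samples_raise_on_zero_spectrum(self, rng):
        s = rand_quaternion_array(rng, (8,))
        with pytest.raises(ValueError):
            fit_qpca([s.copy() for _ in range(4)])

    def test_two_samples_give_one_component(self, rng):
        model = fit_qpca(
            [rand_quaternion_array(rng, (10,)) for _ in range(2)], ratio=0.5
        )
        assert model.n_components == 1

    def test_training_mean_projects_to_zero(self, rng):
        samples = [rand_quaternion_array(rng, (9,)) for _ in range(5)]
        model = fit_qpca(samples, ratio=1.0)
        f = project(model, model.mean)
        assert float(np.sqrt(np.sum(f.abs() ** 2))) == pytest.approx(0.0, abs=1e-10)

    def test_projection_length(self, rng):
        samples = [rand_quaternion_array(rng, (9,)) for _ in range(6)]
        model = fit_qpca(samples, ratio=0.8)
        assert project(model, samples[0]).size == model.n_components

    def test_full_ratio_preserves_pairwise_distances(self, rng):
        samples = [rand_quaternion_array(rng, (20,)) for _ in range(8)]
        model = fit_qpca(samples, ratio=1.0)
        feats = [project(model, s) for s in samples]
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                din = qvec_distance(samples[i], samples[j])
                dfeat = qvec_distance(feats[i], feats[j])
                assert dfeat == pytest.approx(din, rel=1e-6)

    def test_unit_norm_projection_columns(self, rng):
        model = fit_qpca([rand_quaternion_array(rng, (15,)) for _ in range(6)],
                         ratio=1.0)
        norms = np.sqrt(np.sum(model.projection.abs() ** 2, axis=0))
        assert np.allclose(norms, 1.0, atol=1e-10)

    def test_phase_indeterminacy_leaves_distances_unchanged(self, rng):
        """Right-multiplying a projection column by a unit quaternion must not
        change feature distances."""
        samples = [rand_quaternion_array(rng, (12,)) for _ in range(5)]
        model = fit_qpca(samples, ratio=1.0)
        u = rand_quaternion_array(rng, ())
        u = u / float(u.abs())
        rotated = model.projection.copy()
        col = rotated[:, 0]
        rotated[:, 0] = hamilton_product(col, u)
        model2 = QPCAModel(model.mean, rotated, model.eigenvalues,
                           model.n_components, model.energy_ratio)
        d1 = qvec_distance(project(model, samples[0]), project(model, samples[1]))
        d2 = qvec_distance(project(model2, samples[0]), project(model2, samples[1]))
        assert d2 == pytest.approx(d1, rel=1e-10)

    def test_model_save_load_round_trip(self, tmp_path, rng):
        model = fit_qpca([rand_quaternion_array(rng, (10,)) for _ in range(4)])
        p = tmp_path / "model.npz"
        model.save(p)
        loaded = QPCAModel.load(p)
        assert np.array_equal(loaded.projection.channels(),
                              model.projection.channels())
        assert np.array_equal(loaded.eigenvalues, model.eigenvalues)
        assert loaded.n_components == model.n_components
        assert loaded.center == model.center
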