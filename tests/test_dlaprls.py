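import numpy as np
import pytest

from dhanmkf import dlaprls
from dhanmkf.autodiff import Tensor


def random_instance(rng, n_c=6, n_d=5):
    """A small solver instance with well-defined Gaussian kernels."""
    ic = dlaprls.gaussian_kernel(rng.standard_normal((n_c, 3)), 0.3)
    id_ = dlaprls.gaussian_kernel(rng.standard_normal((n_d, 3)), 0.3)
    y = (rng.random((n_c, n_d)) < 0.3).astype(float)
    state = dlaprls.make_state(ic, id_, rng=rng)
    return state, ic, id_, y


class TestKernels:
    def test_identical_rows_give_unit_entry(self):
        emb = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]])
        k = dlaprls.gaussian_kernel(emb, 0.5)
        assert k[0, 1] == pytest.approx(1.0)

    def test_one_dimensional_hand_case(self):
        k = dlaprls.gaussian_kernel(np.array([[0.0], [1.0]]), 1.0 / 75.0)
        assert k[0, 1] == pytest.approx(np.exp(-1.0 / 75.0))

    def test_kernel_count_matches_stack(self):
        stack = [np.random.default_rng(0).standard_normal((4, 2)) for _ in range(3)]
        assert len(dlaprls.embedding_gip_kernels(stack)) == 3

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            dlaprls.embedding_gip_kernels([])

    def test_autodiff_kernel_matches_numpy(self):
        rng = np.random.default_rng(1)
        emb = rng.standard_normal((6, 4))
        k_np = dlaprls.gaussian_kernel(emb, 0.2)
        k_ad = dlaprls.gaussian_kernel_ad(Tensor(emb), 0.2).data
        np.testing.assert_allclose(k_ad, k_np, atol=1e-12)


class TestFusion:
    def test_identical_kernels_fuse_to_themselves(self):
        k = dlaprls.gaussian_kernel(np.random.default_rng(2).standard_normal((5, 2)), 0.4)
        np.testing.assert_allclose(dlaprls.fuse_kernels([k, k, k]), k)

    def test_mean_of_zero_and_one_entries(self):
        a = np.zeros((2, 2))
        b = np.ones((2, 2))
        np.testing.assert_allclose(dlaprls.fuse_kernels([a, b]), 0.5)

    def test_fused_kernel_symmetric_psd(self):
        rng = np.random.default_rng(3)
        kernels = [
            dlaprls.gaussian_kernel(rng.standard_normal((8, 3)), 0.3) for _ in range(4)
        ]
        fused = dlaprls.fuse_kernels(kernels)
        np.testing.assert_allclose(fused, fused.T)
        assert np.linalg.eigvalsh(fused).min() >= -1e-10

    def test_empty_fusion_rejected(self):
        with pytest.raises(ValueError):
            dlaprls.fuse_kernels([])


class TestLaplacian:
    def test_two_by_two_hand_case(self):
        lap = dlaprls.normalized_laplacian(np.array([[1.0, 1.0], [1.0, 1.0]]))
        np.testing.assert_allclose(lap, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-12)

    def test_degree_scaled_constant_vector_in_nullspace(self):
        rng = np.random.default_rng(4)
        k = dlaprls.gaussian_kernel(rng.standard_normal((7, 3)), 0.3)
        lap = dlaprls.normalized_laplacian(k)
        v_half_one = np.sqrt(k.sum(axis=1))
        np.testing.assert_allclose(lap @ v_half_one, 0.0, atol=1e-10)

    def test_psd(self):
        rng = np.random.default_rng(5)
        k = dlaprls.gaussian_kernel(rng.standard_normal((9, 2)), 0.5)
        assert np.linalg.eigvalsh(dlaprls.normalized_laplacian(k)).min() >= -1e-10

    def test_zero_row_sum_rejected(self):
        with pytest.raises(ValueError):
            dlaprls.normalized_laplacian(np.zeros((2, 2)))


class TestLoss:
    def test_all_zero_case(self):
        state = dlaprls.DLapRLSState(
            alpha_c=np.zeros((2, 2)), alpha_d=np.zeros((2, 2)),
            lap_c=np.eye(2), lap_d=np.eye(2),
        )
        assert dlaprls.dlaprls_loss(state, np.eye(2), np.eye(2), np.zeros((2, 2))) == 0.0

    def test_zero_coefficients_give_four_times_positives(self):
        y = np.array([[1.0, 0.0], [1.0, 1.0]])
        state = dlaprls.DLapRLSState(
            alpha_c=np.zeros((2, 2)), alpha_d=np.zeros((2, 2)),
            lap_c=np.eye(2), lap_d=np.eye(2),
        )
        assert dlaprls.dlaprls_loss(state, np.eye(2), np.eye(2), y) == pytest.approx(
            4.0 * y.sum()
        )

    def test_matches_term_by_term_reference(self):
        rng = np.random.default_rng(6)
        state, ic, id_, y = random_instance(rng)
        state.alpha_c = rng.standard_normal(state.alpha_c.shape)
        state.alpha_d = rng.standard_normal(state.alpha_d.shape)
        fit = ic @ state.alpha_c + (id_ @ state.alpha_d).T - 2 * y
        expected = (
            np.sum(fit * fit)
            + state.phi_c * np.trace(state.alpha_c.T @ state.lap_c @ state.alpha_c)
            + state.phi_d * np.trace(state.alpha_d.T @ state.lap_d @ state.alpha_d)
        )
        assert dlaprls.dlaprls_loss(state, ic, id_, y) == pytest.approx(expected)

    def test_laplacian_trace_ad_matches_numpy(self):
        rng = np.random.default_rng(7)
        k = dlaprls.gaussian_kernel(rng.standard_normal((6, 3)), 0.3)
        alpha = rng.standard_normal((6, 4))
        lap = dlaprls.normalized_laplacian(k)
        expected = np.trace(alpha.T @ lap @ alpha)
        got = dlaprls.laplacian_trace_ad(Tensor(k), alpha @ alpha.T).data
        assert float(got) == pytest.approx(expected, rel=1e-10)


class TestUpdates:
    def test_identity_kernel_no_regularization(self):
        rng = np.random.default_rng(8)
        y = (rng.random((4, 3)) < 0.5).astype(float)
        state = dlaprls.DLapRLSState(
            alpha_c=np.zeros((4, 3)), alpha_d=rng.standard_normal((3, 4)),
            lap_c=np.eye(4), lap_d=np.eye(3), phi_c=0.0, phi_d=0.0, jitter=0.0,
        )
        ic, id_ = np.eye(4), np.eye(3)
        got = dlaprls.update_alpha_c(state, ic, id_, y)
        np.testing.assert_allclose(got, 2 * y - state.alpha_d.T @ id_.T, atol=1e-10)

    def test_update_zeroes_partial_derivative(self):
        rng = np.random.default_rng(9)
        state, ic, id_, y = random_instance(rng)
        state.alpha_c = dlaprls.update_alpha_c(state, ic, id_, y)
        grad = (
            2 * ic @ (ic @ state.alpha_c + (id_ @ state.alpha_d).T - 2 * y)
            + 2 * state.phi_c * state.lap_c @ state.alpha_c
        )
        residual = np.linalg.norm(grad) / (1 + np.linalg.norm(state.alpha_c))
        assert residual < 1e-6

    def test_update_never_increases_loss(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            state, ic, id_, y = random_instance(rng)
            j_prev = dlaprls.dlaprls_loss(state, ic, id_, y)
            state.alpha_c = dlaprls.update_alpha_c(state, ic, id_, y)
            j_mid = dlaprls.dlaprls_loss(state, ic, id_, y)
            state.alpha_d = dlaprls.update_alpha_d(state, ic, id_, y)
            j_post = dlaprls.dlaprls_loss(state, ic, id_, y)
            assert j_mid <= j_prev + 1e-9
            assert j_post <= j_mid + 1e-9

    def test_alternation_monotone_over_rounds(self):
        rng = np.random.default_rng(11)
        state, ic, id_, y = random_instance(rng)
        dlaprls.alternate(state, ic, id_, y, n_rounds=10)
        diffs = np.diff(state.history)
        assert (diffs <= 1e-9).all()


class TestPredict:
    def test_zero_coefficients(self):
        state = dlaprls.DLapRLSState(
            alpha_c=np.zeros((3, 2)), alpha_d=np.zeros((2, 3)),
            lap_c=np.eye(3), lap_d=np.eye(2),
        )
        np.testing.assert_array_equal(
            dlaprls.predict(state, np.eye(3), np.eye(2)), np.zeros((3, 2))
        )

    def test_average_of_identical_terms(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        state = dlaprls.DLapRLSState(
            alpha_c=y.copy(), alpha_d=y.T.copy(),
            lap_c=np.eye(2), lap_d=np.eye(2),
        )
        np.testing.assert_allclose(dlaprls.predict(state, np.eye(2), np.eye(2)), y)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(12)
        state, ic, id_, _ = random_instance(rng)
        state.alpha_c = rng.standard_normal(state.alpha_c.shape)
        state.alpha_d = rng.standard_normal(state.alpha_d.shape)
        expected = 0.5 * (ic @ state.alpha_c + (id_ @ state.alpha_d).T)
        np.testing.assert_allclose(dlaprls.predict(state, ic, id_), expected)

    def test_linear_in_coefficients(self):
        rng = np.random.default_rng(13)
        state, ic, id_, _ = random_instance(rng)
        a = dlaprls.predict(state, ic, id_)
        state.alpha_c = 2 * state.alpha_c
        state.alpha_d = 2 * state.alpha_d
        np.testing.assert_allclose(dlaprls.predict(state, ic, id_), 2 * a, atol=1e-12)
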