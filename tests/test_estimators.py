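"""Kernels, RLS and KRLS-ALD recursions against closed-form and batch oracles."""

import numpy as np
import pytest

from nirsdip import (
    KernelSpec,
    RlsState,
    kernel_eval,
    krls_init,
    krls_predict,
    krls_update,
    rls_update,
)
from nirsdip.kernels import gram_matrix
from nirsdip.prediction import ModelOrders, build_regressor


class TestKernels:
    def test_gaussian_at_zero_distance_is_one(self):
        assert kernel_eval(KernelSpec("gaussian"), np.ones(3), np.ones(3)) == 1.0

    def test_gaussian_unit_offset(self):
        # exp(-0.5), arbitrary-precision value 0.60653065971263342360
        v = kernel_eval(KernelSpec("gaussian"), np.array([1.0, 0.0]), np.array([0.0, 0.0]))
        assert v == pytest.approx(0.60653065971263342360, rel=1e-15)

    def test_polynomial_hand_arithmetic(self):
        # (1*3 + 2*4 + 1)^1 = 12
        v = kernel_eval(KernelSpec("polynomial"), np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert v == 12.0

    def test_sigmoid_hand_arithmetic(self):
        v = kernel_eval(KernelSpec("sigmoid"), np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        assert v == pytest.approx(np.tanh(2.0))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec("gaussian", sigma=0.0)
        with pytest.raises(ValueError):
            KernelSpec("polynomial", c=-1.0)
        with pytest.raises(ValueError):
            KernelSpec("polynomial", p=0)
        with pytest.raises(ValueError):
            KernelSpec("hyperbolic")


class TestRls:
    def test_intercept_only_converges_to_constant(self):
        state = RlsState.initialize(1, lam=1.0)
        for _ in range(100):
            state, _, _ = rls_update(state, np.array([1.0]), 3.25)
        assert state.theta[0] == pytest.approx(3.25, abs=1e-6)

    def test_recovers_arx_coefficients_and_matches_batch_ls(self):
        rng = np.random.default_rng(17)
        n = 500
        u = rng.normal(size=n)
        y = np.zeros(n)
        for k in range(1, n):
            y[k] = 0.5 * y[k - 1] + u[k - 1] + 0.2
        orders = ModelOrders()
        state = RlsState.initialize(orders.dim, lam=1.0)
        Phi = []
        for k in range(1, n):
            phi = build_regressor(y, u, orders, k)
            Phi.append(phi)
            state, _, _ = rls_update(state, phi, y[k])
        np.testing.assert_allclose(state.theta, [0.5, 1.0, 0.2], atol=1e-6)
        theta_ls, *_ = np.linalg.lstsq(np.array(Phi), y[1:n], rcond=None)
        np.testing.assert_allclose(state.theta, theta_ls, atol=1e-6)

    def test_zero_data_keeps_zero_estimate(self):
        state = RlsState.initialize(3, lam=0.98)
        for _ in range(50):
            state, _, _ = rls_update(state, np.zeros(3), 0.0)
        assert np.all(state.theta == 0)

    def test_nonfinite_input_rejected(self):
        state = RlsState.initialize(2)
        with pytest.raises(ValueError):
            rls_update(state, np.array([1.0, np.nan]), 0.0)

    def test_covariance_stays_symmetric_positive(self):
        rng = np.random.default_rng(3)
        state = RlsState.initialize(3, lam=0.98)
        for _ in range(200):
            state, _, _ = rls_update(state, rng.normal(size=3), rng.normal())
        np.testing.assert_allclose(state.P, state.P.T, atol=1e-9)
        assert np.all(np.linalg.eigvalsh(state.P) > 0)


class TestKrlsInit:
    def test_first_coefficient_hand_value(self):
        # a(1) = y(1) / (R*lam + k(phi,phi)) with gaussian k(phi,phi)=1
        st = krls_init(np.array([0.3, -0.2, 1.0]), 2.0, KernelSpec("gaussian"),
                       reg=1e-8, lam=0.98)
        assert st.a[0] == pytest.approx(2.0 / (1.0 + 0.98e-8), rel=1e-15)

    def test_zero_target_gives_zero_coefficient(self):
        st = krls_init(np.ones(3), 0.0, KernelSpec("gaussian"))
        assert st.a[0] == 0.0

    def test_polynomial_inverse_gram_hand_value(self):
        # k(phi,phi) = (0+0+1+1)^1 = 2 -> Q(1) ~ 0.5 with negligible ridge
        st = krls_init(np.array([0.0, 0.0, 1.0]), 1.0, KernelSpec("polynomial"),
                       reg=1e-12, lam=1.0)
        assert st.Q[0, 0] == pytest.approx(0.5, rel=1e-10)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            krls_init(np.ones(2), 1.0, reg=0.0)
        with pytest.raises(ValueError):
            krls_init(np.ones(2), 1.0, lam=1.5)


class TestKrlsUpdate:
    def test_duplicate_input_does_not_grow_dictionary(self):
        phi = np.array([0.5, -0.1, 1.0])
        st = krls_init(phi, 1.0, KernelSpec("gaussian"), ald_threshold=1e-6)
        st, _, _ = krls_update(st, phi.copy(), 2.0)
        assert st.dict_size == 1

    def test_zero_stream_keeps_zero_coefficients(self):
        rng = np.random.default_rng(0)
        st = krls_init(rng.normal(size=3), 0.0, KernelSpec("gaussian"))
        for _ in range(20):
            st, yhat, e = krls_update(st, rng.normal(size=3), 0.0)
            assert e == 0.0
        assert np.all(st.a == 0)

    @pytest.mark.parametrize("kind", ["gaussian", "polynomial", "sigmoid"])
    def test_matches_batch_kernel_ridge_on_every_prefix(self, kind):
        """ALD off, lam=1: recursion == (K + R*lam*I)^-1 y on each prefix."""
        rng = np.random.default_rng(0)
        n, reg = 30, 1e-2
        # ARX-style regressors [y, u, 1] at modest amplitude, where all three
        # kernels (sigmoid is only conditionally positive definite) give a
        # positive-definite regularized Gram
        yv, uv = 0.1 * rng.normal(size=n + 1), 0.1 * rng.normal(size=n + 1)
        X = np.stack([yv[:n], uv[:n], np.ones(n)], axis=1)
        y = rng.normal(size=n)
        spec = KernelSpec(kind)
        G = gram_matrix(spec, X)
        st = krls_init(X[0], y[0], spec, reg=reg, lam=1.0, ald_threshold=-1.0, dict_cap=None)
        for k in range(1, n):
            st, y_hat, _ = krls_update(st, X[k], y[k])
            a_batch = np.linalg.solve(G[:k, :k] + reg * np.eye(k), y[:k])
            assert y_hat == pytest.approx(G[:k, k] @ a_batch, abs=1e-8)
        assert st.dict_size == n

    def test_ald_dictionary_much_smaller_than_stream(self):
        """On a smooth 2000-sample stream ALD retains a small dictionary,
        strictly below the one-entry-per-sample growth without ALD."""
        t = np.arange(2000) / 9.19
        yv = np.sin(2 * np.pi * 0.05 * t)
        st = krls_init(np.array([yv[0], 0.0, 1.0]), yv[1], KernelSpec("gaussian"),
                       ald_threshold=1e-4, dict_cap=None)
        for k in range(1, 1999):
            st, _, _ = krls_update(st, np.array([yv[k], 0.0, 1.0]), yv[k + 1])
        assert st.dict_size < 2000  # sparsification engaged
        assert st.dict_size < 100

        # the same first 300 samples without ALD retain every sample
        st_off = krls_init(np.array([yv[0], 0.0, 1.0]), yv[1], KernelSpec("gaussian"),
                           reg=1e-4, ald_threshold=-1.0, dict_cap=None)
        for k in range(1, 300):
            st_off, _, _ = krls_update(st_off, np.array([yv[k], 0.0, 1.0]), yv[k + 1])
        assert st_off.dict_size == 300
        assert st.dict_size < st_off.dict_size

    def test_dictionary_cap_is_respected(self):
        rng = np.random.default_rng(1)
        st = krls_init(rng.normal(size=3), rng.normal(), KernelSpec("gaussian"),
                       ald_threshold=0.0, dict_cap=10)
        for _ in range(50):
            st, _, _ = krls_update(st, rng.normal(size=3), rng.normal())
        assert st.dict_size == 10


class TestKrlsPredict:
    def test_prediction_after_init_hand_value(self):
        phi = np.array([0.1, 0.2, 1.0])
        st = krls_init(phi, 2.0, KernelSpec("gaussian"), reg=1e-8, lam=0.98)
        assert krls_predict(st, phi) == pytest.approx(2.0 / (1.0 + 0.98e-8), rel=1e-12)

    def test_zero_coefficients_predict_zero(self):
        st = krls_init(np.ones(3), 0.0, KernelSpec("gaussian"))
        assert krls_predict(st, np.zeros(3)) == 0.0

    def test_far_query_decays_with_gaussian_kernel(self):
        rng = np.random.default_rng(2)
        st = krls_init(rng.normal(size=3), 1.0, KernelSpec("gaussian"))
        for _ in range(10):
            st, _, _ = krls_update(st, rng.normal(size=3), rng.normal())
        far = 100.0 * np.ones(3)
        assert abs(krls_predict(st, far)) < 1e-6 * np.sum(np.abs(st.a))
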