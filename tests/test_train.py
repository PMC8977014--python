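"""Training loop: gradient, fixed Hessian, Newton updates, full runs."""

import numpy as np
import pytest

from mpclogit import (
    CommLedger,
    ConfigurationError,
    NewtonLogisticRegression,
    SecureLogisticRegression,
    SharedMatrix,
    SyntheticSpec,
    TrainConfig,
    TrainingData,
    fixed_hessian_inverse,
    generate_logistic_data,
    gradient_shared,
    make_protocol,
    newton_update,
    sigmoid,
    train,
    train_plaintext_baseline,
)


def _proto(setting, backend, rng):
    return make_protocol(setting, backend, rng, CommLedger())


@pytest.fixture
def small_data(rng):
    spec = SyntheticSpec(
        n_records=120, m_features=3, true_beta=np.array([1.0, -0.5, 0.25]), seed=11
    )
    return generate_logistic_data(spec)


class TestGradientShared:
    def test_zero_residual_gives_zero_gradient(self, real_backend, rng):
        # duplicated rows with opposite labels cancel exactly at beta = 0
        proto = _proto("honest3", real_backend, rng)
        x = rng.standard_normal((10, 2))
        X = np.vstack([x, x])
        y = np.r_[np.ones(10), np.zeros(10)].reshape(-1, 1)
        sx = SharedMatrix.share(X, 3, real_backend, rng)
        sy = SharedMatrix.share(y, 3, real_backend, rng)
        beta = SharedMatrix.share(np.zeros((2, 1)), 3, real_backend, rng)
        g = gradient_shared(sx, sy, beta, "exact", proto)
        np.testing.assert_allclose(g.reconstruct(), np.zeros((2, 1)), atol=1e-7)

    def test_matches_plaintext_gradient(self, real_backend, rng):
        proto = _proto("honest3", real_backend, rng)
        X = rng.standard_normal((20, 3))
        y = (rng.uniform(size=20) < 0.5).astype(float).reshape(-1, 1)
        beta = rng.uniform(-0.5, 0.5, (3, 1))
        sx = SharedMatrix.share(X, 3, real_backend, rng)
        sy = SharedMatrix.share(y, 3, real_backend, rng)
        sb = SharedMatrix.share(beta, 3, real_backend, rng)
        g = gradient_shared(sx, sy, sb, "exact", proto)
        expected = X.T @ (y - sigmoid(X @ beta))
        np.testing.assert_allclose(g.reconstruct(), expected, atol=1e-5)


class TestFixedHessianInverse:
    def test_scaled_identity(self, real_backend, rng):
        # X = 2I: (-1/4 * 4I)^(-1) = -I
        proto = _proto("honest3", real_backend, rng)
        sx = SharedMatrix.share(2.0 * np.eye(3), 3, real_backend, rng)
        h = fixed_hessian_inverse(sx, proto, nardi_steps=25)
        np.testing.assert_allclose(h.reconstruct(), -np.eye(3), atol=1e-7)

    def test_orthonormal_columns(self, real_backend, rng):
        q, _ = np.linalg.qr(rng.standard_normal((8, 3)))
        proto = _proto("honest3", real_backend, rng)
        sx = SharedMatrix.share(q, 3, real_backend, rng)
        h = fixed_hessian_inverse(sx, proto, nardi_steps=25)
        np.testing.assert_allclose(h.reconstruct(), -4.0 * np.eye(3), atol=1e-6)

    def test_random_design_vs_direct_inverse(self, real_backend, rng):
        X = rng.standard_normal((50, 4))
        proto = _proto("honest3", real_backend, rng)
        sx = SharedMatrix.share(X, 3, real_backend, rng)
        h = fixed_hessian_inverse(sx, proto, nardi_steps=30)
        np.testing.assert_allclose(
            h.reconstruct(), -4.0 * np.linalg.inv(X.T @ X), atol=1e-5
        )


class TestNewtonUpdate:
    def test_zero_gradient_leaves_beta(self, real_backend, rng):
        proto = _proto("honest3", real_backend, rng)
        beta = SharedMatrix.share(np.array([[0.7], [-0.2]]), 3, real_backend, rng)
        h = SharedMatrix.share(-np.eye(2), 3, real_backend, rng)
        g = SharedMatrix.share(np.zeros((2, 1)), 3, real_backend, rng)
        out = newton_update(beta, h, g, proto)
        np.testing.assert_allclose(out.reconstruct(), [[0.7], [-0.2]], atol=1e-9)

    def test_one_feature_hand_arithmetic(self, real_backend, rng):
        # X = (1, 2), y = (1, 0), beta = 0.3: one update by hand
        X = np.array([[1.0], [2.0]])
        y = np.array([[1.0], [0.0]])
        beta0 = 0.3
        pi = 1.0 / (1.0 + np.exp(-X.ravel() * beta0))
        grad = float(X.ravel() @ (y.ravel() - pi))
        h_inv = -4.0 / float(X.ravel() @ X.ravel())
        expected = beta0 - h_inv * grad
        proto = _proto("honest3", real_backend, rng)
        sb = SharedMatrix.share(np.array([[beta0]]), 3, real_backend, rng)
        sh = SharedMatrix.share(np.array([[h_inv]]), 3, real_backend, rng)
        sg = SharedMatrix.share(np.array([[grad]]), 3, real_backend, rng)
        out = newton_update(sb, sh, sg, proto)
        assert out.reconstruct()[0, 0] == pytest.approx(expected, abs=1e-9)


class TestPlaintextBaseline:
    def test_agrees_with_statsmodels_mle(self, small_data):
        sm = pytest.importorskip("statsmodels.api")
        X, y = small_data
        design = np.hstack([np.ones((len(y), 1)), X])
        ref = sm.Logit(y, design).fit(disp=0).params
        model = train_plaintext_baseline(design, y, variant="full_newton", n_iter=25)
        np.testing.assert_allclose(model.beta, ref, atol=1e-3)

    def test_fixed_hessian_reaches_same_optimum(self, small_data):
        X, y = small_data
        design = np.hstack([np.ones((len(y), 1)), X])
        full = train_plaintext_baseline(design, y, variant="full_newton", n_iter=30)
        fixed = train_plaintext_baseline(design, y, variant="fixed_hessian", n_iter=200)
        np.testing.assert_allclose(fixed.beta, full.beta, atol=1e-6)

    def test_zero_iterations_returns_initial_beta(self, small_data):
        X, y = small_data
        model = train_plaintext_baseline(X, y, n_iter=0)
        np.testing.assert_array_equal(model.beta, np.zeros(X.shape[1]))


class TestTrainConfig:
    def test_defaults_per_algorithm(self):
        assert TrainConfig(algorithm="accurate").sigmoid == "exact"
        assert TrainConfig(algorithm="accurate").backend == "real"
        approx = TrainConfig(algorithm="approx")
        assert approx.sigmoid == "g3" and approx.backend == "field"

    def test_invalid_combinations_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(algorithm="accurate", sigmoid="g3")
        with pytest.raises(ConfigurationError):
            TrainConfig(algorithm="approx", sigmoid="exact")
        with pytest.raises(ConfigurationError):
            TrainConfig(setting="honest4")
        with pytest.raises(ConfigurationError):
            TrainConfig(n_iter=0)


class TestFullTraining:
    def test_zero_gradient_data_keeps_beta_zero(self, real_backend, rng):
        x = rng.standard_normal((8, 2))
        X = np.vstack([x, x])
        y = np.r_[np.ones(8), np.zeros(8)]
        config = TrainConfig(setting="honest3", algorithm="accurate", n_iter=2,
                             add_intercept=False, seed=1)
        data = TrainingData(
            X=SharedMatrix.share(X, 3, real_backend, rng),
            y=SharedMatrix.share(y.reshape(-1, 1), 3, real_backend, rng),
        )
        model = train(data, config)
        np.testing.assert_allclose(model.beta, np.zeros(2), atol=1e-6)

    @pytest.mark.parametrize("setting", ["honest3", "dishonest2"])
    @pytest.mark.parametrize("algorithm,sigmoid_mode", [
        ("accurate", "exact"), ("approx", "g3"), ("approx", "g7"),
    ])
    def test_estimator_matches_plaintext_same_formulas(
        self, small_data, setting, algorithm, sigmoid_mode
    ):
        X, y = small_data
        est = SecureLogisticRegression(
            setting=setting, algorithm=algorithm,
            sigmoid_mode=None if algorithm == "accurate" else sigmoid_mode,
            backend="real", n_iter=8, random_state=3,
        ).fit(X, y)
        base = NewtonLogisticRegression(
            variant="fixed_hessian", n_iter=8, sigmoid_mode=sigmoid_mode
        ).fit(X, y)
        np.testing.assert_allclose(
            np.r_[est.intercept_, est.coef_],
            np.r_[base.intercept_, base.coef_],
            atol=1e-4,
        )

    def test_prime_field_training_close_to_plaintext(self, small_data):
        X, y = small_data
        est = SecureLogisticRegression(
            setting="dishonest2", algorithm="approx", n_iter=8, random_state=3
        ).fit(X, y)  # default backend: field, frac_bits = 20
        base = NewtonLogisticRegression(
            variant="fixed_hessian", n_iter=8, sigmoid_mode="g3"
        ).fit(X, y)
        np.testing.assert_allclose(
            np.r_[est.intercept_, est.coef_],
            np.r_[base.intercept_, base.coef_],
            atol=1e-2,
        )

    def test_approximation_quality_ordering(self, rng):
        # both polynomial degrees track the full-Newton optimum; g7 at least
        # as closely as g3 in max-norm
        spec = SyntheticSpec(
            n_records=500, m_features=4,
            true_beta=np.array([1.0, -0.5, 0.25, 0.0]), seed=21,
        )
        X, y = generate_logistic_data(spec)
        ref = NewtonLogisticRegression(variant="full_newton", n_iter=25).fit(X, y)
        ref_beta = np.r_[ref.intercept_, ref.coef_]
        devs = {}
        for mode in ("g3", "g7"):
            est = SecureLogisticRegression(
                setting="honest3", algorithm="approx", sigmoid_mode=mode,
                backend="real", n_iter=10, random_state=4,
            ).fit(X, y)
            devs[mode] = np.max(np.abs(np.r_[est.intercept_, est.coef_] - ref_beta))
        # degree-3 bias grows with the largest fitted coefficient (~1.1 here);
        # degree 7 stays an order of magnitude closer
        assert devs["g7"] <= 0.15
        assert devs["g3"] <= 0.6
        assert devs["g7"] <= devs["g3"]

    def test_determinism_same_seed(self, small_data):
        X, y = small_data
        runs = [
            SecureLogisticRegression(n_iter=3, random_state=9).fit(X, y)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].coef_, runs[1].coef_)
        assert runs[0].ledger_ == runs[1].ledger_

    def test_setting_invariance_on_same_inputs(self, small_data):
        X, y = small_data
        betas = []
        for setting in ("honest3", "dishonest2"):
            est = SecureLogisticRegression(
                setting=setting, n_iter=5, random_state=2
            ).fit(X, y)
            betas.append(np.r_[est.intercept_, est.coef_])
        np.testing.assert_allclose(betas[0], betas[1], atol=2e-9)

    def test_party_count_mismatch_rejected(self, real_backend, rng, small_data):
        X, y = small_data
        config = TrainConfig(setting="dishonest2", n_iter=1)
        data = TrainingData(
            X=SharedMatrix.share(X, 3, real_backend, rng),
            y=SharedMatrix.share(y.reshape(-1, 1).astype(float), 3, real_backend, rng),
        )
        with pytest.raises(ConfigurationError):
            train(data, config)

    def test_sklearn_contract(self, small_data):
        from sklearn.base import clone

        X, y = small_data
        est = SecureLogisticRegression(n_iter=2, random_state=0)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.fit(X, y)
        proba = est.predict_proba(X)
        assert proba.shape == (len(y), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        acc = np.mean(est.predict(X) == y)
        assert acc > 0.6
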