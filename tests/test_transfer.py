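import numpy as np
import pytest

from kerneltransfer.kernels import KernelSpec
from kerneltransfer.regression import LinearModel, fit_kernel, min_norm_linear
from kerneltransfer.theory import linear_transfer_estimator
from kerneltransfer.transfer import (
    TransferModel,
    evaluate_classification,
    fit_projected,
    fit_projected_translated,
    fit_translated,
)

LAPLACE = KernelSpec("laplace", bandwidth=10.0)


def linear_source(rng, c_s, d):
    return LinearModel(weights=rng.standard_normal((c_s, d)))


class TestProjection:
    def test_realizable_target_has_zero_residual(self, rng):
        source = linear_source(rng, 3, 6)
        X_t = rng.standard_normal((10, 6))
        M = rng.standard_normal((2, 3))
        Y_t = (M @ source.predict(X_t)).T
        model = fit_projected(source, X_t, Y_t, head_spec="linear")
        assert np.allclose(model.predict(X_t), Y_t.T, atol=1e-9)

    def test_single_target_sample_interpolated(self, rng):
        source = linear_source(rng, 3, 4)
        X_t = rng.standard_normal((1, 4))
        Y_t = rng.standard_normal((1, 2))
        model = fit_projected(source, X_t, Y_t, head_spec="linear")
        assert np.allclose(model.predict(X_t), Y_t.T, atol=1e-9)

    def test_scalar_source_output_matches_least_squares(self, rng):
        # 1-d source outputs against noise labels: the head is a plain
        # 1-feature regression and shares its residual
        source = linear_source(rng, 1, 5)
        X_t = rng.standard_normal((20, 5))
        Y_t = rng.standard_normal((20, 2))
        model = fit_projected(source, X_t, Y_t, head_spec="linear")
        p = source.predict(X_t).ravel()
        resid_model = Y_t - model.predict(X_t).T
        coef = (Y_t.T @ p) / (p @ p)
        resid_direct = Y_t - np.outer(p, coef)
        assert np.allclose(
            np.linalg.norm(resid_model), np.linalg.norm(resid_direct), atol=1e-9
        )

    def test_constant_source_outputs_warn(self, rng):
        source = LinearModel(weights=np.zeros((2, 3)))
        with pytest.warns(RuntimeWarning, match="constant"):
            fit_projected(source, rng.standard_normal((5, 3)), rng.standard_normal((5, 2)))

    def test_identity_source_reduces_to_direct_fit(self, rng):
        # identity head input: projection is just a direct fit on the features
        d = 4
        source = LinearModel(weights=np.eye(d))
        X_t = rng.standard_normal((12, d))
        Y_t = rng.standard_normal((12, 2))
        proj = fit_projected(source, X_t, Y_t, head_spec=LAPLACE, ridge=0.1)
        direct = fit_kernel(LAPLACE, X_t, Y_t, ridge=0.1)
        Z = rng.standard_normal((6, d))
        assert np.allclose(proj.predict(Z), direct.predict(Z), atol=1e-8)


class TestTranslation:
    def test_zero_source_equals_baseline(self, rng):
        source = LinearModel(weights=np.zeros((2, 5)))
        X_t = rng.standard_normal((15, 5))
        Y_t = rng.standard_normal((15, 2))
        model = fit_translated(source, X_t, Y_t, head_spec=LAPLACE, ridge=0.2)
        baseline = fit_kernel(LAPLACE, X_t, Y_t, ridge=0.2)
        Z = rng.standard_normal((8, 5))
        assert np.allclose(model.predict(Z), baseline.predict(Z), atol=1e-8)

    def test_interpolating_source_needs_no_correction(self, rng):
        X_t = rng.standard_normal((10, 3))
        Y_t = rng.standard_normal((10, 2))
        source = fit_kernel(LAPLACE, X_t, Y_t, ridge=0.0)
        model = fit_translated(source, X_t, Y_t, head_spec=LAPLACE, ridge=0.0)
        head_out = model.head.predict(X_t)
        assert np.max(np.abs(head_out)) < 1e-6
        assert np.allclose(model.predict(X_t), Y_t.T, atol=1e-6)

    def test_residual_identity(self, rng):
        source = linear_source(rng, 2, 4)
        X_t = rng.standard_normal((12, 4))
        Y_t = rng.standard_normal((12, 2))
        model = fit_translated(source, X_t, Y_t, head_spec=LAPLACE, ridge=0.5)
        Z = rng.standard_normal((7, 4))
        assert np.allclose(
            model.predict(Z) - source.predict(Z), model.head.predict(Z), atol=1e-12
        )

    def test_label_dimension_mismatch_rejected(self, rng):
        source = linear_source(rng, 3, 4)
        with pytest.raises(ValueError, match="projected"):
            fit_translated(source, rng.standard_normal((5, 4)), rng.standard_normal((5, 2)))


class TestCombined:
    def test_additive_head_reproduces_translation(self, rng):
        # a combined head constrained to f([p|x]) = p + g(x) is translation
        source = linear_source(rng, 2, 5)
        X_t = rng.standard_normal((14, 5))
        Y_t = rng.standard_normal((14, 2))
        translated = fit_translated(source, X_t, Y_t, head_spec="linear")

        class AdditiveHead:
            def __init__(self, g, c_s):
                self.g, self.c_s = g, c_s

            def predict(self, concat):
                return concat[:, : self.c_s].T + self.g.predict(concat[:, self.c_s :])

        combined = TransferModel(
            mode="projected_translated",
            source=source,
            head=AdditiveHead(translated.head, 2),
        )
        Z = rng.standard_normal((9, 5))
        assert np.allclose(combined.predict(Z), translated.predict(Z), atol=1e-8)

    def test_dropping_feature_block_reproduces_projection(self, rng):
        # min-norm linear head on [P | 0] puts no weight on the zero block
        source = linear_source(rng, 3, 5)
        X_t = rng.standard_normal((10, 5))
        Y_t = rng.standard_normal((10, 2))
        proj = fit_projected(source, X_t, Y_t, head_spec="linear")
        P = source.predict(X_t).T
        padded = np.hstack([P, np.zeros_like(X_t)])
        head = min_norm_linear(padded.T, Y_t.T)
        assert np.allclose(head.weights[:, : P.shape[1]], proj.head.weights, atol=1e-8)
        assert np.max(np.abs(head.weights[:, P.shape[1] :])) < 1e-8

    def test_ntk_head_training_residual_bounded_by_direct_solve(self, rng):
        from kerneltransfer.kernels import gram_matrix

        source = linear_source(rng, 4, 8)
        X_t = rng.standard_normal((50, 8))
        Y_t = rng.standard_normal((50, 3))
        spec = KernelSpec("ntk_fc", depth=1, offset=True)
        ridge = 10.0
        model = fit_projected_translated(source, X_t, Y_t, head_spec=spec, ridge=ridge)
        resid = np.linalg.norm(Y_t - model.predict(X_t).T)
        concat = np.hstack([source.predict(X_t).T, X_t])
        K = gram_matrix(spec, concat)
        alphaT = np.linalg.solve(K + ridge * np.eye(50), Y_t)
        resid_direct = np.linalg.norm(Y_t - K @ alphaT)
        assert resid == pytest.approx(resid_direct, rel=1e-6)


class TestLinearEstimatorIdentity:
    def test_matches_theory_module_estimators(self, rng):
        # transfer operators on linear parts coincide with the closed-form
        # minimum-norm estimators of the linear theory
        d, n_s, n_t, c = 10, 6, 4, 3
        omega_s = rng.standard_normal((c, d))
        omega_t = rng.standard_normal((c, d))
        X_s = rng.standard_normal((d, n_s))
        X_t = rng.standard_normal((d, n_t))
        source = min_norm_linear(X_s, omega_s @ X_s)
        Y_t = (omega_t @ X_t).T

        proj = fit_projected(source, X_t.T, Y_t, head_spec="linear")
        W_proj = proj.head.weights @ source.weights
        expected = linear_transfer_estimator("projected", omega_s, omega_t, X_s, X_t)
        assert np.allclose(W_proj, expected, atol=1e-8)

        trans = fit_translated(source, X_t.T, Y_t, head_spec="linear")
        W_trans = source.weights + trans.head.weights
        expected = linear_transfer_estimator("translated", omega_s, omega_t, X_s, X_t)
        assert np.allclose(W_trans, expected, atol=1e-8)


class TestEvaluateClassification:
    def test_perfect_predictions(self, rng):
        Y = np.eye(4)[rng.integers(0, 4, 30)]
        model = LinearModel(weights=np.eye(4))
        assert evaluate_classification(model, Y, Y) == 1.0

    def test_negated_predictions_on_two_classes(self, rng):
        Y = np.eye(2)[rng.integers(0, 2, 20)]
        model = LinearModel(weights=-np.eye(2))
        assert evaluate_classification(model, Y, Y) == 0.0

    def test_random_three_class_accuracy_near_chance(self, rng):
        n = 10_000
        X = rng.standard_normal((n, 3))
        Y = np.eye(3)[rng.integers(0, 3, n)]
        model = LinearModel(weights=rng.standard_normal((3, 3)))
        acc = evaluate_classification(model, X, Y)
        assert acc == pytest.approx(1 / 3, abs=0.02)

    def test_empty_input_rejected(self):
        model = LinearModel(weights=np.eye(2))
        with pytest.raises(ValueError, match="empty"):
            evaluate_classification(model, np.zeros((0, 2)), np.zeros((0, 2)))
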