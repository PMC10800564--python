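import math

import numpy as np
import pytest

from npca import (
    DataMatrix,
    TrainConfig,
    encode,
    forward,
    gradients,
    init_model,
    reconstruction_loss,
    standardize,
    svd_pca,
    train,
    variance_captured,
)
from npca.network import NPCAParams


def finite_difference_gradients(model, values, h=1e-5):
    """Independent numerical-differentiation oracle: central differences of
    the loss w.r.t. every parameter."""
    def loss():
        _, recon = forward(model, values)
        return reconstruction_loss(recon, values)

    arrays = (
        [("encoder_weights", model.encoder_weights)]
        + [(f"decoder_w{i}", w) for i, w in enumerate(model.decoder_weights)]
        + [(f"decoder_b{i}", b) for i, b in enumerate(model.decoder_biases)]
    )
    out = {}
    for name, arr in arrays:
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + h
            f1 = loss()
            arr[idx] = orig - h
            f2 = loss()
            arr[idx] = orig
            g[idx] = (f1 - f2) / (2 * h)
        out[name] = g
    return out


def max_relative_gradient_error(model, values):
    analytic = gradients(model, values)
    flat_analytic = (
        [("encoder_weights", analytic["encoder_weights"])]
        + [(f"decoder_w{i}", w) for i, w in enumerate(analytic["decoder_weights"])]
        + [(f"decoder_b{i}", b) for i, b in enumerate(analytic["decoder_biases"])]
    )
    numeric = finite_difference_gradients(model, values)
    worst = 0.0
    for name, g in flat_analytic:
        fd = numeric[name]
        rel = np.abs(g - fd) / np.maximum(np.maximum(np.abs(g), np.abs(fd)), 1e-8)
        worst = max(worst, float(rel.max()))
    return worst


@pytest.fixture
def tiny_standardized(rng):
    X = DataMatrix(values=rng.normal(size=(20, 6)))
    Z, _ = standardize(X)
    return Z


class TestInitModel:
    def test_same_seed_identical(self, tiny_standardized):
        a = init_model(tiny_standardized, seed=7)
        b = init_model(tiny_standardized, seed=7)
        np.testing.assert_array_equal(a.encoder_weights, b.encoder_weights)
        for wa, wb in zip(a.decoder_weights, b.decoder_weights):
            np.testing.assert_array_equal(wa, wb)

    def test_encoder_equals_pca_loadings(self, tiny_standardized):
        model = init_model(tiny_standardized, seed=0)
        basis = svd_pca(tiny_standardized, 2)
        np.testing.assert_array_equal(model.encoder_weights, basis.loadings)

    def test_initial_embedding_is_pca_scores(self, tiny_standardized):
        model = init_model(tiny_standardized, seed=0)
        basis = svd_pca(tiny_standardized, 2)
        scores = tiny_standardized.values @ basis.loadings
        np.testing.assert_array_equal(encode(model, tiny_standardized), scores)

    def test_biases_start_at_zero(self, tiny_standardized):
        model = init_model(tiny_standardized, seed=0)
        assert all(np.all(b == 0) for b in model.decoder_biases)

    def test_invalid_hidden_width(self, tiny_standardized):
        with pytest.raises(ValueError):
            init_model(tiny_standardized, hidden_width=0)


class TestForward:
    def test_zero_decoder_gives_zero_reconstruction(self, tiny_standardized):
        model = init_model(tiny_standardized, hidden_width=4, seed=0)
        model.decoder_weights = [np.zeros_like(w) for w in model.decoder_weights]
        _, recon = forward(model, tiny_standardized)
        np.testing.assert_array_equal(recon, np.zeros_like(tiny_standardized.values))

    def test_encoder_homogeneity(self, tiny_standardized):
        model = init_model(tiny_standardized, seed=0)
        emb, _ = forward(model, tiny_standardized)
        doubled = tiny_standardized.values * 2.0
        emb2, _ = forward(model, doubled)
        np.testing.assert_allclose(emb2, 2.0 * emb, atol=1e-12)

    def test_hand_computed_single_sample(self):
        """One sample, m=3, d=2, hand-set weights: reconstruction matches
        scalar arithmetic done with math.tanh, to 1e-12."""
        x = np.array([[0.5, -0.25, 0.1]])
        enc = np.array([[0.2, -0.1], [0.3, 0.4], [-0.5, 0.6]])
        w1 = np.array([[0.1, -0.2], [0.3, 0.05]])
        w2 = np.array([[0.4, 0.2], [-0.1, 0.3]])
        w3 = np.array([[0.7, -0.6, 0.5], [0.2, 0.1, -0.3]])
        b1, b2, b3 = np.array([0.01, -0.02]), np.array([0.03, 0.04]), np.array([0.1, 0.0, -0.1])
        model = NPCAParams(
            encoder_weights=enc, decoder_weights=[w1, w2, w3],
            decoder_biases=[b1, b2, b3], hidden_width=2,
        )
        # scalar forward pass
        z = [sum(x[0][i] * enc[i][j] for i in range(3)) for j in range(2)]
        h1 = [math.tanh(sum(z[i] * w1[i][j] for i in range(2)) + b1[j]) for j in range(2)]
        h2 = [math.tanh(sum(h1[i] * w2[i][j] for i in range(2)) + b2[j]) for j in range(2)]
        y = [sum(h2[i] * w3[i][j] for i in range(2)) + b3[j] for j in range(3)]
        emb, recon = forward(model, x)
        np.testing.assert_allclose(emb[0], z, atol=1e-12)
        np.testing.assert_allclose(recon[0], y, atol=1e-12)

    def test_shape_mismatch_rejected(self, tiny_standardized):
        model = init_model(tiny_standardized, seed=0)
        with pytest.raises(ValueError, match="features"):
            forward(model, np.ones((3, 4)))


class TestLossAndVarianceCaptured:
    def test_perfect_reconstruction_zero_loss(self, tiny_standardized):
        assert reconstruction_loss(tiny_standardized.values, tiny_standardized) == 0.0

    def test_single_entry_error(self):
        X = np.zeros((10, 10))
        recon = X.copy()
        recon[3, 7] = 1.0
        assert reconstruction_loss(recon, X) == pytest.approx(0.005)

    def test_zero_predictor_on_standardized_data(self, rng):
        X = DataMatrix(values=rng.normal(size=(500, 20)) * 3.0 + 1.0)
        Z, _ = standardize(X)
        E = reconstruction_loss(np.zeros_like(Z.values), Z)
        assert E == pytest.approx(0.5, abs=1e-12)
        assert variance_captured(E) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "E,expected", [(0.0, 100.0), (0.5, 0.0), (0.00125, 99.75)]
    )
    def test_variance_captured_formula(self, E, expected):
        assert variance_captured(E) == pytest.approx(expected)

    def test_shape_mismatch_rejected(self, tiny_standardized):
        with pytest.raises(ValueError, match="mismatch"):
            reconstruction_loss(np.zeros((3, 3)), tiny_standardized)


class TestGradients:
    def test_zero_residual_zero_gradients(self, rng):
        """Perfect reconstruction on the batch makes every gradient vanish.
        Constructed exactly: a zero decoder outputs zeros, so the all-zeros
        batch has zero residual."""
        X = DataMatrix(values=rng.normal(size=(10, 4)))
        Z, _ = standardize(X)
        model = init_model(Z, hidden_width=3, seed=1)
        model.decoder_weights = [np.zeros_like(w) for w in model.decoder_weights]
        g = gradients(model, np.zeros((6, 4)))
        for arr in [g["encoder_weights"], *g["decoder_weights"], *g["decoder_biases"]]:
            np.testing.assert_array_equal(arr, np.zeros_like(arr))

    def test_output_bias_gradient_closed_form(self, rng):
        """∂E/∂b₃ equals the per-feature mean residual divided by m (the
        chain rule done by hand under the per-entry-mean loss)."""
        X = DataMatrix(values=rng.normal(size=(15, 5)))
        Z, _ = standardize(X)
        model = init_model(Z, hidden_width=4, seed=2)
        _, recon = forward(model, Z)
        g = gradients(model, Z.values)
        expected = (recon - Z.values).mean(axis=0) / Z.n_features
        np.testing.assert_allclose(g["decoder_biases"][2], expected, atol=1e-14)

    @pytest.mark.parametrize("activation", ["tanh", "sigmoid", "relu"])
    def test_matches_finite_differences(self, rng, activation):
        X = DataMatrix(values=rng.normal(size=(12, 5)))
        Z, _ = standardize(X)
        model = init_model(Z, hidden_width=6, activation_name=activation, seed=3)
        for b in model.decoder_biases:
            b += rng.normal(scale=0.05, size=b.shape)
        if activation == "relu":
            # keep pre-activations away from the kink where the derivative
            # is discontinuous and finite differences are meaningless
            tol = 1e-4
        else:
            tol = 1e-5
        assert max_relative_gradient_error(model, Z.values) < tol

    def test_empty_batch_rejected(self, tiny_standardized):
        model = init_model(tiny_standardized, seed=0)
        with pytest.raises(ValueError, match="nonempty"):
            gradients(model, np.empty((0, 6)))


class TestTrain:
    def test_full_batch_small_lr_monotone(self, rng):
        X = DataMatrix(values=rng.normal(size=(30, 4)))
        Z, _ = standardize(X)
        config = TrainConfig(
            learning_rate=1e-3, epochs=200, batch_size="full", seed=0, patience=0
        )
        result = train(Z, config)
        assert np.all(np.diff(result.loss_history) <= 0)

    def test_frozen_encoder_bitwise_unchanged(self, tiny_standardized):
        model = init_model(tiny_standardized, seed=4)
        before = model.encoder_weights.copy()
        config = TrainConfig(epochs=50, seed=4, freeze_encoder=True, patience=0)
        result = train(tiny_standardized, config, model)
        np.testing.assert_array_equal(result.model.encoder_weights, before)

    def test_bit_identical_reruns(self, tiny_standardized):
        config = TrainConfig(epochs=30, seed=5, patience=0)
        a = train(tiny_standardized, config)
        b = train(tiny_standardized, config)
        np.testing.assert_array_equal(a.loss_history, b.loss_history)
        np.testing.assert_array_equal(
            a.model.encoder_weights, b.model.encoder_weights
        )
        assert a.final_loss == b.final_loss

    def test_final_loss_is_last_history_entry(self, tiny_standardized):
        result = train(tiny_standardized, TrainConfig(epochs=20, seed=0, patience=0))
        assert result.final_loss == result.loss_history[-1]
        assert result.variance_captured_pct == pytest.approx(
            (1 - 2 * result.final_loss) * 100
        )

    def test_snapshots_recorded(self, tiny_standardized):
        config = TrainConfig(epochs=20, seed=0, snapshot_every=5, patience=0)
        result = train(tiny_standardized, config)
        epochs = [e for e, _ in result.embedding_snapshots]
        assert epochs == [0, 5, 10, 15, 20]
        for _, snap in result.embedding_snapshots:
            assert snap.shape == (20, 2)

    def test_divergence_raises_actionable_error(self, tiny_standardized):
        config = TrainConfig(learning_rate=1e6, epochs=50, seed=0)
        with pytest.raises(FloatingPointError, match="learning rate"):
            train(tiny_standardized, config)

    def test_early_stopping_shortens_history(self, tiny_standardized):
        config = TrainConfig(
            epochs=400, seed=0, patience=5, min_delta=1e-2, batch_size="full",
            learning_rate=1e-4,
        )
        result = train(tiny_standardized, config)
        assert len(result.loss_history) < 400


class TestEncode:
    def test_matches_forward_embedding(self, tiny_standardized):
        model = init_model(tiny_standardized, seed=0)
        emb, _ = forward(model, tiny_standardized)
        np.testing.assert_array_equal(encode(model, tiny_standardized), emb)

    def test_linearity(self, rng, tiny_standardized):
        model = init_model(tiny_standardized, seed=0)
        x1, x2 = tiny_standardized.values[0], tiny_standardized.values[1]
        combo = 0.3 * x1 + 0.7 * x2
        e = encode(model, combo[None, :])
        e1 = encode(model, x1[None, :])
        e2 = encode(model, x2[None, :])
        np.testing.assert_allclose(e, 0.3 * e1 + 0.7 * e2, atol=1e-12)
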