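import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from odormetric import (
    DeepTripletEmbedder,
    embed,
    exp_triplet_loss,
    margin_triplet_loss,
    perceptual_distance,
)
from odormetric.deep import _MLP
from odormetric.synthetic import sample_triplets_from_distances


class TestExpTripletLoss:
    def test_zero_margin_gives_one(self):
        a, p, n = np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
        assert exp_triplet_loss(a, p, n) == pytest.approx(1.0)

    def test_ln2_margin_gives_half(self):
        # ||a-p||^2 = 0, ||a-n||^2 = ln 2 -> exp(-ln 2) = 0.5
        a = np.zeros(2)
        n = np.array([np.sqrt(np.log(2)), 0.0])
        assert exp_triplet_loss(a, a, n) == pytest.approx(0.5)

    def test_batch_sums(self):
        a = np.zeros((2, 3))
        p = np.eye(2, 3)
        n = np.eye(2, 3)  # zero margin per row -> 1 + 1
        assert exp_triplet_loss(a, p, n) == pytest.approx(2.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            exp_triplet_loss(np.zeros(2), np.zeros(3), np.zeros(3))

    def test_strictly_decreasing_in_margin(self):
        # finite-difference check: dL/dmargin < 0 everywhere we probe
        a = np.zeros(1)
        for margin in (-2.0, -0.5, 0.0, 0.5, 3.0):
            def loss(m):
                n = np.array([np.sqrt(max(m, 0.0))]) if m >= 0 else np.zeros(1)
                p = np.zeros(1) if m >= 0 else np.array([np.sqrt(-m)])
                return exp_triplet_loss(a, p, n)

            eps = 1e-5
            assert loss(margin + eps) < loss(margin - eps)

    def test_margin_loss_hinge(self):
        a, p, n = np.zeros(2), np.zeros(2), np.array([2.0, 0.0])
        # gap = 0 - 4: margin 1 -> max(0, 1 - 4) = 0
        assert margin_triplet_loss(a, p, n, margin=1.0) == 0.0
        assert margin_triplet_loss(a, p, a, margin=1.0) == pytest.approx(1.0)


def _hand_net():
    # 2 -> 2 -> 2 network with hand-set weights (last layer linear, no bias)
    W0 = np.array([[1.0, -1.0], [0.5, 2.0]])
    b0 = np.array([0.1, -0.2])
    W1 = np.array([[2.0, 0.0], [1.0, 1.0]])
    return _MLP(weights=[W0, W1], biases=[b0, np.zeros(2)])


def _fitted_stub():
    model = DeepTripletEmbedder(hidden_layer_sizes=(2,), n_components=2, epochs=0)
    model.net_ = _hand_net()
    model.n_features_in_ = 2
    return model


class TestForwardPass:
    def test_matches_hand_computation(self):
        model = _fitted_stub()
        x = np.array([1.0, 2.0])
        h = np.maximum(_hand_net().weights[0] @ x + _hand_net().biases[0], 0.0)
        expected = _hand_net().weights[1] @ h
        np.testing.assert_allclose(model.transform(x)[0], expected)

    def test_deterministic_and_row_preserving(self, rng):
        model = _fitted_stub()
        X = rng.normal(size=(7, 2))
        Z1, Z2 = model.transform(X), model.transform(X)
        np.testing.assert_array_equal(Z1, Z2)
        assert Z1.shape == (7, 2)
        np.testing.assert_allclose(model.transform(X[3]), Z1[3][None, :])

    def test_single_molecule_single_row(self):
        model = _fitted_stub()
        assert embed(model, np.array([[0.3, -0.4]])).shape == (1, 2)

    def test_perceptual_distance_properties(self, rng):
        model = _fitted_stub()
        x, y = rng.normal(size=2), rng.normal(size=2)
        assert perceptual_distance(model, x, x) == 0.0
        assert perceptual_distance(model, x, y) == pytest.approx(
            perceptual_distance(model, y, x)
        )
        zx, zy = model.transform(x)[0], model.transform(y)[0]
        assert perceptual_distance(model, x, y) == pytest.approx(
            ((zx - zy) ** 2).sum()
        )

    def test_dimension_mismatch(self):
        model = _fitted_stub()
        with pytest.raises(ValueError):
            model.transform(np.zeros((2, 5)))


def _toy_problem(seed=0, n=40, d=6):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d)) / np.sqrt(2 * d)
    D = squareform(pdist(X, metric="sqeuclidean"))
    train = sample_triplets_from_distances(D, 2000, seed=seed)
    val = sample_triplets_from_distances(D, 500, seed=seed + 1)
    return X, train, val


class TestTraining:
    def test_zero_epochs_returns_initialized_model(self):
        X, train, _ = _toy_problem()
        model = DeepTripletEmbedder(epochs=0, random_state=1).fit(X, train.triples)
        assert len(model.train_loss_trace_) == 0
        assert model.transform(X).shape == (40, 25)

    def test_fixed_seed_reproducible_traces(self):
        X, train, val = _toy_problem()
        kw = dict(hidden_layer_sizes=(16, 8), n_components=4, epochs=5, random_state=3)
        m1 = DeepTripletEmbedder(**kw).fit(X, train.triples, validation_triplets=val.triples)
        m2 = DeepTripletEmbedder(**kw).fit(X, train.triples, validation_triplets=val.triples)
        np.testing.assert_array_equal(m1.train_loss_trace_, m2.train_loss_trace_)
        np.testing.assert_array_equal(m1.val_tga_trace_, m2.val_tga_trace_)

    def test_loss_decreases_and_best_epoch_tracked(self):
        X, train, val = _toy_problem(seed=5)
        model = DeepTripletEmbedder(
            hidden_layer_sizes=(16, 8), n_components=4, epochs=20, random_state=5
        ).fit(X, train.triples, validation_triplets=val.triples)
        assert model.train_loss_trace_[-1] < model.train_loss_trace_[0]
        assert 1 <= model.best_epoch_ <= 20
        assert len(model.val_tga_trace_) == 20

    def test_final_bias_stays_zero(self):
        X, train, _ = _toy_problem(seed=6)
        model = DeepTripletEmbedder(
            hidden_layer_sizes=(8,), n_components=3, epochs=10, random_state=6
        ).fit(X, train.triples)
        np.testing.assert_array_equal(model.net_.biases[-1], np.zeros(3))

    def test_margin_loss_variant_trains(self):
        X, train, _ = _toy_problem(seed=7)
        model = DeepTripletEmbedder(
            hidden_layer_sizes=(8,), n_components=3, epochs=5,
            loss="margin", random_state=7,
        ).fit(X, train.triples)
        assert np.isfinite(model.train_loss_trace_).all()

    def test_empty_training_set_rejected(self):
        X, _, _ = _toy_problem()
        with pytest.raises(ValueError):
            DeepTripletEmbedder(epochs=1).fit(X, np.empty((0, 3), dtype=int))

    def test_output_orthogonal_invariance(self, rng):
        # relabeling output coordinates by an orthogonal transform of the
        # final layer leaves d_P unchanged
        X, train, _ = _toy_problem(seed=8)
        model = DeepTripletEmbedder(
            hidden_layer_sizes=(8,), n_components=3, epochs=3, random_state=8
        ).fit(X, train.triples)
        D1 = model.pairwise_distance(X)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        model.net_.weights[-1] = Q @ model.net_.weights[-1]
        np.testing.assert_allclose(model.pairwise_distance(X), D1, atol=1e-9)

    def test_save_load_round_trip(self, tmp_path):
        X, train, val = _toy_problem(seed=9)
        model = DeepTripletEmbedder(
            hidden_layer_sizes=(8,), n_components=3, epochs=3, random_state=9
        ).fit(X, train.triples, validation_triplets=val.triples)
        model.save(tmp_path / "deep.npz")
        back = DeepTripletEmbedder.load(tmp_path / "deep.npz")
        np.testing.assert_allclose(back.transform(X), model.transform(X))
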