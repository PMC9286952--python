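"""RBM conditionals and CD-1 against exact-enumeration oracles; DBN training."""

import itertools

import numpy as np
import pytest

from iaoadbn import dbn
from iaoadbn.dbn import (
    DbnConfig,
    DbnModel,
    RbmParams,
    cd1_update,
    finetune_and_predict,
    hidden_given_visible,
    load_model,
    predict,
    pretrain,
    rbm_energy,
    save_model,
    train_dbn,
    visible_given_hidden,
)


def _tiny_rbm(m=3, n=2, seed=0, scale=0.7):
    rng = np.random.default_rng(seed)
    return RbmParams(
        rng.normal(0, scale, (m, n)), rng.normal(0, scale, m), rng.normal(0, scale, n)
    )


def _enumerate_joint(params):
    """Exact joint P(v, h) over all binary states via the partition function."""
    m, n = params.n_visible, params.n_hidden
    states_v = list(itertools.product([0, 1], repeat=m))
    states_h = list(itertools.product([0, 1], repeat=n))
    energies = np.array(
        [[rbm_energy(params, np.array(v, float), np.array(h, float)) for h in states_h]
         for v in states_v]
    )
    w = np.exp(-energies)
    return states_v, states_h, w / w.sum()


class TestEnergy:
    def test_zero_parameters(self):
        p = RbmParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        assert rbm_energy(p, np.ones(3), np.ones(2)) == 0.0

    def test_one_by_one(self):
        p = RbmParams(np.ones((1, 1)), np.zeros(1), np.zeros(1))
        assert rbm_energy(p, np.ones(1), np.ones(1)) == -1.0

    def test_linear_in_visible_bias(self):
        p = _tiny_rbm()
        v, h = np.array([1.0, 0.0, 1.0]), np.array([1.0, 0.0])
        e1 = rbm_energy(p, v, h)
        p2 = RbmParams(p.weights, 2 * p.visible_bias, p.hidden_bias)
        e2 = rbm_energy(p2, v, h)
        assert e2 - e1 == pytest.approx(-(p.visible_bias @ v))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            rbm_energy(_tiny_rbm(), np.ones(2), np.ones(2))


class TestConditionals:
    def test_zero_parameters_give_half(self):
        p = RbmParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        np.testing.assert_allclose(hidden_given_visible(p, np.ones(3)), 0.5)
        np.testing.assert_allclose(visible_given_hidden(p, np.ones(2)), 0.5)

    def test_saturation(self):
        p = RbmParams(np.zeros((2, 1)), np.zeros(2), np.array([50.0]))
        assert hidden_given_visible(p, np.zeros(2))[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_hidden_conditional_matches_enumeration(self, seed):
        p = _tiny_rbm(seed=seed)
        states_v, states_h, joint = _enumerate_joint(p)
        for i, v in enumerate(states_v):
            pv = joint[i].sum()
            exact = np.array(
                [sum(joint[i, j] for j, h in enumerate(states_h) if h[k] == 1) / pv
                 for k in range(p.n_hidden)]
            )
            np.testing.assert_allclose(
                hidden_given_visible(p, np.array(v, float)), exact, atol=1e-12
            )

    def test_transpose_symmetry(self):
        p = _tiny_rbm()
        swapped = RbmParams(p.weights.T, p.hidden_bias, p.visible_bias)
        h = np.array([1.0, 0.0])
        np.testing.assert_allclose(
            visible_given_hidden(p, h), hidden_given_visible(swapped, h)
        )


class TestContrastiveDivergence:
    def test_zero_learning_rate_is_identity(self):
        p = _tiny_rbm()
        w0 = p.weights.copy()
        cd1_update(p, np.array([[1.0, 0.0, 1.0]]), 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(p.weights, w0)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            cd1_update(_tiny_rbm(), np.empty((0, 3)), 0.1, np.random.default_rng(0))

    @pytest.mark.parametrize("seed", range(3))
    def test_data_term_matches_enumeration_oracle(self, seed):
        """With sampling disabled, the positive statistics of the update are
        the exact conditional expectations E[v h' | v] = v P(h=1|v)."""
        p = _tiny_rbm(seed=seed)
        batch = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        h_probs = hidden_given_visible(p, batch)
        expected_data_term = batch.T @ h_probs / len(batch)

        # reconstruct the data term from two updates that differ only in the
        # negative phase being frozen (alpha=1, manually recompute)
        v0 = batch
        h0 = hidden_given_visible(p, v0)
        v1 = visible_given_hidden(p, h0)
        h1 = hidden_given_visible(p, v1)
        w_before = p.weights.copy()
        cd1_update(p, batch, 1.0, np.random.default_rng(0), sample_hidden=False)
        data_term = (p.weights - w_before) + v1.T @ h1 / len(batch)
        np.testing.assert_allclose(data_term, expected_data_term, atol=1e-12)

    def test_repeated_cd_raises_likelihood_of_training_vector(self):
        p = _tiny_rbm(seed=4, scale=0.1)
        target = np.array([1.0, 1.0, 0.0])

        def log_p(params):
            states_v, _, joint = _enumerate_joint(params)
            return np.log(joint[states_v.index((1, 1, 0))].sum())

        before = log_p(p)
        rng = np.random.default_rng(0)
        for _ in range(50):
            cd1_update(p, target[None, :], 0.1, rng)
        assert log_p(p) > before

    def test_stability_many_updates(self):
        p = _tiny_rbm(seed=5)
        rng = np.random.default_rng(1)
        data = (rng.random((10_000, 3)) < 0.5).astype(float)
        for row in data:
            cd1_update(p, row[None, :], 0.1, rng)
        for arr in (p.weights, p.visible_bias, p.hidden_bias):
            assert np.all(np.isfinite(arr))
        probs = hidden_given_visible(p, data[:100])
        assert np.all((probs > 0) & (probs < 1))


class TestPretrain:
    def test_zero_epochs_returns_initial_params(self):
        cfg = DbnConfig(layer_sizes=(4,), pretrain_epochs=0, seed=7)
        data = np.random.default_rng(0).random((20, 3))
        stack = pretrain(cfg, data)
        expected = RbmParams.initialize(3, 4, np.random.default_rng(7))
        np.testing.assert_array_equal(stack[0].weights, expected.weights)

    def test_layer_dimensions_chain(self):
        cfg = DbnConfig(layer_sizes=(8, 3), pretrain_epochs=1, seed=0)
        data = np.random.default_rng(0).random((30, 5))
        stack = pretrain(cfg, data)
        assert (stack[0].n_visible, stack[0].n_hidden) == (5, 8)
        assert (stack[1].n_visible, stack[1].n_hidden) == (8, 3)

    def test_reconstruction_error_decreases(self):
        rng = np.random.default_rng(3)
        data = np.where(rng.random((200, 6)) < 0.5, 0.05, 0.95)
        data[:, 3:] = data[:, :3]  # strong structure to model
        cfg = DbnConfig(layer_sizes=(6,), pretrain_epochs=30, batch_size=10, seed=0)

        def recon_error(params):
            h = hidden_given_visible(params, data)
            return float(np.mean((visible_given_hidden(params, h) - data) ** 2))

        init = RbmParams.initialize(6, 6, np.random.default_rng(0))
        trained = pretrain(cfg, data)[0]
        assert recon_error(trained) < recon_error(init)


class TestSupervised:
    def test_separable_blobs_high_accuracy(self, blobs_separable):
        cfg = DbnConfig(layer_sizes=(16, 8), pretrain_epochs=10, finetune_epochs=60, seed=0)
        model = train_dbn(blobs_separable.values, blobs_separable.labels, cfg)
        acc = np.mean(predict(model, blobs_separable.values) == blobs_separable.labels)
        assert acc >= 0.95

    def test_memorizes_tiny_set(self):
        rng = np.random.default_rng(0)
        X = rng.random((12, 4))
        y = np.array([0, 1] * 6)
        cfg = DbnConfig(layer_sizes=(16,), pretrain_epochs=5, finetune_epochs=400,
                        batch_size=4, seed=0)
        model = train_dbn(X, y, cfg)
        assert np.mean(predict(model, X) == y) == 1.0

    def test_permuted_labels_give_chance_level(self, blobs_separable):
        rng = np.random.default_rng(5)
        y = rng.permutation(blobs_separable.labels)
        from sklearn.model_selection import StratifiedKFold

        cfg = DbnConfig(layer_sizes=(8,), pretrain_epochs=5, finetune_epochs=40, seed=0)
        accs = []
        for tr, te in StratifiedKFold(5, shuffle=True, random_state=0).split(
            blobs_separable.values, y
        ):
            m = train_dbn(blobs_separable.values[tr], y[tr], cfg)
            accs.append(np.mean(predict(m, blobs_separable.values[te]) == y[te]))
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_finetune_and_predict_from_pretrained_stack(self, blobs_separable):
        X, y = blobs_separable.values, blobs_separable.labels
        cfg = DbnConfig(layer_sizes=(8,), pretrain_epochs=5, finetune_epochs=80, seed=0)
        rng = np.random.default_rng(cfg.seed)
        fmin, fmax = X.min(0), X.max(0)
        X01 = (X - fmin) / np.where(fmax > fmin, fmax - fmin, 1.0)
        stack = pretrain(cfg, X01, rng)
        model = DbnModel(stack, rng.normal(0, 0.1, (8, 2)), np.zeros(2), fmin, fmax)
        pred, acc = finetune_and_predict(model, (X[:200], y[:200]), (X[200:], y[200:]), cfg)
        assert pred.shape == (100,)
        assert acc >= 0.9

    def test_single_class_training_rejected(self):
        X = np.random.default_rng(0).random((10, 3))
        with pytest.raises(ValueError, match="single class"):
            train_dbn(X, np.zeros(10, dtype=int), DbnConfig(layer_sizes=(4,)))

    def test_end_to_end_determinism(self, blobs_separable):
        cfg = DbnConfig(layer_sizes=(8,), pretrain_epochs=3, finetune_epochs=20, seed=11)
        m1 = train_dbn(blobs_separable.values, blobs_separable.labels, cfg)
        m2 = train_dbn(blobs_separable.values, blobs_separable.labels, cfg)
        np.testing.assert_array_equal(m1.rbms[0].weights, m2.rbms[0].weights)
        np.testing.assert_array_equal(m1.output_weights, m2.output_weights)

    def test_model_roundtrip(self, tmp_path, blobs_separable):
        cfg = DbnConfig(layer_sizes=(6,), pretrain_epochs=2, finetune_epochs=10, seed=0)
        model = train_dbn(blobs_separable.values, blobs_separable.labels, cfg)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(
            predict(model, blobs_separable.values), predict(loaded, blobs_separable.values)
        )


def test_config_validation():
    with pytest.raises(ValueError):
        DbnConfig(layer_sizes=(0,))
    with pytest.raises(ValueError):
        DbnConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        DbnConfig(momentum=1.0)
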