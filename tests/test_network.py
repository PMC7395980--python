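"""Architecture contracts, gradients, loss, and the training loop."""

import numpy as np
import pytest

from mvsir.network import (MVSIRClassifier, MVSIRNetwork, NetConfig,
                           ResidualBlock, TrainConfig, bce_loss,
                           build_sir_submodel, sigmoid)

TINY = dict(patch_size=8, stem_channels=3, residual1_widths=(3, 3, 3),
            residual2_widths=(5, 5, 5), fc_width=7, fusion_width=6)


class TestResidualBlock:
    def test_zero_main_path_exposes_identity_shortcut(self):
        rng = np.random.default_rng(0)
        block = ResidualBlock(4, (4, 4, 4), rng=rng, dtype=np.float64)
        for conv in (block.conv1, block.conv2, block.conv3):
            conv.w.value[...] = 0
            conv.b.value[...] = 0
        x = rng.standard_normal((2, 6, 6, 4))
        assert np.allclose(block.forward(x), np.maximum(x, 0))

    def test_shape_preserved_at_published_size(self):
        rng = np.random.default_rng(0)
        block = ResidualBlock(32, (32, 32, 32), rng=rng)
        x = rng.standard_normal((1, 15, 15, 32)).astype(np.float32)
        assert block.forward(x).shape == (1, 15, 15, 32)

    def test_preactivation_additivity(self):
        rng = np.random.default_rng(1)
        block = ResidualBlock(3, (3, 3, 3), rng=rng, dtype=np.float64)
        x = rng.standard_normal((2, 5, 5, 3))
        assert np.allclose(block.forward(x), np.maximum(block.main_path(x) + x, 0))

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ResidualBlock(4, (4, 4, 8), rng=np.random.default_rng(0))


class TestStageShapes:
    def test_published_submodel_stage_shapes(self):
        net = MVSIRNetwork(NetConfig(), seed=0)
        shapes = net.stage_shapes()
        assert shapes["c1"] == (30, 30, 32)
        assert shapes["p2"] == (15, 15, 32)
        assert shapes["block1"] == (15, 15, 32)
        assert shapes["secondary"] == (15, 15, 32)
        assert shapes["concat"] == (15, 15, 64)
        assert shapes["p3"] == (8, 8, 64)
        assert shapes["c4"] == (8, 8, 128)
        assert shapes["block2"] == (8, 8, 128)
        assert shapes["p5"] == (8, 8, 128)
        assert shapes["f7"] == (256,)
        assert shapes["f8"] == (256,)
        assert shapes["fusion_in"] == (6 * 256,)

    def test_submodel_embedding_width(self):
        sm = build_sir_submodel(seed=0)
        x = np.zeros((2, 30, 30, 1), dtype=np.float32)
        assert sm.forward(x, x).shape == (2, 256)

    def test_variant_parameter_counts_nest(self):
        counts = {v: MVSIRNetwork(NetConfig(variant=v), seed=0).n_parameters()
                  for v in ("MV-CNN", "MV-I-CNN", "MV-SIR")}
        assert counts["MV-CNN"] < counts["MV-I-CNN"] < counts["MV-SIR"]

    def test_wrong_stream_count_rejected(self):
        net = MVSIRNetwork(NetConfig(**TINY), seed=0)
        with pytest.raises(ValueError):
            net.forward_logits(np.zeros((1, 5, 8, 8), dtype=np.float32))


class TestSigmoidAndLoss:
    def test_sigmoid_at_zero_is_half(self):
        assert sigmoid(0.0) == 0.5

    def test_sigmoid_bounded_and_stable(self):
        z = np.array([-1000.0, -10.0, 0.0, 10.0, 1000.0])
        p = sigmoid(z)
        assert np.all((p >= 0) & (p <= 1))
        assert np.all(np.diff(p) >= 0)

    def test_bce_closed_forms(self):
        assert bce_loss(np.array([1.0]), np.array([0.5])) == pytest.approx(np.log(2))
        assert bce_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0])) == \
            pytest.approx(0.0, abs=1e-6)

    def test_bce_matches_naive_summation_oracle(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50).astype(float)
        p = rng.uniform(0.01, 0.99, 50)
        naive = -sum(yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
                     for yi, pi in zip(y, p)) / 50
        assert bce_loss(y, p) == pytest.approx(naive, rel=1e-12)

    def test_bce_rejects_out_of_range_predictions(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([1.0]), np.array([1.2]))

    def test_probability_output_in_open_interval(self):
        net = MVSIRNetwork(NetConfig(**TINY), seed=2)
        x = np.random.default_rng(0).standard_normal((4, 6, 8, 8)).astype(np.float32)
        p = sigmoid(net.forward_logits(x))
        assert np.all((p > 0) & (p < 1))


class TestGradients:
    def test_backprop_matches_finite_differences_all_variants(self):
        """Full-network analytic gradients vs central differences (float64).

        Biases are perturbed away from zero first: with zero biases ReLU
        activations sit exactly on the kink where no derivative exists.
        """
        for variant in ("MV-SIR", "MV-I-CNN", "MV-CNN"):
            net = MVSIRNetwork(NetConfig(**TINY, variant=variant), seed=3,
                               dtype=np.float64)
            rinit = np.random.default_rng(9)
            for P in net.params():
                P.value += 0.05 * rinit.standard_normal(P.value.shape)
            rng = np.random.default_rng(0)
            X = rng.standard_normal((3, 6, 8, 8))
            y = np.array([1.0, 0.0, 1.0])

            def loss():
                return bce_loss(y, sigmoid(net.forward_logits(X)))

            for p in net.params():
                p.zero_grad()
            p_hat = sigmoid(net.forward_logits(X))
            net.backward_logits((p_hat - y) / len(y))
            params = net.params()
            rng2 = np.random.default_rng(1)
            for pi in rng2.choice(len(params), 10, replace=False):
                P = params[pi]
                flat = P.value.ravel()
                for k in rng2.choice(flat.size, 2, replace=False):
                    eps, old = 1e-6, flat[k]
                    flat[k] = old + eps
                    lp = loss()
                    flat[k] = old - eps
                    lm = loss()
                    flat[k] = old
                    num = (lp - lm) / (2 * eps)
                    ana = P.grad.ravel()[k]
                    assert abs(num - ana) <= 1e-5 * max(1.0, abs(num)), \
                        f"{variant} param {pi}[{k}]: fd {num} vs analytic {ana}"


class TestTraining:
    def _streams(self, n=64, seed=0, size=8):
        """Separable toy streams: positives have a bright centre blob."""
        rng = np.random.default_rng(seed)
        y = np.arange(n) % 2
        X = rng.normal(0, 0.3, (n, 6, size, size))
        X[y == 1, :, size // 2 - 1:size // 2 + 2, size // 2 - 1:size // 2 + 2] += 2.0
        return X.astype(np.float32), y

    def _clf(self, **kw):
        base = dict(variant="MV-SIR", patch_size=8, stem_channels=3,
                    fc_width=16, fusion_width=16, learning_rate=1e-3,
                    batch_size=16, epochs=1, validation_fraction=0.25,
                    random_state=0)
        base.update(kw)
        return MVSIRClassifier(**base)

    def test_one_epoch_emits_one_curve_row(self):
        X, y = self._streams()
        clf = self._clf().fit(X, y)
        assert len(clf.learning_curve_) == 1
        assert {"epoch", "acc", "loss", "val_acc", "val_loss"} <= \
            set(clf.learning_curve_.columns)

    def test_overfits_tiny_separable_set(self):
        X, y = self._streams(n=32)
        clf = self._clf(epochs=30, learning_rate=3e-3).fit(X, y)
        curve = clf.learning_curve_
        assert curve.loss.iloc[-3:].mean() < curve.loss.iloc[0]
        assert curve.acc.iloc[-1] > 0.6

    def test_seed_changes_final_weights(self):
        X, y = self._streams()
        a = self._clf(random_state=1).fit(X, y)
        b = self._clf(random_state=2).fit(X, y)
        wa = a.network_.state_arrays()
        wb = b.network_.state_arrays()
        assert any(not np.array_equal(x, z) for x, z in zip(wa, wb))

    def test_same_seed_reproduces_weights(self):
        X, y = self._streams()
        a = self._clf(random_state=5).fit(X, y)
        b = self._clf(random_state=5).fit(X, y)
        for x, z in zip(a.network_.state_arrays(), b.network_.state_arrays()):
            assert np.array_equal(x, z)

    def test_single_class_training_rejected(self):
        X, _ = self._streams()
        with pytest.raises(ValueError):
            self._clf().fit(X, np.zeros(len(X), dtype=int))

    def test_predict_proba_rows_sum_to_one(self):
        X, y = self._streams()
        clf = self._clf().fit(X, y)
        proba = clf.predict_proba(X[:8])
        assert proba.shape == (8, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_sklearn_params_round_trip(self):
        clf = self._clf()
        params = clf.get_params()
        clone = MVSIRClassifier(**params)
        assert clone.get_params() == params

    def test_checkpoint_save_load_preserves_predictions(self, tmp_path):
        X, y = self._streams()
        clf = self._clf().fit(X, y)
        clf.save(tmp_path / "model")
        back = MVSIRClassifier.load(tmp_path / "model")
        assert np.allclose(back.predict_proba(X[:8]), clf.predict_proba(X[:8]))

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(validation_fraction=1.5)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0)
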