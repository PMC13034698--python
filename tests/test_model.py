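"""GRU encoder, multimodal variants, training, and frozen transfer."""

import numpy as np
import pytest

from cometdr.autodiff import Tensor, bce_with_logits
from cometdr.model import (
    CometModel,
    GRUEncoder,
    ModelConfig,
    MultimodalData,
    extract_latent,
    load_checkpoint,
    parameter_checksum,
    prepare_omics,
    pretrain,
    save_checkpoint,
    train_model,
    transfer_and_finetune,
)


def _toy_ehr(n=40, T=5, D=3, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    seq = np.zeros((n, T, D))
    seq[:, :, 0] = z[:, None] + 0.2 * rng.standard_normal((n, T))
    masks = np.ones((n, T), dtype=bool)
    labels = (z > 0).astype(int)
    return seq, masks, labels


def _toy_multimodal(n=40, T=5, D=3, P=6, seed=0):
    seq, masks, labels = _toy_ehr(n, T, D, seed)
    rng = np.random.default_rng(seed + 1)
    omics = rng.standard_normal((n, P))
    omics[:, 0] += labels
    return MultimodalData(seq, masks, omics, labels)


def _config(mode, **kw):
    base = dict(layers=1, hidden_dim=6, dropout=0.0, learning_rate=0.1,
                lr_decay=0.01, batch_size=8, max_epochs=15, seed=0)
    base.update(kw)
    return ModelConfig(mode=mode, **base)


class TestConfig:
    def test_invalid_mode(self):
        with pytest.raises(ValueError, match="mode"):
            ModelConfig(mode="transformer")

    def test_invalid_dropout(self):
        with pytest.raises(ValueError, match="dropout"):
            _config("joint", dropout=1.0)


class TestForward:
    def test_probability_in_open_interval(self):
        data = _toy_multimodal()
        model = CometModel(_config("joint"), input_dim=3, n_proteins=6)
        prob, _, _ = model.forward(data.sequences, data.masks, data.omics)
        assert (prob > 0).all() and (prob < 1).all()

    def test_omics_only_ignores_sequences(self):
        data = _toy_multimodal()
        model = CometModel(_config("omics_only"), input_dim=None, n_proteins=6)
        p1 = model.predict_proba(data)
        other = MultimodalData(None, None, data.omics, data.labels)
        p2 = model.predict_proba(other)
        assert np.array_equal(p1, p2)

    def test_omics_shape_mismatch(self):
        model = CometModel(_config("omics_only"), input_dim=None, n_proteins=6)
        with pytest.raises(ValueError, match="omics input"):
            model.forward(omics=np.zeros((4, 5)))

    def test_combiner_is_bias_free(self):
        """Zeroing all component logits must give probability exactly 0.5."""
        model = CometModel(_config("comet"), input_dim=3, n_proteins=6)
        assert model.combiner.data.shape == (3, 1)
        for name, p in model.parameters().items():
            if name != "combiner.weight":
                p.data = np.zeros_like(p.data)
        data = _toy_multimodal()
        prob, _, _ = model.forward(data.sequences, data.masks, data.omics)
        assert np.all(prob == 0.5)

    def test_hand_computed_logit_with_identity_encoder(self):
        """Replace the encoder with an identity seam and hand-set weights."""

        class IdentityEncoder:
            input_dim = 2

            def forward(self, x, mask, train=False, rng=None):
                t = x if isinstance(x, Tensor) else Tensor(x)
                return t[:, -1, :]  # latent = last row

        model = CometModel(_config("joint", hidden_dim=2), input_dim=2, n_proteins=2)
        model.encoder = IdentityEncoder()
        model.ehr_head.weight.data = np.array([[1.0], [0.0]])
        model.ehr_head.bias.data = np.zeros(1)
        model.omics_head.weight.data = np.array([[1.0], [0.0]])
        model.omics_head.bias.data = np.zeros(1)
        model.joint_head.weight.data = np.zeros((4, 1))
        model.joint_head.bias.data = np.zeros(1)
        model.combiner.data = np.array([[1.0], [1.0], [0.0]])
        seq = np.array([[[0.0, 0.0], [0.3, 9.0]]])  # latent = (0.3, 9)
        omics = np.array([[0.5, 7.0]])
        prob, parts, latent = model.forward(seq, np.ones((1, 2), bool), omics)
        expected = 1.0 / (1.0 + np.exp(-(0.3 + 0.5)))
        assert prob[0] == pytest.approx(expected)
        assert parts["ehr"][0] == pytest.approx(0.3)
        assert parts["omics"][0] == pytest.approx(0.5)
        assert np.allclose(latent[0], [0.3, 9.0])

    def test_evaluation_forward_is_deterministic(self):
        data = _toy_multimodal()
        model = CometModel(_config("joint", dropout=0.4), input_dim=3, n_proteins=6)
        p1 = model.predict_proba(data)
        p2 = model.predict_proba(data)
        assert np.array_equal(p1, p2)


class TestGRUStep:
    def test_hand_computed_single_step(self):
        """1-layer, 1-step GRU against hand-evaluated gate arithmetic."""
        rng = np.random.default_rng(0)
        enc = GRUEncoder(input_dim=2, hidden_dim=2, layers=1, dropout=0.0, rng=rng)
        x = np.array([[[0.5, -1.0]]])  # (1, 1, 2)
        mask = np.ones((1, 1), dtype=bool)
        latent = enc.forward(x, mask).data[0]

        w_ih, w_hh = enc.w_ih[0].data, enc.w_hh[0].data
        b_ih, b_hh = enc.b_ih[0].data, enc.b_hh[0].data
        gi = x[0, 0] @ w_ih + b_ih
        gh = np.zeros(2) @ w_hh + b_hh
        sig = lambda v: 1 / (1 + np.exp(-v))
        r = sig(gi[:2] + gh[:2])
        z = sig(gi[2:4] + gh[2:4])
        n = np.tanh(gi[4:] + r * gh[4:])
        h = (1 - z) * n  # h_prev = 0
        assert np.allclose(latent, h)

    def test_all_padding_returns_initial_state(self):
        rng = np.random.default_rng(0)
        enc = GRUEncoder(2, 3, 1, 0.0, rng)
        latent = enc.forward(np.ones((2, 4, 2)), np.zeros((2, 4), bool)).data
        assert not latent.any()

    def test_identical_sequences_identical_latents(self):
        data = _toy_multimodal()
        model = CometModel(_config("ehr_only"), input_dim=3, n_proteins=None)
        seq = np.repeat(data.sequences[:1], 2, axis=0)
        masks = np.repeat(data.masks[:1], 2, axis=0)
        latents = extract_latent(model, seq, masks)
        assert np.array_equal(latents[0], latents[1])


class TestLoss:
    def test_bce_matches_hand_computed_batch(self):
        z = Tensor(np.array([[0.0], [2.0], [-1.0]]))
        y = np.array([[1.0], [0.0], [1.0]])
        loss = bce_with_logits(z, y)
        hand = np.mean(
            [np.log(2.0), 2.0 + np.log(1 + np.exp(-2.0)), 1.0 + np.log(1 + np.exp(-1.0))]
        )
        assert float(loss.data) == pytest.approx(hand)


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        seq, masks, labels = _toy_ehr()
        model, history = pretrain(_config("ehr_only", max_epochs=30), seq, masks, labels)
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_single_class_rejected(self):
        seq, masks, _ = _toy_ehr()
        with pytest.raises(ValueError, match="single class"):
            pretrain(_config("ehr_only"), seq, masks, np.ones(len(seq)))

    def test_patience_stops_by_epoch_six(self):
        """With held-out loss worsening from epoch 1, training stops after
        patience=5 unimproved epochs (6 epochs total)."""
        data = _toy_multimodal()
        model = CometModel(_config("omics_only", learning_rate=50.0, max_epochs=100),
                           input_dim=None, n_proteins=6)
        # absurd learning rate makes held-out loss blow up immediately
        history = train_model(
            model, MultimodalData(None, None, data.omics, data.labels),
            train_idx=np.arange(30), stop_idx=np.arange(30, 40),
        )
        assert len(history) <= 7
        assert "early stop" in history[-1]["stop"]

    def test_same_seed_identical_weights(self):
        seq, masks, labels = _toy_ehr()
        m1, _ = pretrain(_config("ehr_only"), seq, masks, labels)
        m2, _ = pretrain(_config("ehr_only"), seq, masks, labels)
        assert parameter_checksum(m1) == parameter_checksum(m2)


class TestTransfer:
    def test_encoder_frozen_through_finetuning(self):
        seq, masks, labels = _toy_ehr()
        pre, _ = pretrain(_config("ehr_only"), seq, masks, labels)
        before = parameter_checksum(pre, "encoder")
        data = _toy_multimodal()
        model, _ = transfer_and_finetune(pre, data, _config("comet"))
        assert parameter_checksum(model, "encoder") == before

    def test_heads_change_during_finetuning(self):
        seq, masks, labels = _toy_ehr()
        pre, _ = pretrain(_config("ehr_only"), seq, masks, labels)
        data = _toy_multimodal()
        config = _config("comet")
        fresh = CometModel(config, input_dim=3, n_proteins=6)
        model, _ = transfer_and_finetune(pre, data, config)
        assert parameter_checksum(model, "omics_head") != parameter_checksum(
            fresh, "omics_head"
        )

    def test_geometry_mismatch_rejected(self):
        seq, masks, labels = _toy_ehr()
        pre, _ = pretrain(_config("ehr_only"), seq, masks, labels)
        data = _toy_multimodal()
        with pytest.raises(ValueError, match="geometry"):
            transfer_and_finetune(pre, data, _config("comet", hidden_dim=12))

    def test_dropout_fixed_to_pretraining_value(self):
        seq, masks, labels = _toy_ehr()
        pre, _ = pretrain(_config("ehr_only", dropout=0.3, layers=2), seq, masks, labels)
        data = _toy_multimodal()
        model, _ = transfer_and_finetune(
            pre, data, _config("comet", dropout=0.1, layers=2)
        )
        assert model.config.dropout == 0.3


class TestLatent:
    def test_latent_dimension_equals_hidden_dim(self):
        data = _toy_multimodal()
        model = CometModel(_config("ehr_only", hidden_dim=6), input_dim=3, n_proteins=None)
        lat = extract_latent(model, data.sequences, data.masks)
        assert lat.shape == (data.n, 6)

    def test_omics_only_has_no_latent(self):
        model = CometModel(_config("omics_only"), input_dim=None, n_proteins=6)
        with pytest.raises(ValueError, match="no EHR encoder"):
            extract_latent(model, np.zeros((1, 2, 3)), np.ones((1, 2), bool))


class TestOmicsPreparation:
    def test_output_standardized(self):
        rng = np.random.default_rng(0)
        raw = rng.lognormal(3, 1, size=(30, 5))
        out = prepare_omics(raw)
        assert np.allclose(out.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(out.std(axis=0), 1, atol=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            prepare_omics(np.array([[1.0, 0.0]]))


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        data = _toy_multimodal()
        seq, masks, labels = _toy_ehr()
        pre, _ = pretrain(_config("ehr_only"), seq, masks, labels)
        model, _ = transfer_and_finetune(pre, data, _config("comet"))
        save_checkpoint(model, tmp_path / "model")
        loaded = load_checkpoint(tmp_path / "model")
        assert parameter_checksum(loaded) == parameter_checksum(model)
        assert loaded.frozen == {"encoder"}
        assert np.array_equal(loaded.predict_proba(data), model.predict_proba(data))
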