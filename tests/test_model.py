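"""Model construction: shape audit, pooling contracts, transfer rules,
checkpoint round-trips, eval-mode determinism."""

import numpy as np
import pytest

from molfinetune.errors import ConfigurationError, TransferError
from molfinetune.model import (
    ClassifierConfig,
    EncoderConfig,
    EncoderOutput,
    MSPM,
    QSARModel,
    build_mspm,
    build_qsar,
    concat_pool,
    load_checkpoint,
    save_checkpoint,
    transfer_encoder,
)
from molfinetune.tokenizer import RESERVED, Vocabulary

TINY = EncoderConfig(embedding_dim=8, hidden_dim=12, n_layers=3, dropouts={})


@pytest.fixture
def vocab():
    return Vocabulary(tokens=RESERVED + ("C", "c", "O", "N", "1", "(", ")", "="))


def expected_shapes(vocab_size: int, cfg: EncoderConfig) -> dict:
    shapes = {"embedding": (vocab_size, cfg.embedding_dim)}
    in_dim = cfg.embedding_dim
    for layer in range(cfg.n_layers):
        out = cfg.embedding_dim if layer == cfg.n_layers - 1 else cfg.hidden_dim
        shapes[f"lstm{layer}.Wx"] = (in_dim, 4 * out)
        shapes[f"lstm{layer}.Wh"] = (out, 4 * out)
        shapes[f"lstm{layer}.b"] = (4 * out,)
        in_dim = out
    return shapes


class TestShapes:
    def test_default_config_dimensions(self):
        cfg = EncoderConfig()
        assert cfg.embedding_dim == 400 and cfg.hidden_dim == 1152
        assert cfg.layer_sizes() == [(400, 1152), (1152, 1152), (1152, 400)]

    def test_mspm_shape_audit(self, vocab):
        model = build_mspm(vocab, TINY, seed=0)
        want = expected_shapes(len(vocab), TINY)
        want["decoder.bias"] = (len(vocab),)
        assert model.parameter_shapes() == want

    def test_qsar_shape_audit(self, vocab):
        head = ClassifierConfig(pooled_dim=24, hidden_dim=10, output_dim=2)
        model = build_qsar(vocab, TINY, head, seed=0)
        shapes = model.parameter_shapes()
        assert shapes["head.W1"] == (24, 10)
        assert shapes["head.W2"] == (10, 2)

    def test_pooled_width_is_three_embeddings(self):
        head = ClassifierConfig(pooled_dim=3 * 400)
        assert head.pooled_dim == 1200

    def test_inconsistent_head_rejected(self, vocab):
        with pytest.raises(ConfigurationError):
            build_qsar(vocab, TINY, ClassifierConfig(pooled_dim=99), seed=0)

    def test_untied_decoder_has_own_weight(self, vocab):
        model = build_mspm(vocab, TINY, seed=0, tie_weights=False)
        assert "decoder.weight" in model.params

    def test_vocab_too_small_rejected(self):
        with pytest.raises(ConfigurationError):
            build_mspm(Vocabulary(tokens=RESERVED), TINY, seed=0)


class TestDeterminism:
    def test_identical_builds_forward_identically(self, vocab):
        inputs = np.array([[4, 5, 6, 7], [5, 5, 4, 4]])
        targets = np.array([[5, 6, 7, 4], [5, 4, 4, 5]])
        a = build_mspm(vocab, TINY, seed=42)
        b = build_mspm(vocab, TINY, seed=42)
        assert a.evaluate_loss(inputs, targets) == b.evaluate_loss(inputs, targets)

    def test_eval_forward_reproducible(self, vocab):
        model = build_qsar(vocab, TINY, seed=1)
        ids = np.array([[4, 5, 6, 0], [6, 5, 0, 0]])
        lengths = np.array([3, 2])
        assert np.array_equal(model.predict(ids, lengths), model.predict(ids, lengths))


class TestInitialLoss:
    def test_fresh_model_is_near_uniform(self, small_vocab, small_smiles):
        from molfinetune.train import lm_epoch_loss, make_lm_stream

        model = build_mspm(
            small_vocab,
            EncoderConfig(embedding_dim=32, hidden_dim=64, n_layers=3, dropouts={}),
            seed=0,
        )
        stream = make_lm_stream(small_smiles, small_vocab)
        loss = lm_epoch_loss(model, stream, batch_size=8)
        assert loss == pytest.approx(np.log(len(small_vocab)), rel=0.05)


class TestConcatPool:
    def test_constant_state_triples(self):
        h = np.tile(np.array([1.0, -2.0, 3.0]), (4, 2, 1))  # (T=4, B=2, E=3)
        out = EncoderOutput(hidden_sequence=h, h_T=h[-1])
        pooled = concat_pool(out, np.ones((4, 2)))
        expected = np.tile(np.array([1.0, -2.0, 3.0]), (2, 3))
        assert np.allclose(pooled, expected)

    def test_single_position(self):
        h = np.random.default_rng(0).normal(size=(1, 3, 5))
        out = EncoderOutput(hidden_sequence=h, h_T=h[0])
        pooled = concat_pool(out, np.ones((1, 3)))
        assert np.allclose(pooled, np.concatenate([h[0], h[0], h[0]], axis=1))

    def test_padding_invariance(self):
        rng = np.random.default_rng(1)
        h = rng.normal(size=(3, 2, 4))
        mask = np.ones((3, 2))
        base = concat_pool(EncoderOutput(hidden_sequence=h, h_T=h[2]), mask)
        padded_h = np.concatenate([h, rng.normal(size=(2, 2, 4))], axis=0)
        padded_mask = np.concatenate([mask, np.zeros((2, 2))], axis=0)
        padded = concat_pool(
            EncoderOutput(hidden_sequence=padded_h, h_T=h[2]), padded_mask
        )
        assert np.allclose(base, padded)

    def test_all_pad_rejected(self):
        h = np.zeros((2, 1, 3))
        with pytest.raises(ValueError):
            concat_pool(EncoderOutput(hidden_sequence=h, h_T=h[-1]), np.zeros((2, 1)))

    def test_model_padding_does_not_change_prediction(self, vocab):
        # the in-model masked pooling obeys the same contract
        model = build_qsar(vocab, TINY, seed=3)
        ids = np.array([[4, 5, 6]])
        lengths = np.array([3])
        base = model.predict(ids, lengths)
        padded = np.array([[4, 5, 6, 0, 0]])
        assert np.allclose(base, model.predict(padded, lengths), atol=1e-6)


class TestTransfer:
    def test_identical_vocab_copies_everything(self, vocab):
        src = build_mspm(vocab, TINY, seed=0)
        dst = build_mspm(vocab, TINY, seed=99)
        transfer_encoder(src, dst)
        for name in src.encoder.params:
            assert np.array_equal(src.params[name].data, dst.params[name].data)

    def test_new_token_gets_mean_embedding(self, vocab):
        src = build_mspm(vocab, TINY, seed=0)
        bigger = Vocabulary(tokens=vocab.tokens + ("[nH]",))
        dst = build_mspm(bigger, TINY, seed=1)
        transfer_encoder(src, dst)
        mean_row = src.params["embedding"].data.mean(axis=0)
        assert np.allclose(dst.params["embedding"].data[-1], mean_row, atol=1e-6)

    def test_qsar_head_untouched(self, vocab):
        src = build_mspm(vocab, TINY, seed=0)
        dst = build_qsar(vocab, TINY, seed=7)
        before = dst.params["head.W1"].data.copy()
        transfer_encoder(src, dst)
        assert np.array_equal(dst.params["head.W1"].data, before)

    def test_transfer_fidelity_on_shared_vocab(self, vocab):
        src = build_mspm(vocab, TINY, seed=0)
        dst = build_qsar(vocab, TINY, seed=5)
        transfer_encoder(src, dst)
        ids = np.array([[4, 6, 5, 7]])
        src.eval_mode(), dst.eval_mode()
        out_src, _ = src.encoder.forward(ids, training=False, rng=None)
        out_dst, _ = dst.encoder.forward(ids, training=False, rng=None)
        for a, b in zip(out_src, out_dst):
            assert np.array_equal(a.data, b.data)

    def test_shape_mismatch_rejected(self, vocab):
        src = build_mspm(vocab, TINY, seed=0)
        other = EncoderConfig(embedding_dim=16, hidden_dim=12, n_layers=3, dropouts={})
        dst = build_mspm(vocab, other, seed=0)
        with pytest.raises(TransferError):
            transfer_encoder(src, dst)


class TestCheckpoint:
    def test_mspm_roundtrip(self, tmp_path, vocab):
        model = build_mspm(vocab, TINY, seed=0)
        path = tmp_path / "model.ckpt"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert isinstance(back, MSPM)
        inputs = np.array([[4, 5, 6]])
        targets = np.array([[5, 6, 4]])
        assert model.evaluate_loss(inputs, targets) == back.evaluate_loss(
            inputs, targets
        )

    def test_qsar_roundtrip_keeps_label_scaling(self, tmp_path, vocab):
        model = build_qsar(vocab, TINY, seed=0)
        model.target_mean, model.target_std = 2.5, 1.7
        path = tmp_path / "qsar.ckpt"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert isinstance(back, QSARModel)
        assert back.target_mean == 2.5 and back.target_std == 1.7
        ids, lengths = np.array([[4, 5, 6]]), np.array([3])
        assert np.allclose(model.predict(ids, lengths), back.predict(ids, lengths))


def test_dropout_validation():
    with pytest.raises(ConfigurationError):
        EncoderConfig(dropouts={"weight": 1.5})
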