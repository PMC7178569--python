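"""AWD-LSTM sequence models for SMILES.

Two model heads share one encoder architecture:

* the language model (next-token prediction over a SMILES token stream) —
  embedding, a stack of LSTM layers whose last layer projects back to the
  embedding width, and a softmax decoder tied to the embedding matrix;
* the QSAR/QSPR model — the same encoder, followed by concat pooling
  (max-pool, mean-pool and the last-time-step state of the final layer,
  concatenated) and a two-layer feed-forward head with a ReLU in between.

Regularization follows the weight-dropped LSTM recipe: dropout on embedding
rows, on the embedding output, on the recurrent weight matrices
(DropConnect), between LSTM layers, and on the encoder output. All dropout
is inert in eval mode, which makes forward passes bit-reproducible.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from molfinetune import autograd as ag
from molfinetune.autograd import Tensor
from molfinetune.errors import ConfigurationError, TransferError
from molfinetune.tokenizer import PAD_INDEX, Vocabulary

DEFAULT_LM_DROPOUTS = {
    "embedding": 0.1,
    "input": 0.25,
    "weight": 0.5,
    "hidden": 0.15,
    "output": 0.1,
}


@dataclass(frozen=True)
class EncoderConfig:
    """Shape and regularization of the LSTM encoder.

    Defaults are the full-scale settings: embedding width 400, hidden width
    1152, three layers (400 -> 1152 -> 1152 -> 400). Tests and desk-scale
    runs shrink ``embedding_dim``/``hidden_dim``; the last layer always
    projects back to the embedding width so the decoder can be weight-tied.
    """

    embedding_dim: int = 400
    hidden_dim: int = 1152
    n_layers: int = 3
    dropouts: dict = field(default_factory=lambda: dict(DEFAULT_LM_DROPOUTS))
    dropout_scale: float = 1.0
    pad_index: int = PAD_INDEX

    def __post_init__(self):
        if self.n_layers < 1 or self.embedding_dim < 1 or self.hidden_dim < 1:
            raise ConfigurationError("encoder dimensions must be positive")
        for name, p in self.dropouts.items():
            if not 0.0 <= p * self.dropout_scale < 1.0:
                raise ConfigurationError(f"dropout {name!r} must lie in [0, 1)")

    def layer_sizes(self) -> list[tuple[int, int]]:
        """(input, hidden) widths per layer; last layer emits embedding_dim."""
        sizes = []
        in_dim = self.embedding_dim
        for layer in range(self.n_layers):
            out_dim = self.embedding_dim if layer == self.n_layers - 1 else self.hidden_dim
            sizes.append((in_dim, out_dim))
            in_dim = out_dim
        return sizes

    def p(self, name: str) -> float:
        return self.dropouts.get(name, 0.0) * self.dropout_scale


@dataclass(frozen=True)
class ClassifierConfig:
    """Feed-forward head over the pooled encoder output.

    ``pooled_dim`` must equal three times the encoder embedding width
    (max-pool + mean-pool + last step). ``output_dim`` is 1 for regression
    and the number of classes otherwise.
    """

    pooled_dim: int
    hidden_dim: int = 50
    output_dim: int = 1
    head_dropouts: tuple[float, float] = (0.2, 0.1)

    def __post_init__(self):
        if self.output_dim < 1 or self.hidden_dim < 1:
            raise ConfigurationError("head dimensions must be positive")


@dataclass
class EncoderOutput:
    """Final-layer hidden states (T, B, E) and the state at the last
    non-pad step of each sequence (B, E)."""

    hidden_sequence: np.ndarray
    h_T: np.ndarray


def concat_pool(out: EncoderOutput, mask: np.ndarray) -> np.ndarray:
    """[max-pool || mean-pool || h_T] over valid positions only.

    ``mask`` is (T, B) with 1 at real tokens and 0 at padding; pad positions
    never contribute to either pool, so appending padding cannot change the
    result. Raises on an all-pad sequence.
    """
    hidden = np.asarray(out.hidden_sequence, dtype=np.float64)
    m = np.asarray(mask, dtype=np.float64)
    counts = m.sum(axis=0)
    if np.any(counts == 0):
        raise ValueError("concat_pool requires at least one valid position")
    m3 = m[:, :, None]
    masked = np.where(m3 > 0, hidden, -np.inf)
    maxpool = masked.max(axis=0)
    meanpool = (hidden * m3).sum(axis=0) / counts[:, None]
    return np.concatenate([maxpool, meanpool, out.h_T], axis=1)


def _uniform(rng: np.random.Generator, shape, bound: float) -> np.ndarray:
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


def _orthogonal_gates(rng: np.random.Generator, size: int) -> np.ndarray:
    """(size, 4*size) recurrent matrix with one orthogonal block per gate.

    Orthogonal recurrent initialization keeps backpropagated signal norms
    stable through time, which matters for narrow stacked LSTMs.
    """
    blocks = []
    for _ in range(4):
        q, _ = np.linalg.qr(rng.normal(size=(size, size)))
        blocks.append(q)
    return np.concatenate(blocks, axis=1).astype(np.float32)


class _Encoder:
    """Embedding + LSTM stack shared by both model heads."""

    def __init__(self, vocab_size: int, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        self.vocab_size = vocab_size
        e = config.embedding_dim
        self.params: dict[str, Tensor] = {
            "embedding": Tensor(
                rng.uniform(-0.1, 0.1, size=(vocab_size, e)).astype(np.float32),
                requires_grad=True,
            )
        }
        for layer, (in_dim, out_dim) in enumerate(config.layer_sizes()):
            bound = 1.0 / np.sqrt(out_dim)
            self.params[f"lstm{layer}.Wx"] = Tensor(
                _uniform(rng, (in_dim, 4 * out_dim), bound), requires_grad=True
            )
            self.params[f"lstm{layer}.Wh"] = Tensor(
                _orthogonal_gates(rng, out_dim), requires_grad=True
            )
            # forget-gate bias starts at 1 so early training retains state
            bias = np.zeros(4 * out_dim, dtype=np.float32)
            bias[out_dim : 2 * out_dim] = 1.0
            self.params[f"lstm{layer}.b"] = Tensor(bias, requires_grad=True)

    def forward(
        self,
        token_ids: np.ndarray,
        training: bool,
        rng: np.random.Generator | None,
        initial_state: list[tuple[np.ndarray, np.ndarray]] | None = None,
    ):
        """Run the encoder over a (B, T) index batch.

        Returns (per-step final-layer states as Tensors, final (h, c) numpy
        state per layer). Dropout masks are sampled once per call and shared
        across time steps (variational dropout); the recurrent weight mask is
        sampled once per call (DropConnect).
        """
        cfg = self.config
        token_ids = np.asarray(token_ids, dtype=np.int64)
        batch, seq_len = token_ids.shape
        sizes = cfg.layer_sizes()

        emb_weight = self.params["embedding"]
        if training and rng is not None and cfg.p("embedding") > 0:
            keep = 1.0 - cfg.p("embedding")
            row_mask = (rng.random((self.vocab_size, 1)) < keep) / keep
            emb_weight = ag.mul_const(emb_weight, row_mask.astype(np.float32))

        def var_mask(width: int, p: float) -> np.ndarray | None:
            if not training or rng is None or p <= 0:
                return None
            keep = 1.0 - p
            return ((rng.random((batch, width)) < keep) / keep).astype(np.float32)

        input_mask = var_mask(cfg.embedding_dim, cfg.p("input"))
        hidden_masks = [
            var_mask(sizes[layer][1], cfg.p("hidden"))
            for layer in range(cfg.n_layers - 1)
        ]
        output_mask = var_mask(sizes[-1][1], cfg.p("output"))

        xs = [ag.embedding(emb_weight, token_ids[:, t]) for t in range(seq_len)]
        if input_mask is not None:
            xs = [ag.mul_const(x, input_mask) for x in xs]

        final_state: list[tuple[np.ndarray, np.ndarray]] = []
        for layer in range(cfg.n_layers):
            in_dim, out_dim = sizes[layer]
            Wx = self.params[f"lstm{layer}.Wx"]
            Wh = self.params[f"lstm{layer}.Wh"]
            b = self.params[f"lstm{layer}.b"]
            if training and rng is not None and cfg.p("weight") > 0:
                keep = 1.0 - cfg.p("weight")
                w_mask = ((rng.random(Wh.shape) < keep) / keep).astype(np.float32)
                Wh = ag.mul_const(Wh, w_mask)
            if initial_state is not None:
                h = Tensor(initial_state[layer][0])
                c = Tensor(initial_state[layer][1])
            else:
                h = Tensor(np.zeros((batch, out_dim), dtype=np.float32))
                c = Tensor(np.zeros((batch, out_dim), dtype=np.float32))
            outs = []
            for x in xs:
                gates = ag.add(ag.add(ag.matmul(x, Wx), ag.matmul(h, Wh)), b)
                i_g = ag.sigmoid(ag.slice_cols(gates, 0, out_dim))
                f_g = ag.sigmoid(ag.slice_cols(gates, out_dim, 2 * out_dim))
                g_g = ag.tanh(ag.slice_cols(gates, 2 * out_dim, 3 * out_dim))
                o_g = ag.sigmoid(ag.slice_cols(gates, 3 * out_dim, 4 * out_dim))
                c = ag.add(ag.mul(f_g, c), ag.mul(i_g, g_g))
                h = ag.mul(o_g, ag.tanh(c))
                outs.append(h)
            final_state.append((h.data.copy(), c.data.copy()))
            xs = outs
            if layer < cfg.n_layers - 1 and hidden_masks[layer] is not None:
                xs = [ag.mul_const(x, hidden_masks[layer]) for x in xs]
        if output_mask is not None:
            xs = [ag.mul_const(x, output_mask) for x in xs]
        return xs, final_state


class _ModelBase:
    def __init__(self):
        self.training = False

    def train_mode(self) -> None:
        self.training = True

    def eval_mode(self) -> None:
        self.training = False

    @property
    def params(self) -> dict[str, Tensor]:
        raise NotImplementedError

    def parameter_shapes(self) -> dict[str, tuple[int, ...]]:
        return {name: tuple(t.shape) for name, t in self.params.items()}

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, tensor in self.params.items():
            if name not in state:
                raise TransferError(f"missing parameter {name!r} in state dict")
            if state[name].shape != tensor.data.shape:
                raise TransferError(
                    f"shape mismatch for {name!r}: "
                    f"{state[name].shape} vs {tensor.data.shape}"
                )
            tensor.data = state[name].astype(np.float32).copy()


class MSPM(_ModelBase):
    """Next-token SMILES language model (embedding + encoder + tied softmax)."""

    def __init__(
        self,
        vocab: Vocabulary,
        config: EncoderConfig,
        seed: int,
        tie_weights: bool = True,
    ):
        super().__init__()
        if len(vocab) < 5:
            raise ConfigurationError("vocabulary must hold the specials plus a token")
        self.vocab = vocab
        self.config = config
        self.tie_weights = tie_weights
        rng = np.random.default_rng(seed)
        self.encoder = _Encoder(len(vocab), config, rng)
        self._params = dict(self.encoder.params)
        self._params["decoder.bias"] = Tensor(
            np.zeros(len(vocab), dtype=np.float32), requires_grad=True
        )
        if not tie_weights:
            self._params["decoder.weight"] = Tensor(
                rng.uniform(-0.1, 0.1, size=(len(vocab), config.embedding_dim)).astype(
                    np.float32
                ),
                requires_grad=True,
            )

    @property
    def params(self) -> dict[str, Tensor]:
        return self._params

    def forward_loss(
        self,
        inputs: np.ndarray,
        targets: np.ndarray,
        rng: np.random.Generator | None = None,
        initial_state=None,
    ):
        """Mean next-token cross-entropy over a (B, T) window.

        Returns (loss Tensor, detached final hidden state) so callers can run
        truncated backpropagation through time over a contiguous stream.
        """
        outs, state = self.encoder.forward(
            inputs, training=self.training, rng=rng, initial_state=initial_state
        )
        flat = ag.concat_rows(outs)  # (T*B, E)
        decoder_w = (
            self._params["embedding"] if self.tie_weights else self._params["decoder.weight"]
        )
        logits = ag.add(ag.matmul_nt(flat, decoder_w), self._params["decoder.bias"])
        flat_targets = np.asarray(targets, dtype=np.int64).T.reshape(-1)
        loss = ag.softmax_cross_entropy(logits, flat_targets)
        return loss, state

    def evaluate_loss(self, inputs: np.ndarray, targets: np.ndarray) -> float:
        was_training = self.training
        self.eval_mode()
        loss, _ = self.forward_loss(inputs, targets)
        self.training = was_training
        return float(loss.data)


class QSARModel(_ModelBase):
    """Encoder + concat pooling + two-layer feed-forward prediction head."""

    def __init__(
        self,
        vocab: Vocabulary,
        enc_config: EncoderConfig,
        head_config: ClassifierConfig,
        seed: int,
    ):
        super().__init__()
        if head_config.pooled_dim != 3 * enc_config.embedding_dim:
            raise ConfigurationError(
                "pooled_dim must equal 3 x encoder embedding_dim "
                f"({head_config.pooled_dim} != {3 * enc_config.embedding_dim})"
            )
        self.vocab = vocab
        self.config = enc_config
        self.head_config = head_config
        # Regression targets are standardized before fitting; the affine
        # de-standardization lives with the model so predictions come back
        # on the original label scale.
        self.target_mean = 0.0
        self.target_std = 1.0
        rng = np.random.default_rng(seed)
        self.encoder = _Encoder(len(vocab), enc_config, rng)
        self._params = dict(self.encoder.params)
        bound1 = 1.0 / np.sqrt(head_config.pooled_dim)
        bound2 = 1.0 / np.sqrt(head_config.hidden_dim)
        self._params["head.W1"] = Tensor(
            _uniform(rng, (head_config.pooled_dim, head_config.hidden_dim), bound1),
            requires_grad=True,
        )
        self._params["head.b1"] = Tensor(
            np.zeros(head_config.hidden_dim, dtype=np.float32), requires_grad=True
        )
        self._params["head.W2"] = Tensor(
            _uniform(rng, (head_config.hidden_dim, head_config.output_dim), bound2),
            requires_grad=True,
        )
        self._params["head.b2"] = Tensor(
            np.zeros(head_config.output_dim, dtype=np.float32), requires_grad=True
        )

    @property
    def params(self) -> dict[str, Tensor]:
        return self._params

    def forward(
        self,
        token_ids: np.ndarray,
        lengths: np.ndarray,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Scores for a right-padded (B, T) batch; ``lengths`` gives the
        number of real tokens per row."""
        token_ids = np.asarray(token_ids, dtype=np.int64)
        lengths = np.asarray(lengths, dtype=np.int64)
        if np.any(lengths < 1):
            raise ValueError("every sequence needs at least one valid position")
        batch, seq_len = token_ids.shape
        outs, _ = self.encoder.forward(token_ids, training=self.training, rng=rng)

        valid = (np.arange(seq_len)[None, :] < lengths[:, None]).astype(np.float32)
        neg_inf = np.float32(-1e30)
        maxp: Tensor | None = None
        sump: Tensor | None = None
        h_T: Tensor | None = None
        for t, h in enumerate(outs):
            m = valid[:, t : t + 1]
            masked = ag.add_const(ag.mul_const(h, m), neg_inf * (1.0 - m))
            maxp = masked if maxp is None else ag.maximum(maxp, masked)
            contrib = ag.mul_const(h, m)
            sump = contrib if sump is None else ag.add(sump, contrib)
            last = (lengths == t + 1).astype(np.float32)[:, None]
            picked = ag.mul_const(h, last)
            h_T = picked if h_T is None else ag.add(h_T, picked)
        meanp = ag.mul_const(sump, (1.0 / lengths.astype(np.float32))[:, None])
        pooled = ag.concat_cols([maxp, meanp, h_T])

        if self.training and rng is not None and self.head_config.head_dropouts[0] > 0:
            keep = 1.0 - self.head_config.head_dropouts[0]
            mask = ((rng.random(pooled.shape) < keep) / keep).astype(np.float32)
            pooled = ag.mul_const(pooled, mask)
        hidden = ag.relu(
            ag.add(ag.matmul(pooled, self._params["head.W1"]), self._params["head.b1"])
        )
        if self.training and rng is not None and self.head_config.head_dropouts[1] > 0:
            keep = 1.0 - self.head_config.head_dropouts[1]
            mask = ((rng.random(hidden.shape) < keep) / keep).astype(np.float32)
            hidden = ag.mul_const(hidden, mask)
        return ag.add(ag.matmul(hidden, self._params["head.W2"]), self._params["head.b2"])

    def predict(self, token_ids: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        """Eval-mode predictions: de-standardized values for regression,
        class probabilities for classification."""
        was_training = self.training
        self.eval_mode()
        scores = self.forward(token_ids, lengths).data
        self.training = was_training
        if self.head_config.output_dim == 1:
            return scores[:, 0] * self.target_std + self.target_mean
        return ag.softmax_probs(scores)


def build_mspm(
    vocab: Vocabulary | int,
    config: EncoderConfig | None = None,
    seed: int = 0,
    tie_weights: bool = True,
) -> MSPM:
    """Construct a language model; ``vocab`` may be a Vocabulary or a size
    (a size builds a placeholder vocabulary, used only in shape audits)."""
    if isinstance(vocab, int):
        from molfinetune.tokenizer import RESERVED

        vocab = Vocabulary(
            tokens=RESERVED + tuple(f"t{i}" for i in range(vocab - len(RESERVED)))
        )
    return MSPM(vocab, config or EncoderConfig(), seed=seed, tie_weights=tie_weights)


def build_qsar(
    vocab: Vocabulary,
    enc: EncoderConfig,
    head: ClassifierConfig | None = None,
    seed: int = 0,
) -> QSARModel:
    if head is None:
        head = ClassifierConfig(pooled_dim=3 * enc.embedding_dim)
    return QSARModel(vocab, enc, head, seed=seed)


def transfer_encoder(
    source: MSPM,
    target: MSPM | QSARModel,
    source_vocab: Vocabulary | None = None,
    target_vocab: Vocabulary | None = None,
) -> MSPM | QSARModel:
    """Copy the pretrained embedding and encoder into ``target``.

    Encoder weights are copied verbatim. Embedding rows for tokens present
    in both vocabularies move to their target indices; rows for target-only
    tokens are initialized to the mean of all source rows. The task head is
    left untouched (freshly initialized). Between two language models the
    decoder bias is mapped the same way as the embedding.
    """
    source_vocab = source_vocab or source.vocab
    target_vocab = target_vocab or target.vocab
    if source.config.layer_sizes() != target.config.layer_sizes():
        raise TransferError("source and target encoder configurations differ")
    for name, tensor in source.encoder.params.items():
        if name == "embedding":
            continue
        target.params[name].data = tensor.data.copy()

    src_emb = source.params["embedding"].data
    src_index = source_vocab.index
    mean_row = src_emb.mean(axis=0)
    new_emb = np.tile(mean_row, (len(target_vocab), 1)).astype(np.float32)
    for tok, t_idx in target_vocab.index.items():
        s_idx = src_index.get(tok)
        if s_idx is not None:
            new_emb[t_idx] = src_emb[s_idx]
    target.params["embedding"].data = new_emb

    if isinstance(target, MSPM):
        src_bias = source.params["decoder.bias"].data
        new_bias = np.full(len(target_vocab), src_bias.mean(), dtype=np.float32)
        for tok, t_idx in target_vocab.index.items():
            s_idx = src_index.get(tok)
            if s_idx is not None:
                new_bias[t_idx] = src_bias[s_idx]
        target.params["decoder.bias"].data = new_bias
    return target


# ---------------------------------------------------------------------------
# Checkpoints: one zip archive holding config JSON, vocabulary JSON and the
# named weight arrays.


def save_checkpoint(model: MSPM | QSARModel, path: str | Path) -> None:
    meta: dict = {
        "kind": "mspm" if isinstance(model, MSPM) else "qsar",
        "encoder": asdict(model.config),
    }
    if isinstance(model, MSPM):
        meta["tie_weights"] = model.tie_weights
    else:
        meta["head"] = asdict(model.head_config)
        meta["target_mean"] = model.target_mean
        meta["target_std"] = model.target_std
    buf = io.BytesIO()
    np.savez(buf, **model.state_dict())
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(meta, indent=2))
        zf.writestr(
            "vocab.json",
            json.dumps(
                {"reserved": list(model.vocab.tokens[:4]), "tokens": list(model.vocab.tokens[4:])}
            ),
        )
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path: str | Path) -> MSPM | QSARModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("config.json"))
        vocab_payload = json.loads(zf.read("vocab.json"))
        weights = dict(np.load(io.BytesIO(zf.read("weights.npz"))))
    vocab = Vocabulary(
        tokens=tuple(vocab_payload["reserved"]) + tuple(vocab_payload["tokens"])
    )
    enc = EncoderConfig(**meta["encoder"])
    if meta["kind"] == "mspm":
        model: MSPM | QSARModel = MSPM(
            vocab, enc, seed=0, tie_weights=meta.get("tie_weights", True)
        )
    else:
        model = QSARModel(vocab, enc, ClassifierConfig(**meta["head"]), seed=0)
        model.target_mean = meta["target_mean"]
        model.target_std = meta["target_std"]
    model.load_state_dict(weights)
    return model
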