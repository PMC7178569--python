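"""Training regimen: one-cycle scheduling, discriminative layer-wise
learning rates, gradual unfreezing, and the three-stage pipeline
(general-corpus language model -> optional task-corpus language model ->
QSAR/QSPR fine-tuning).

The schedule machinery is deliberately explicit: every optimizer step logs
the learning rate applied to each layer group, so schedule conformance can
be checked against the closed-form formulas to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from molfinetune import autograd as ag
from molfinetune.augment import AugmentedDataset
from molfinetune.chem import MoleculeRecord
from molfinetune.errors import ConfigurationError
from molfinetune.model import MSPM, QSARModel
from molfinetune.tokenizer import PAD_INDEX, Vocabulary, numericalize, tokenize

DEFAULT_LR_DECAY = 2.6
DEFAULT_BPTT = 70
DEFAULT_CLIP = 0.4


# ---------------------------------------------------------------------------
# Schedules


@dataclass(frozen=True)
class OneCycleSpec:
    """One-cycle learning-rate schedule endpoints.

    Starts at ``lr_max / div_factor``, rises to ``lr_max`` at
    ``pct_start * total_steps`` and anneals to
    ``lr_max / (div_factor * final_div)``, both phases cosine-interpolated.
    Momentum counter-cycles between ``mom_max`` and ``mom_min``.
    """

    lr_max: float
    total_steps: int
    pct_start: float = 0.3
    div_factor: float = 25.0
    final_div: float = 1e4
    mom_max: float = 0.95
    mom_min: float = 0.85

    def __post_init__(self):
        if self.lr_max <= 0 or self.total_steps < 1:
            raise ConfigurationError("lr_max and total_steps must be positive")
        if not 0.0 < self.pct_start < 1.0:
            raise ConfigurationError("pct_start must lie in (0, 1)")
        if self.div_factor <= 0 or self.final_div <= 0:
            raise ConfigurationError("div factors must be positive")


def _cos_interp(a: float, b: float, frac: float) -> float:
    return a + (b - a) * (1.0 - math.cos(math.pi * frac)) / 2.0


def one_cycle_lr(step: int, spec: OneCycleSpec) -> float:
    """Learning rate at ``step`` (0 .. total_steps inclusive)."""
    if not 0 <= step <= spec.total_steps:
        raise ValueError(f"step {step} outside [0, {spec.total_steps}]")
    start = spec.lr_max / spec.div_factor
    end = spec.lr_max / (spec.div_factor * spec.final_div)
    peak_step = spec.pct_start * spec.total_steps
    if step <= peak_step:
        return _cos_interp(start, spec.lr_max, step / peak_step if peak_step else 1.0)
    return _cos_interp(
        spec.lr_max, end, (step - peak_step) / (spec.total_steps - peak_step)
    )


def one_cycle_momentum(step: int, spec: OneCycleSpec) -> float:
    """Momentum at ``step``: high at the endpoints, low at the lr peak."""
    if not 0 <= step <= spec.total_steps:
        raise ValueError(f"step {step} outside [0, {spec.total_steps}]")
    peak_step = spec.pct_start * spec.total_steps
    if step <= peak_step:
        return _cos_interp(
            spec.mom_max, spec.mom_min, step / peak_step if peak_step else 1.0
        )
    return _cos_interp(
        spec.mom_min, spec.mom_max, (step - peak_step) / (spec.total_steps - peak_step)
    )


def discriminative_lrs(
    base_lr: float, n_groups: int, decay: float = DEFAULT_LR_DECAY
) -> list[float]:
    """Per-group learning rates, bottom group first.

    The top group receives ``base_lr``; each group below it receives the
    rate of the group above divided by ``decay``.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    return [base_lr / decay ** (n_groups - 1 - i) for i in range(n_groups)]


# ---------------------------------------------------------------------------
# Stage plans


@dataclass(frozen=True)
class StageSpec:
    unfrozen_groups: int
    base_lr: float
    epochs: int


@dataclass(frozen=True)
class StagePlan:
    """Gradual-unfreezing schedule: stages of (groups unfrozen top-down,
    base learning rate for the top group, epochs)."""

    stages: tuple[StageSpec, ...]
    lr_decay_factor: float = DEFAULT_LR_DECAY
    n_groups: int = 4

    def __post_init__(self):
        counts = [s.unfrozen_groups for s in self.stages]
        if any(b <= a for a, b in zip(counts, counts[1:])):
            raise ConfigurationError("unfrozen_groups must strictly increase")
        if counts and counts[-1] != self.n_groups:
            raise ConfigurationError("the final stage must unfreeze all groups")
        if any(s.base_lr <= 0 or s.epochs < 1 for s in self.stages):
            raise ConfigurationError("stage learning rates and epochs must be positive")


def default_stage_plan() -> StagePlan:
    """The default QSAR fine-tuning schedule: head only at 3e-2 for 4
    epochs, then +final LSTM at 5e-3/4, +final two LSTMs at 5e-4/4, and the
    full model at 5e-5 for 6 epochs, with the 2.6 discriminative ladder."""
    return StagePlan(
        stages=(
            StageSpec(1, 3e-2, 4),
            StageSpec(2, 5e-3, 4),
            StageSpec(3, 5e-4, 4),
            StageSpec(4, 5e-5, 6),
        )
    )


def layer_groups(model: MSPM | QSARModel) -> list[list[str]]:
    """Partition parameters into layer groups, bottom first.

    Groups (for the three-layer encoder): (1) embedding + first LSTM layer,
    (2) second LSTM layer, (3) last LSTM layer, (4) the prediction head.
    Unfreezing proceeds top-down, so "1 group unfrozen" means the head only.
    """
    n_layers = model.config.n_layers
    names = set(model.params)
    bottom = ["embedding"] + [
        f"lstm{i}.{p}" for i in range(max(n_layers - 2, 0)) for p in ("Wx", "Wh", "b")
    ]
    groups: list[list[str]] = [bottom]
    for i in range(max(n_layers - 2, 0), n_layers):
        groups.append([f"lstm{i}.{p}" for p in ("Wx", "Wh", "b")])
    head = sorted(
        names - {name for group in groups for name in group}
    )
    groups.append(head)
    return [g for g in groups if g]


# ---------------------------------------------------------------------------
# Optimizer


class Adam:
    """Adam over named parameter groups with per-group learning rates and a
    global-norm gradient clip; beta1 is supplied per step so momentum can
    follow the one-cycle counter-schedule."""

    def __init__(
        self,
        param_groups: list[list],
        beta2: float = 0.99,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        clip: float | None = DEFAULT_CLIP,
    ):
        self.param_groups = param_groups
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip = clip
        self.t = 0
        self.state = {
            id(p): (np.zeros_like(p.data), np.zeros_like(p.data))
            for group in param_groups
            for p in group
        }

    def zero_grad(self) -> None:
        for group in self.param_groups:
            for p in group:
                p.zero_grad()

    def step(self, lrs: Sequence[float], beta1: float = 0.9) -> None:
        if len(lrs) != len(self.param_groups):
            raise ValueError("one learning rate per parameter group is required")
        params = [p for g in self.param_groups for p in g if p.grad is not None]
        if self.clip is not None and params:
            total = math.sqrt(sum(float((p.grad**2).sum()) for p in params))
            if total > self.clip:
                scale = self.clip / (total + 1e-12)
                for p in params:
                    p.grad *= scale
        self.t += 1
        for lr, group in zip(lrs, self.param_groups):
            for p in group:
                if p.grad is None:
                    continue
                m, v = self.state[id(p)]
                grad = p.grad
                if self.weight_decay:
                    grad = grad + self.weight_decay * p.data
                m *= beta1
                m += (1 - beta1) * grad
                v *= self.beta2
                v += (1 - self.beta2) * grad * grad
                m_hat = m / (1 - beta1**self.t)
                v_hat = v / (1 - self.beta2**self.t)
                p.data -= (lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(np.float32)


# ---------------------------------------------------------------------------
# Language-model data plumbing


def make_lm_stream(
    smiles: Sequence[str], vocab: Vocabulary, add_bos_eos: bool = True
) -> np.ndarray:
    """Concatenate tokenized SMILES into one delimiter-joined index stream."""
    chunks = []
    for s in smiles:
        seq = numericalize(tokenize(s), vocab, add_bos_eos=add_bos_eos)
        chunks.extend(seq.indices)
    if not chunks:
        raise ValueError("empty corpus")
    return np.asarray(chunks, dtype=np.int64)


def _stream_to_batches(stream: np.ndarray, batch_size: int) -> np.ndarray:
    n_cols = len(stream) // batch_size
    if n_cols < 2:
        raise ValueError("corpus too small for the requested batch size")
    return stream[: n_cols * batch_size].reshape(batch_size, n_cols)


def _lm_windows(batched: np.ndarray, bptt: int):
    n_cols = batched.shape[1]
    for start in range(0, n_cols - 1, bptt):
        stop = min(start + bptt, n_cols - 1)
        yield batched[:, start:stop], batched[:, start + 1 : stop + 1]


def lm_epoch_loss(
    model: MSPM, stream: np.ndarray, bptt: int = DEFAULT_BPTT, batch_size: int = 16
) -> float:
    """Eval-mode mean next-token loss (nats/token) over a stream."""
    batched = _stream_to_batches(stream, batch_size)
    total, count = 0.0, 0
    state = None
    model.eval_mode()
    for inputs, targets in _lm_windows(batched, bptt):
        loss, state = model.forward_loss(inputs, targets, initial_state=state)
        total += float(loss.data) * inputs.size
        count += inputs.size
    return total / count


def train_mspm(
    corpus: Sequence[str] | np.ndarray,
    model: MSPM,
    lr_max: float = 1e-2,
    epochs: int = 10,
    bptt: int = DEFAULT_BPTT,
    batch_size: int = 16,
    seed: int = 0,
    one_cycle: bool = True,
    clip: float | None = DEFAULT_CLIP,
) -> tuple[MSPM, dict]:
    """Train the language model on a corpus with the one-cycle policy.

    ``corpus`` is either a sequence of SMILES strings or a pre-built index
    stream. One cycle spans the whole run; ``one_cycle=False`` trains at a
    strictly constant ``lr_max`` instead. Returns the model and a log with
    per-epoch mean losses and per-step learning rates.
    """
    stream = (
        corpus
        if isinstance(corpus, np.ndarray)
        else make_lm_stream(corpus, model.vocab)
    )
    batched = _stream_to_batches(stream, batch_size)
    steps_per_epoch = len(list(_lm_windows(batched, bptt)))
    total_steps = steps_per_epoch * epochs
    spec = OneCycleSpec(lr_max=lr_max, total_steps=total_steps)
    groups = layer_groups(model)
    params = [[model.params[n] for n in g] for g in groups]
    opt = Adam(params, clip=clip)
    rng = np.random.default_rng(seed)
    log: dict = {"epoch_loss": [], "steps": []}
    step = 0
    model.train_mode()
    for _ in range(epochs):
        state = None
        total, count = 0.0, 0
        for inputs, targets in _lm_windows(batched, bptt):
            loss, state = model.forward_loss(
                inputs, targets, rng=rng, initial_state=state
            )
            opt.zero_grad()
            loss.backward()
            lr = one_cycle_lr(step, spec) if one_cycle else lr_max
            mom = one_cycle_momentum(step, spec) if one_cycle else spec.mom_max
            opt.step([lr] * len(groups), beta1=mom)
            log["steps"].append({"step": step, "lr": [lr] * len(groups), "loss": float(loss.data)})
            total += float(loss.data) * inputs.size
            count += inputs.size
            step += 1
        log["epoch_loss"].append(total / count)
    model.eval_mode()
    return model, log


def finetune_task_mspm(
    general: MSPM,
    task_corpus: Sequence[str],
    base_lr: float = 4e-3,
    epochs: int = 4,
    bptt: int = DEFAULT_BPTT,
    batch_size: int = 16,
    decay: float = DEFAULT_LR_DECAY,
    seed: int = 0,
    clip: float | None = DEFAULT_CLIP,
) -> tuple[MSPM, dict]:
    """Adapt a general language model to a task corpus.

    This stage is optional in the pipeline; it fine-tunes the full model
    with one-cycle scheduling and discriminative layer-wise rates. The
    caller is responsible for any vocabulary alignment (``transfer_encoder``)
    beforehand; here the model is trained in place on the task stream.
    """
    stream = make_lm_stream(task_corpus, general.vocab)
    batched = _stream_to_batches(stream, batch_size)
    steps_per_epoch = len(list(_lm_windows(batched, bptt)))
    spec = OneCycleSpec(lr_max=base_lr, total_steps=steps_per_epoch * epochs)
    groups = layer_groups(general)
    params = [[general.params[n] for n in g] for g in groups]
    opt = Adam(params, clip=clip)
    rng = np.random.default_rng(seed)
    ratios = discriminative_lrs(1.0, len(groups), decay)
    log: dict = {"epoch_loss": [], "steps": []}
    step = 0
    general.train_mode()
    for _ in range(epochs):
        state = None
        total, count = 0.0, 0
        for inputs, targets in _lm_windows(batched, bptt):
            loss, state = general.forward_loss(
                inputs, targets, rng=rng, initial_state=state
            )
            opt.zero_grad()
            loss.backward()
            lr = one_cycle_lr(step, spec)
            mom = one_cycle_momentum(step, spec)
            lrs = [lr * r for r in ratios]
            opt.step(lrs, beta1=mom)
            log["steps"].append({"step": step, "lr": lrs, "loss": float(loss.data)})
            total += float(loss.data) * inputs.size
            count += inputs.size
            step += 1
        log["epoch_loss"].append(total / count)
    general.eval_mode()
    return general, log


# ---------------------------------------------------------------------------
# QSAR fine-tuning


def encode_records(
    records: Sequence[MoleculeRecord], vocab: Vocabulary
) -> tuple[np.ndarray, np.ndarray]:
    """Right-padded (B, T) index matrix and per-row true lengths."""
    seqs = [
        numericalize(tokenize(r.raw_smiles), vocab, add_bos_eos=True).indices
        for r in records
    ]
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    width = int(lengths.max())
    ids = np.full((len(seqs), width), PAD_INDEX, dtype=np.int64)
    for i, s in enumerate(seqs):
        ids[i, : len(s)] = s
    return ids, lengths


def finetune_qsar(
    model: QSARModel,
    train_data: AugmentedDataset | Sequence[MoleculeRecord],
    plan: StagePlan | None = None,
    task: str = "regression",
    seed: int = 0,
    batch_size: int = 128,
    decay: float | None = None,
    clip: float | None = DEFAULT_CLIP,
    on_stage_end=None,
) -> tuple[QSARModel, dict]:
    """Run the gradual-unfreezing stage plan on a labeled dataset.

    Within each stage only the stage's unfrozen (topmost) layer groups
    receive updates; the top group trains at the stage base rate and each
    lower unfrozen group at the rate above it divided by the discriminative
    decay. Loss is mean squared error on standardized labels for regression
    and cross-entropy for classification.
    """
    plan = plan or default_stage_plan()
    records = train_data.records if isinstance(train_data, AugmentedDataset) else list(train_data)
    if not records:
        raise ValueError("empty training set")
    decay = plan.lr_decay_factor if decay is None else decay
    ids, lengths = encode_records(records, model.vocab)

    if task == "regression":
        y = np.array([r.label for r in records], dtype=np.float64)
        model.target_mean = float(y.mean())
        model.target_std = float(y.std()) or 1.0
        targets = ((y - model.target_mean) / model.target_std).astype(np.float32)
    elif task == "classification":
        targets = np.array([r.class_id for r in records], dtype=np.int64)
    else:
        raise ValueError(f"unknown task {task!r}")

    groups = layer_groups(model)
    if len(groups) != plan.n_groups:
        raise ConfigurationError(
            f"plan expects {plan.n_groups} layer groups, model has {len(groups)}"
        )
    rng = np.random.default_rng(seed)
    n = len(records)
    steps_per_epoch = max(1, math.ceil(n / batch_size))
    log: dict = {"stages": []}

    model.train_mode()
    for stage in plan.stages:
        unfrozen = groups[-stage.unfrozen_groups :]
        params = [[model.params[nm] for nm in g] for g in unfrozen]
        opt = Adam(params, clip=clip)
        spec = OneCycleSpec(
            lr_max=stage.base_lr, total_steps=steps_per_epoch * stage.epochs
        )
        ratios = discriminative_lrs(1.0, stage.unfrozen_groups, decay)
        stage_log: dict = {"epoch_loss": [], "steps": []}
        step = 0
        for _ in range(stage.epochs):
            order = rng.permutation(n)
            total, count = 0.0, 0
            for start in range(0, n, batch_size):
                sel = order[start : start + batch_size]
                width = int(lengths[sel].max())
                scores = model.forward(ids[sel, :width], lengths[sel], rng=rng)
                if task == "regression":
                    loss = ag.mse_loss(scores, targets[sel])
                else:
                    loss = ag.softmax_cross_entropy(scores, targets[sel])
                opt.zero_grad()
                loss.backward()
                lr = one_cycle_lr(step, spec)
                mom = one_cycle_momentum(step, spec)
                lrs = [lr * r for r in ratios]
                opt.step(lrs, beta1=mom)
                stage_log["steps"].append(
                    {"step": step, "lr": lrs, "loss": float(loss.data)}
                )
                total += float(loss.data) * len(sel)
                count += len(sel)
                step += 1
            stage_log["epoch_loss"].append(total / count)
        log["stages"].append(stage_log)
        if on_stage_end is not None:
            on_stage_end(len(log["stages"]) - 1, model)
    model.eval_mode()
    return model, log
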