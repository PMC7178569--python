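"""Schedule formulas, stage plans, freezing contracts, reproducibility."""

import hashlib

import numpy as np
import pytest

from molfinetune.errors import ConfigurationError
from molfinetune.model import EncoderConfig, build_mspm, build_qsar
from molfinetune.tokenizer import RESERVED, Vocabulary
from molfinetune.train import (
    Adam,
    OneCycleSpec,
    StagePlan,
    StageSpec,
    default_stage_plan,
    discriminative_lrs,
    encode_records,
    finetune_qsar,
    finetune_task_mspm,
    layer_groups,
    lm_epoch_loss,
    make_lm_stream,
    one_cycle_lr,
    one_cycle_momentum,
    train_mspm,
)

TINY = EncoderConfig(embedding_dim=8, hidden_dim=12, n_layers=3, dropouts={})


@pytest.fixture
def vocab():
    return Vocabulary(tokens=RESERVED + ("C", "c", "O", "N", "1", "(", ")", "="))


class TestOneCycle:
    SPEC = OneCycleSpec(lr_max=0.01, total_steps=100)

    def test_endpoints(self):
        spec = self.SPEC
        assert one_cycle_lr(0, spec) == pytest.approx(spec.lr_max / spec.div_factor)
        assert one_cycle_lr(30, spec) == pytest.approx(spec.lr_max)
        assert one_cycle_lr(100, spec) == pytest.approx(
            spec.lr_max / (spec.div_factor * spec.final_div)
        )

    def test_continuity_and_shape(self):
        values = [one_cycle_lr(s, self.SPEC) for s in range(101)]
        peak = int(np.argmax(values))
        assert peak == 30
        assert all(b >= a for a, b in zip(values[:30], values[1:31]))
        assert all(b <= a for a, b in zip(values[30:-1], values[31:]))

    def test_momentum_counter_cycles(self):
        assert one_cycle_momentum(0, self.SPEC) == pytest.approx(0.95)
        assert one_cycle_momentum(30, self.SPEC) == pytest.approx(0.85)
        assert one_cycle_momentum(100, self.SPEC) == pytest.approx(0.95)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            one_cycle_lr(101, self.SPEC)


class TestDiscriminativeLRs:
    def test_ladder_arithmetic(self):
        lrs = discriminative_lrs(3e-2, 4, 2.6)
        assert lrs == pytest.approx(
            [3e-2 / 2.6**3, 3e-2 / 2.6**2, 3e-2 / 2.6, 3e-2]
        )

    def test_decay_one_is_uniform(self):
        assert discriminative_lrs(0.1, 4, 1.0) == pytest.approx([0.1] * 4)

    def test_adjacent_ratio_is_decay(self):
        lrs = discriminative_lrs(1e-3, 5, 2.6)
        for low, high in zip(lrs, lrs[1:]):
            assert high / low == pytest.approx(2.6)


class TestStagePlan:
    def test_default_matches_published_schedule(self):
        plan = default_stage_plan()
        assert plan.lr_decay_factor == 2.6
        assert plan.stages == (
            StageSpec(1, 3e-2, 4),
            StageSpec(2, 5e-3, 4),
            StageSpec(3, 5e-4, 4),
            StageSpec(4, 5e-5, 6),
        )

    def test_non_monotone_rejected(self):
        with pytest.raises(ConfigurationError):
            StagePlan(stages=(StageSpec(2, 1e-2, 1), StageSpec(1, 1e-3, 1)))

    def test_incomplete_final_stage_rejected(self):
        with pytest.raises(ConfigurationError):
            StagePlan(stages=(StageSpec(1, 1e-2, 1), StageSpec(3, 1e-3, 1)))


class TestLayerGroups:
    def test_four_groups_partition(self, vocab):
        model = build_qsar(vocab, TINY, seed=0)
        groups = layer_groups(model)
        assert len(groups) == 4
        flat = [n for g in groups for n in g]
        assert sorted(flat) == sorted(model.params)
        assert "embedding" in groups[0] and "lstm0.Wx" in groups[0]
        assert groups[1] == ["lstm1.Wx", "lstm1.Wh", "lstm1.b"]
        assert groups[2] == ["lstm2.Wx", "lstm2.Wh", "lstm2.b"]
        assert all(n.startswith("head.") for n in groups[3])

    def test_mspm_head_group_is_decoder(self, vocab):
        model = build_mspm(vocab, TINY, seed=0)
        assert layer_groups(model)[-1] == ["decoder.bias"]


def _hash_params(model, names):
    digest = hashlib.sha256()
    for name in sorted(names):
        digest.update(model.params[name].data.tobytes())
    return digest.hexdigest()


@pytest.fixture
def labeled_records(regression_data):
    return regression_data[0][:40]


class TestFreezing:
    def test_frozen_groups_invariant_per_stage(self, small_vocab, labeled_records):
        model = build_qsar(small_vocab, TINY, seed=0)
        groups = layer_groups(model)
        plan = StagePlan(
            stages=(StageSpec(1, 1e-2, 2), StageSpec(2, 5e-3, 1), StageSpec(4, 1e-3, 1))
        )
        seen: dict[int, list[str]] = {}

        def snapshot(stage_idx, m):
            seen[stage_idx] = [_hash_params(m, g) for g in layer_groups(m)]

        start = [_hash_params(model, g) for g in groups]
        model, _ = finetune_qsar(
            model,
            labeled_records,
            plan=plan,
            task="regression",
            seed=0,
            batch_size=16,
            on_stage_end=snapshot,
        )
        # after the head-only stage, every encoder group is bit-identical
        assert seen[0][:3] == start[:3]
        assert seen[0][3] != start[3]
        # after stage 2 (head + last LSTM) the two lower groups are untouched
        assert seen[1][:2] == start[:2]
        assert seen[1][2] != start[2]

    def test_full_unfreeze_updates_every_group(self, small_vocab, labeled_records):
        model = build_qsar(small_vocab, TINY, seed=0)
        groups = layer_groups(model)
        hashes = [_hash_params(model, g) for g in groups]
        plan = StagePlan(stages=(StageSpec(4, 1e-2, 2),))
        model, _ = finetune_qsar(
            model, labeled_records, plan=plan, task="regression", seed=0, batch_size=16
        )
        for g, h in zip(groups, hashes):
            assert _hash_params(model, g) != h


class TestScheduleConformance:
    def test_logged_lrs_match_formula(self, small_vocab, labeled_records):
        model = build_qsar(small_vocab, TINY, seed=0)
        plan = StagePlan(stages=(StageSpec(2, 5e-3, 2), StageSpec(4, 5e-4, 1)))
        model, log = finetune_qsar(
            model, labeled_records, plan=plan, task="regression", seed=0, batch_size=16
        )
        for stage_spec, stage_log in zip(plan.stages, log["stages"]):
            total = len(stage_log["steps"])
            spec = OneCycleSpec(lr_max=stage_spec.base_lr, total_steps=total)
            ratios = discriminative_lrs(1.0, stage_spec.unfrozen_groups, 2.6)
            for entry in stage_log["steps"]:
                base = one_cycle_lr(entry["step"], spec)
                for logged, ratio in zip(entry["lr"], ratios):
                    assert logged == pytest.approx(base * ratio, rel=1e-12)

    def test_lm_constant_mode(self, small_vocab, small_smiles):
        model = build_mspm(small_vocab, TINY, seed=0)
        stream = make_lm_stream(small_smiles[:10], small_vocab)
        model, log = train_mspm(
            stream, model, lr_max=1e-3, epochs=2, batch_size=2, seed=0, one_cycle=False
        )
        assert all(e["lr"][0] == 1e-3 for e in log["steps"])


class TestReproducibility:
    def test_lm_loss_log_reproducible(self, small_vocab, small_smiles):
        stream = make_lm_stream(small_smiles[:20], small_vocab)

        def run():
            model = build_mspm(small_vocab, TINY, seed=5)
            _, log = train_mspm(stream, model, lr_max=3e-3, epochs=3, batch_size=4, seed=5)
            return log["epoch_loss"]

        assert run() == run()

    def test_qsar_loss_log_reproducible(self, small_vocab, labeled_records):
        plan = StagePlan(stages=(StageSpec(1, 1e-2, 1), StageSpec(4, 1e-3, 1)))

        def run():
            model = build_qsar(small_vocab, TINY, seed=2)
            _, log = finetune_qsar(
                model, labeled_records, plan=plan, task="regression", seed=2, batch_size=16
            )
            return [s["epoch_loss"] for s in log["stages"]]

        assert run() == run()


class TestLMTraining:
    def test_initial_loss_near_uniform(self, small_vocab, small_smiles):
        model = build_mspm(
            small_vocab,
            EncoderConfig(embedding_dim=32, hidden_dim=64, n_layers=3, dropouts={}),
            seed=1,
        )
        stream = make_lm_stream(small_smiles, small_vocab)
        assert lm_epoch_loss(model, stream, batch_size=8) == pytest.approx(
            np.log(len(small_vocab)), rel=0.05
        )

    def test_loss_decreases(self, small_vocab, small_smiles):
        model = build_mspm(small_vocab, TINY, seed=0)
        stream = make_lm_stream(small_smiles, small_vocab)
        model, log = train_mspm(stream, model, lr_max=5e-3, epochs=5, batch_size=4, seed=0)
        assert log["epoch_loss"][-1] < log["epoch_loss"][0]

    def test_task_finetune_improves_task_perplexity(self, small_vocab, small_smiles):
        general = build_mspm(small_vocab, TINY, seed=0)
        general, _ = train_mspm(
            make_lm_stream(small_smiles[:30], small_vocab),
            general,
            lr_max=5e-3,
            epochs=10,
            batch_size=4,
            seed=0,
        )
        task_smiles = small_smiles[30:]
        task_stream = make_lm_stream(task_smiles, small_vocab)
        before = lm_epoch_loss(general, task_stream, batch_size=2)
        general, _ = finetune_task_mspm(
            general, task_smiles, base_lr=3e-3, epochs=10, batch_size=2, seed=0
        )
        after = lm_epoch_loss(general, task_stream, batch_size=2)
        assert after < before

    def test_empty_corpus_rejected(self, small_vocab):
        model = build_mspm(small_vocab, TINY, seed=0)
        with pytest.raises(ValueError):
            train_mspm([], model)


class TestAdam:
    def test_requires_one_lr_per_group(self, vocab):
        model = build_qsar(vocab, TINY, seed=0)
        groups = layer_groups(model)
        opt = Adam([[model.params[n] for n in g] for g in groups])
        with pytest.raises(ValueError):
            opt.step([1e-3])


def test_encode_records_padding(small_vocab, regression_data):
    records = regression_data[0][:8]
    ids, lengths = encode_records(records, small_vocab)
    assert ids.shape[0] == 8
    assert (lengths <= ids.shape[1]).all()
    for row, n in zip(ids, lengths):
        assert (row[n:] == 0).all()
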