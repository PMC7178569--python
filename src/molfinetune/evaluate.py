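"""Metrics, split protocols, test-time-augmented prediction, benchmarking.

Regression quality is reported as RMSE, classification quality as AUROC
(the Mann-Whitney probability that a random positive outscores a random
negative, ties counted one half). Datasets are split 80:10:10 either at
random or by Bemis-Murcko scaffold; a scaffold split keeps every scaffold
group whole so train and test share no ring system, the harder and more
realistic protocol for prospective prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from molfinetune.augment import AugmentationSpec, make_tta_variants
from molfinetune.chem import MoleculeRecord, murcko_scaffold
from molfinetune.model import QSARModel
from molfinetune.train import StagePlan, encode_records, finetune_qsar

DEFAULT_N_TTA = 4


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    mode: str = "random"
    seed: int = 0
    n_repeats: int = 10

    def __post_init__(self):
        if any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.mode not in ("random", "scaffold"):
            raise ValueError(f"unknown split mode {self.mode!r}")


@dataclass
class PredictionSet:
    """Per-variant predictions for one molecule plus their mean."""

    variant_predictions: list[float]
    aggregate: float
    truth: float | None = None


@dataclass
class MetricsReport:
    metric_name: str
    values: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def std(self) -> float:
        return float(np.std(self.values))


# ---------------------------------------------------------------------------
# Metrics


def rmse(truth: Sequence[float], pred: Sequence[float]) -> float:
    """Root-mean-square error."""
    t = np.asarray(truth, dtype=np.float64)
    p = np.asarray(pred, dtype=np.float64)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("rmse needs two equal-length, non-empty vectors")
    return float(np.sqrt(np.mean((t - p) ** 2)))


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve via the Mann-Whitney rank formulation.

    Equals the probability that a uniformly chosen positive receives a
    higher score than a uniformly chosen negative, with ties worth 1/2.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError("labels and scores must align")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc requires both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Splits


def _sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    # train and valid take the floor; the remainder goes to test last
    n_train = int(np.floor(fractions[0] * n))
    n_valid = int(np.floor(fractions[1] * n))
    return n_train, n_valid, n - n_train - n_valid


def random_split(
    dataset: Sequence, spec: SplitSpec
) -> tuple[list[int], list[int], list[int]]:
    """Seeded disjoint, exhaustive train/valid/test index sets."""
    n = len(dataset)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n).tolist()
    n_train, n_valid, _ = _sizes(n, spec.fractions)
    return (
        order[:n_train],
        order[n_train : n_train + n_valid],
        order[n_train + n_valid :],
    )


def scaffold_split(
    dataset: Sequence[MoleculeRecord], spec: SplitSpec
) -> tuple[list[int], list[int], list[int]]:
    """Bemis-Murcko scaffold split: scaffold groups are assigned whole.

    Groups are placed largest-first into train until it reaches capacity,
    then into valid, then test, so no scaffold ever spans partitions.
    Acyclic molecules (empty scaffold) form one shared group. Ties in group
    size are broken by scaffold string for determinism.
    """
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(dataset):
        groups.setdefault(murcko_scaffold(rec.canonical_smiles), []).append(i)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    n = len(dataset)
    n_train, n_valid, _ = _sizes(n, spec.fractions)
    train: list[int] = []
    valid: list[int] = []
    test: list[int] = []
    for _, members in ordered:
        if len(train) + len(members) <= n_train:
            train.extend(members)
        elif len(valid) + len(members) <= n_valid:
            valid.extend(members)
        else:
            test.extend(members)
    return train, valid, test


def save_split(split: tuple[list[int], list[int], list[int]], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"train": split[0], "valid": split[1], "test": split[2]})
    )


def load_split(path: str | Path) -> tuple[list[int], list[int], list[int]]:
    """Read an externally supplied split definition (JSON index lists)."""
    payload = json.loads(Path(path).read_text())
    return list(payload["train"]), list(payload["valid"]), list(payload["test"])


# ---------------------------------------------------------------------------
# Prediction


def predict_records(model: QSARModel, records: Sequence[MoleculeRecord]) -> np.ndarray:
    """Canonical-only eval-mode predictions (value or positive-class
    probability) for a batch of records."""
    ids, lengths = encode_records(records, model.vocab)
    out = model.predict(ids, lengths)
    if out.ndim == 2:
        return out[:, 1] if out.shape[1] == 2 else out.max(axis=1)
    return out


def predict_with_tta(
    model: QSARModel,
    record: MoleculeRecord,
    n_tta: int = DEFAULT_N_TTA,
    seed: int = 0,
) -> PredictionSet:
    """Average the model over the canonical SMILES and ``n_tta`` variants.

    Regression averages raw outputs; classification averages positive-class
    probabilities. ``n_tta=0`` reduces to canonical-only evaluation.
    """
    variants = make_tta_variants(record, n_tta=n_tta, seed=seed)
    variant_records = [
        MoleculeRecord(raw_smiles=v, canonical_smiles=record.canonical_smiles)
        for v in variants
    ]
    preds = predict_records(model, variant_records)
    return PredictionSet(
        variant_predictions=[float(p) for p in preds],
        aggregate=float(np.mean(preds)),
        truth=record.label if record.label is not None else record.class_id,
    )


def evaluate_split(
    model: QSARModel,
    records: Sequence[MoleculeRecord],
    task: str,
    tta: bool = False,
    n_tta: int = DEFAULT_N_TTA,
    seed: int = 0,
) -> float:
    """RMSE (regression) or AUROC (classification) on a record set."""
    if tta:
        preds = np.array(
            [
                predict_with_tta(model, r, n_tta=n_tta, seed=seed + i).aggregate
                for i, r in enumerate(records)
            ]
        )
    else:
        preds = predict_records(model, records)
    if task == "regression":
        return rmse([r.label for r in records], preds)
    return auroc([r.class_id for r in records], preds)


# ---------------------------------------------------------------------------
# Benchmark harness


def run_benchmark(
    dataset: Sequence[MoleculeRecord],
    make_model,
    plan: StagePlan | None,
    spec: SplitSpec,
    task: str = "regression",
    augmentation: AugmentationSpec | None = None,
    tta: bool = True,
    n_tta: int = DEFAULT_N_TTA,
    batch_size: int = 128,
) -> dict[str, MetricsReport]:
    """Repeated split -> augment(train only) -> fine-tune -> test evaluation.

    ``make_model(seed)`` must return a fresh (typically weight-transferred)
    QSAR model per repeat. Only the training partition is ever augmented;
    test labels are never perturbed. Returns canonical-SMILES and (if
    requested) TTA metric reports across repeats.
    """
    from molfinetune.augment import augment_classification, augment_regression

    metric = "RMSE" if task == "regression" else "AUROC"
    canonical_values: list[float] = []
    tta_values: list[float] = []
    for rep in range(spec.n_repeats):
        rep_spec = SplitSpec(
            fractions=spec.fractions,
            mode=spec.mode,
            seed=spec.seed + rep,
            n_repeats=1,
        )
        splitter = scaffold_split if spec.mode == "scaffold" else random_split
        train_idx, _, test_idx = splitter(dataset, rep_spec)
        train = [dataset[i] for i in train_idx]
        test = [dataset[i] for i in test_idx]
        if augmentation is not None:
            if task == "regression":
                train = augment_regression(train, augmentation, seed=rep_spec.seed)
            else:
                train = augment_classification(train, augmentation, seed=rep_spec.seed)
        model = make_model(rep_spec.seed)
        model, _ = finetune_qsar(
            model, train, plan=plan, task=task, seed=rep_spec.seed, batch_size=batch_size
        )
        canonical_values.append(
            evaluate_split(model, test, task, tta=False)
        )
        if tta:
            tta_values.append(
                evaluate_split(model, test, task, tta=True, n_tta=n_tta, seed=rep_spec.seed)
            )
    out = {"canonical": MetricsReport(metric_name=metric, values=canonical_values)}
    if tta:
        out["tta"] = MetricsReport(metric_name=metric, values=tta_values)
    return out
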