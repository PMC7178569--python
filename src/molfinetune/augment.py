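"""SMILES-enumeration data augmentation.

One molecular graph admits many valid SMILES strings; writing the same
molecule under random atom orderings is a label-preserving augmentation.
Three uses are covered: regression training sets (variants carry the label
plus zero-mean Gaussian noise emulating experimental error), unbalanced
classification sets (per-class variant counts re-balance the class ratio),
and test-time augmentation (predictions averaged over the canonical string
and a few variants; labels never touched).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from molfinetune.chem import MoleculeRecord, randomized_smiles
from molfinetune.errors import MolFineTuneError

DEFAULT_MAX_ATTEMPT_FACTOR = 10
DEFAULT_N_TTA = 4


@dataclass(frozen=True)
class AugmentationSpec:
    """How many variants per molecule, and what happens to their labels.

    ``n_augment`` requests N *additional* variants per molecule (the original
    canonical record is always retained); ``count_includes_original`` flips to
    the N-total reading. ``sigma_noise`` is the standard deviation of the
    zero-mean Gaussian added to augmented regression labels only.
    """

    n_augment: int = 0
    sigma_noise: float = 0.0
    per_class_counts: Mapping[int, int] | None = None
    max_attempt_factor: int = DEFAULT_MAX_ATTEMPT_FACTOR
    count_includes_original: bool = False

    def __post_init__(self):
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be non-negative")
        if self.n_augment < 0 or self.max_attempt_factor < 1:
            raise ValueError("counts must be non-negative")
        if self.per_class_counts is not None and any(
            v < 0 for v in self.per_class_counts.values()
        ):
            raise ValueError("per-class counts must be non-negative")

    def variants_for(self, n: int) -> int:
        return max(n - 1, 0) if self.count_includes_original else n


@dataclass
class AugmentedDataset:
    """Augmented records plus the mapping back to their source molecules."""

    records: list[MoleculeRecord]
    parent_index: list[int]

    def __post_init__(self):
        if len(self.records) != len(self.parent_index):
            raise ValueError("records and parent_index must align")

    def __len__(self) -> int:
        return len(self.records)


def enumerate_variants(
    record: MoleculeRecord,
    n: int,
    seed: int,
    max_attempt_factor: int = DEFAULT_MAX_ATTEMPT_FACTOR,
) -> list[str]:
    """Up to ``n`` distinct randomized SMILES of ``record``'s molecule.

    Variants differ from the canonical form when the molecule admits any
    alternative writing; at most ``n * max_attempt_factor`` draws are made
    before returning fewer than ``n`` (small symmetric molecules exhaust
    their enumeration early). Deterministic under a fixed seed.
    """
    if n <= 0:
        return []
    rng = np.random.default_rng(seed)
    variants: list[str] = []
    seen = {record.canonical_smiles}
    for _ in range(n * max_attempt_factor):
        draw = randomized_smiles(
            record.canonical_smiles, int(rng.integers(0, 2**31 - 1))
        )
        if draw not in seen:
            seen.add(draw)
            variants.append(draw)
            if len(variants) == n:
                break
    return variants


def _augmented(parent: MoleculeRecord, raw: str, label=None, class_id=None):
    return MoleculeRecord(
        raw_smiles=raw,
        canonical_smiles=parent.canonical_smiles,
        label=label,
        class_id=class_id,
        is_augmented=True,
    )


def augment_regression(
    dataset: Sequence[MoleculeRecord], spec: AugmentationSpec, seed: int
) -> AugmentedDataset:
    """Enumeration augmentation with Gaussian label noise on variants only.

    Each molecule contributes its original record with the label unchanged,
    plus up to ``spec.n_augment`` variants labeled ``label + eps`` with
    ``eps ~ Normal(0, sigma_noise^2)`` drawn independently per variant.
    """
    rng = np.random.default_rng(seed)
    records: list[MoleculeRecord] = []
    parents: list[int] = []
    n_var = spec.variants_for(spec.n_augment)
    for i, rec in enumerate(dataset):
        if rec.label is None:
            raise MolFineTuneError(
                f"regression augmentation requires a label: {rec.canonical_smiles}"
            )
        records.append(rec)
        parents.append(i)
        variants = enumerate_variants(
            rec, n_var, int(rng.integers(0, 2**31 - 1)), spec.max_attempt_factor
        )
        for raw in variants:
            eps = float(rng.normal(0.0, spec.sigma_noise)) if spec.sigma_noise else 0.0
            records.append(_augmented(rec, raw, label=rec.label + eps))
            parents.append(i)
    return AugmentedDataset(records=records, parent_index=parents)


def augment_classification(
    dataset: Sequence[MoleculeRecord], spec: AugmentationSpec, seed: int
) -> AugmentedDataset:
    """Per-class enumeration augmentation; class labels copied unperturbed.

    With all requested variants available, a class of size n augmented a
    times grows to (1 + a) * n records, which is how re-balancing ratios are
    chosen.
    """
    if spec.per_class_counts is None:
        raise MolFineTuneError("classification augmentation needs per_class_counts")
    rng = np.random.default_rng(seed)
    records: list[MoleculeRecord] = []
    parents: list[int] = []
    for i, rec in enumerate(dataset):
        if rec.class_id is None:
            raise MolFineTuneError(
                f"classification augmentation requires a class: {rec.canonical_smiles}"
            )
        if rec.class_id not in spec.per_class_counts:
            raise MolFineTuneError(f"no augmentation count for class {rec.class_id}")
        records.append(rec)
        parents.append(i)
        n_var = spec.variants_for(spec.per_class_counts[rec.class_id])
        variants = enumerate_variants(
            rec, n_var, int(rng.integers(0, 2**31 - 1)), spec.max_attempt_factor
        )
        for raw in variants:
            records.append(_augmented(rec, raw, class_id=rec.class_id))
            parents.append(i)
    return AugmentedDataset(records=records, parent_index=parents)


def achieved_class_ratio(dataset: AugmentedDataset, positive: int = 1) -> float:
    """positive:negative record ratio actually achieved after augmentation."""
    pos = sum(1 for r in dataset.records if r.class_id == positive)
    neg = len(dataset.records) - pos
    if neg == 0:
        raise MolFineTuneError("no negative records present")
    return pos / neg


def make_tta_variants(
    record: MoleculeRecord, n_tta: int = DEFAULT_N_TTA, seed: int = 0
) -> list[str]:
    """The canonical SMILES plus up to ``n_tta`` distinct variants.

    Test-time augmentation inputs: labels are never attached or perturbed.
    ``n_tta=0`` reduces to canonical-only evaluation.
    """
    if n_tta < 0:
        raise ValueError("n_tta must be >= 0")
    return [record.canonical_smiles] + enumerate_variants(record, n_tta, seed)
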