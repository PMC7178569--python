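"""Seeded generator of valid synthetic SMILES corpora and labeled datasets.

Molecules are assembled as random valence-respecting trees over a small
heavy-atom alphabet (C, N, O, S, F), optionally seeded or decorated with
aromatic six-membered rings, and legality is deferred to the chemistry
backend (reject-and-retry). Labels derive from structural counts —

    y = a * (#N atoms) + b * (#rings) + c * (#heavy atoms) + eps

— so ground truth is unambiguous under SMILES enumeration and the
generating coefficients are recoverable by ordinary least squares. Binary
class labels threshold the latent y at a quantile chosen to hit a target
class imbalance. Everything is reproducible from the spec seed; no
downloads are ever required.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from molfinetune.chem import MoleculeRecord
from molfinetune.errors import GenerationError

_ATOMIC_NUM = {"C": 6, "N": 7, "O": 8, "S": 16, "F": 9}
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1}
DEFAULT_ATOM_PROBS = {"C": 0.60, "N": 0.15, "O": 0.15, "S": 0.05, "F": 0.05}


@dataclass(frozen=True)
class SynthSpec:
    """Conditions under which a synthetic corpus or dataset is drawn.

    ``ring_prob`` is the probability of inserting an aromatic six-ring at
    each growth opportunity; ``label_model`` holds (a, b, c) and the label
    noise standard deviation; ``target_positive_fraction`` sets the class
    imbalance for binary datasets.
    """

    n_molecules: int = 100
    atom_probs: dict = field(default_factory=lambda: dict(DEFAULT_ATOM_PROBS))
    ring_prob: float = 0.3
    size_range: tuple[int, int] = (8, 24)
    label_model: tuple[float, float, float] = (1.0, 0.5, 0.1)
    eps_sd: float = 0.1
    target_positive_fraction: float = 0.5
    seed: int = 0
    max_attempts_per_molecule: int = 200

    def __post_init__(self):
        if self.n_molecules < 1 or self.size_range[0] < 1:
            raise GenerationError("n_molecules and sizes must be positive")
        if self.size_range[0] > self.size_range[1]:
            raise GenerationError("size_range must be (min, max) with min <= max")
        unknown = set(self.atom_probs) - set(_ATOMIC_NUM)
        if unknown:
            raise GenerationError(f"unsupported atoms {sorted(unknown)}")


def _assemble(rng: np.random.Generator, n_heavy: int, spec: SynthSpec) -> str | None:
    """One attempt at a random molecule with exactly n_heavy heavy atoms."""
    symbols = list(spec.atom_probs)
    probs = np.array([spec.atom_probs[s] for s in symbols], dtype=float)
    probs /= probs.sum()
    mol = Chem.RWMol()
    free: dict[int, int] = {}  # atom index -> remaining single-bond slots

    def add_aromatic_ring(attach: int | None) -> bool:
        idxs = []
        for _ in range(6):
            atom = Chem.Atom(6)
            atom.SetIsAromatic(True)
            idxs.append(mol.AddAtom(atom))
        for k in range(6):
            bond = mol.AddBond(idxs[k], idxs[(k + 1) % 6], Chem.BondType.AROMATIC) - 1
            mol.GetBondWithIdx(bond).SetIsAromatic(True)
        for i in idxs:
            free[i] = 1
        if attach is not None:
            mol.AddBond(attach, idxs[0], Chem.BondType.SINGLE)
            free[attach] -= 1
            free[idxs[0]] -= 1
        return True

    remaining = n_heavy
    if remaining >= 6 and rng.random() < spec.ring_prob:
        add_aromatic_ring(None)
        remaining -= 6
    else:
        sym = str(rng.choice(symbols, p=probs))
        idx = mol.AddAtom(Chem.Atom(_ATOMIC_NUM[sym]))
        free[idx] = _VALENCE[sym]
        remaining -= 1

    while remaining > 0:
        sites = [i for i, f in free.items() if f > 0]
        if not sites:
            return None  # dead end (e.g. chain capped by monovalent atoms)
        attach = int(sites[rng.integers(len(sites))])
        if remaining >= 6 and rng.random() < spec.ring_prob:
            add_aromatic_ring(attach)
            remaining -= 6
        else:
            sym = str(rng.choice(symbols, p=probs))
            idx = mol.AddAtom(Chem.Atom(_ATOMIC_NUM[sym]))
            mol.AddBond(attach, idx, Chem.BondType.SINGLE)
            free[attach] -= 1
            free[idx] = _VALENCE[sym] - 1
            remaining -= 1

    try:
        plain = mol.GetMol()
        Chem.SanitizeMol(plain)
        return Chem.MolToSmiles(plain)
    except Exception:
        return None


def generate_corpus(
    spec: SynthSpec, exclude: set[str] | None = None
) -> list[MoleculeRecord]:
    """Draw ``spec.n_molecules`` distinct canonical SMILES.

    ``exclude`` removes a canonical-SMILES set from consideration (used to
    keep pretraining and task data disjoint). Raises
    :class:`GenerationError` if the spec cannot yield enough distinct
    molecules within the attempt budget.
    """
    rng = np.random.default_rng(spec.seed)
    exclude = exclude or set()
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    budget = spec.n_molecules * spec.max_attempts_per_molecule
    for _ in range(budget):
        if len(records) == spec.n_molecules:
            break
        n_heavy = int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
        smiles = _assemble(rng, n_heavy, spec)
        if smiles is None or smiles in seen or smiles in exclude:
            continue
        seen.add(smiles)
        records.append(MoleculeRecord(raw_smiles=smiles, canonical_smiles=smiles))
    if len(records) < spec.n_molecules:
        raise GenerationError(
            f"could only generate {len(records)} of {spec.n_molecules} "
            "distinct molecules under this spec"
        )
    return records


def structure_counts(smiles: str) -> tuple[int, int, int]:
    """(#N atoms, #rings, #heavy atoms) — the latent label features."""
    mol = Chem.MolFromSmiles(smiles)
    n_nitrogen = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 7)
    n_rings = mol.GetRingInfo().NumRings()
    return n_nitrogen, n_rings, mol.GetNumHeavyAtoms()


def latent_label(smiles: str, coefficients: tuple[float, float, float]) -> float:
    a, b, c = coefficients
    n_n, n_r, n_h = structure_counts(smiles)
    return a * n_n + b * n_r + c * n_h


def generate_regression_dataset(
    spec: SynthSpec, exclude: set[str] | None = None
) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Labeled molecules plus the ground-truth feature table.

    The returned frame holds the structural counts, noiseless latent label
    and realized noisy label per molecule, so coefficient-recovery checks
    can run against the exact generating model.
    """
    corpus = generate_corpus(spec, exclude=exclude)
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    records = []
    for rec in corpus:
        n_n, n_r, n_h = structure_counts(rec.canonical_smiles)
        a, b, c = spec.label_model
        latent = a * n_n + b * n_r + c * n_h
        noise = float(rng.normal(0.0, spec.eps_sd)) if spec.eps_sd > 0 else 0.0
        label = latent + noise
        records.append(rec.with_label(label))
        rows.append(
            {
                "smiles": rec.canonical_smiles,
                "n_nitrogen": n_n,
                "n_rings": n_r,
                "n_heavy": n_h,
                "latent": latent,
                "label": label,
            }
        )
    truth = pd.DataFrame(rows)
    counts = truth[["n_nitrogen", "n_rings", "n_heavy"]].to_numpy(dtype=float)
    if np.linalg.matrix_rank(counts) < 3:
        raise GenerationError(
            "count matrix is rank-deficient; coefficients would not be identifiable"
        )
    return records, truth


def generate_classification_dataset(
    spec: SynthSpec, exclude: set[str] | None = None
) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Binary-labeled molecules by thresholding the latent label.

    The threshold is the empirical (1 - target) quantile of the latent
    values, so the achieved positive fraction lands within +-20% relative of
    ``spec.target_positive_fraction``; a degenerate one-class outcome raises.
    """
    records, truth = generate_regression_dataset(
        replace(spec, eps_sd=0.0), exclude=exclude
    )
    latent = truth["latent"].to_numpy()
    threshold = float(np.quantile(latent, 1.0 - spec.target_positive_fraction))
    classes = (latent > threshold).astype(int)
    achieved = classes.mean()
    target = spec.target_positive_fraction
    if achieved == 0.0 or achieved == 1.0:
        raise GenerationError("degenerate classification dataset (single class)")
    if abs(achieved - target) > 0.2 * target:
        # quantile ties can push the fraction off target; tie-break by rank
        order = np.argsort(-latent, kind="stable")
        classes = np.zeros(len(latent), dtype=int)
        classes[order[: max(1, round(target * len(latent)))]] = 1
        achieved = classes.mean()
        if abs(achieved - target) > 0.2 * target:
            raise GenerationError(
                f"achieved positive fraction {achieved:.3f} outside 20% of {target}"
            )
    truth = truth.assign(class_id=classes, threshold=threshold)
    labeled = [
        MoleculeRecord(
            raw_smiles=r.raw_smiles,
            canonical_smiles=r.canonical_smiles,
            class_id=int(c),
        )
        for r, c in zip(records, classes)
    ]
    return labeled, truth


# ---------------------------------------------------------------------------
# Transfer benchmark


def transfer_benchmark(
    pretrain_n: int = 20_000,
    task_ns: Sequence[int] | int = (100, 500),
    seeds: Sequence[int] = tuple(range(10)),
    n_valid: int = 200,
    pretrain_epochs: int = 4,
    pretrain_lr: float = 1e-2,
    base_spec: SynthSpec | None = None,
    encoder_kwargs: dict | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Paired pretrained-vs-scratch experiment on synthetic regression data.

    A shared pretraining corpus of ``pretrain_n`` molecules and a shared
    labeled task pool are generated once, disjoint in canonical SMILES.
    For each seed: a small language model is pretrained on the corpus
    (seed-specific initialization and data order), then fine-tuned into a
    regressor on each task size (the pretrained arm); an identically
    initialized regressor is trained from scratch under the same stage
    plan, data subsets and seeds (the scratch arm). Validation molecules
    are held out of both arms' training sets. Returns one row per
    (seed, task size, arm) with the canonical-SMILES validation RMSE.
    """
    from molfinetune.model import EncoderConfig, build_mspm, build_qsar, transfer_encoder
    from molfinetune.tokenizer import build_vocab, tokenize
    from molfinetune.train import finetune_qsar, train_mspm
    from molfinetune.evaluate import evaluate_split

    if isinstance(task_ns, int):
        task_ns = (task_ns,)
    task_ns = tuple(task_ns)
    base_spec = base_spec or SynthSpec()
    enc_kwargs = {
        "embedding_dim": 32,
        "hidden_dim": 64,
        "n_layers": 3,
        "dropouts": {},
    }
    enc_kwargs.update(encoder_kwargs or {})

    task_spec = replace(
        base_spec, n_molecules=max(task_ns) + n_valid, seed=base_seed + 100_003
    )
    task_records, _ = generate_regression_dataset(task_spec)
    task_canonical = {r.canonical_smiles for r in task_records}
    corpus_spec = replace(base_spec, n_molecules=pretrain_n, seed=base_seed + 200_003)
    corpus = generate_corpus(corpus_spec, exclude=task_canonical)

    smiles = [r.canonical_smiles for r in corpus]
    vocab = build_vocab(
        [tokenize(s) for s in smiles]
        + [tokenize(r.canonical_smiles) for r in task_records]
    )
    enc = EncoderConfig(**enc_kwargs)
    from molfinetune.train import make_lm_stream

    stream = make_lm_stream(smiles, vocab)

    rows = []
    for seed in seeds:
        mspm = build_mspm(vocab, enc, seed=seed)
        train_mspm(
            stream,
            mspm,
            lr_max=pretrain_lr,
            epochs=pretrain_epochs,
            batch_size=128,
            seed=seed,
        )
        rng = np.random.default_rng(base_seed + 300_003 + seed)
        order = rng.permutation(len(task_records))
        valid = [task_records[i] for i in order[:n_valid]]
        pool = [task_records[i] for i in order[n_valid:]]
        for task_n in task_ns:
            train_recs = pool[:task_n]
            for arm in ("pretrained", "scratch"):
                model = build_qsar(vocab, enc, seed=seed)
                if arm == "pretrained":
                    transfer_encoder(mspm, model)
                model, _ = finetune_qsar(
                    model, train_recs, task="regression", seed=seed, batch_size=32
                )
                error = evaluate_split(model, valid, task="regression", tta=False)
                rows.append(
                    {"seed": seed, "task_n": task_n, "arm": arm, "rmse": error}
                )
    return pd.DataFrame(rows)


def summarize_transfer(results: pd.DataFrame) -> pd.DataFrame:
    """Per task size: paired win count and mean RMSE per arm."""
    out = []
    for task_n, sub in results.groupby("task_n"):
        wide = sub.pivot(index="seed", columns="arm", values="rmse")
        wins = int((wide["pretrained"] <= wide["scratch"]).sum())
        out.append(
            {
                "task_n": task_n,
                "n_seeds": len(wide),
                "pretrained_wins": wins,
                "mean_rmse_pretrained": float(wide["pretrained"].mean()),
                "mean_rmse_scratch": float(wide["scratch"].mean()),
            }
        )
    return pd.DataFrame(out)
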