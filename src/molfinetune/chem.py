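"""Chemistry backend: canonicalization, SMILES enumeration, scaffolds, curation.

All structure handling goes through RDKit. Canonical SMILES are the fixed
point of :func:`canonicalize`; every enumerated variant of a molecule maps
back to the same canonical form, which is what makes enumeration safe as a
data-augmentation primitive.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.Scaffolds import MurckoScaffold

from molfinetune.errors import InvalidSMILESError

RDLogger.DisableLog("rdApp.*")

DEFAULT_MAX_HEAVY_ATOMS = 50


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: raw text, canonical form, optional labels, provenance.

    ``raw_smiles`` is the string as written (possibly an enumeration
    variant); ``canonical_smiles`` is the backend canonical form. For
    non-augmented records the two coincide.
    """

    raw_smiles: str
    canonical_smiles: str
    label: float | None = None
    class_id: int | None = None
    is_augmented: bool = False

    def with_label(self, label: float) -> "MoleculeRecord":
        return replace(self, label=label)


@dataclass
class CurationReport:
    """Accounting of a corpus curation pass; counts always sum to n_input."""

    n_input: int = 0
    n_removed_invalid: int = 0
    n_removed_mixture: int = 0
    n_removed_heavy_atoms: int = 0
    n_removed_duplicate: int = 0
    n_retained: int = 0

    def validate(self) -> None:
        removed = (
            self.n_removed_invalid
            + self.n_removed_mixture
            + self.n_removed_heavy_atoms
            + self.n_removed_duplicate
        )
        if self.n_input != self.n_retained + removed:
            raise ValueError("curation report does not account for every input")
        if min(
            self.n_input,
            self.n_removed_invalid,
            self.n_removed_mixture,
            self.n_removed_heavy_atoms,
            self.n_removed_duplicate,
            self.n_retained,
        ) < 0:
            raise ValueError("curation counts must be non-negative")

    def to_json(self, path: str | Path) -> None:
        self.validate()
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not smiles:
        raise InvalidSMILESError(smiles, "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSMILESError(smiles)
    return mol


def canonicalize(smiles: str) -> str:
    """Return the deterministic canonical SMILES of ``smiles``.

    Idempotent: all enumeration variants of one molecule map to the same
    output. Raises :class:`InvalidSMILESError` on unparsable input.
    """
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def standardize(smiles: str) -> str:
    """Sanitize and normalize a structure, returning canonical SMILES.

    Backend sanitization plus the standardizer's cleanup normalizations,
    exposed behind one function so a fuller standardization pipeline can be
    slotted in without touching the curation contract.
    """
    mol = rdMolStandardize.Cleanup(_mol_from_smiles(smiles))
    return Chem.MolToSmiles(mol)


def randomized_smiles(smiles: str, rng_seed: int) -> str:
    """A valid SMILES of the same molecule under a random atom ordering.

    Deterministic for a fixed seed; ``canonicalize(output) ==
    canonicalize(input)`` always holds.
    """
    mol = _mol_from_smiles(smiles)
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(mol.GetNumAtoms()).tolist()
    shuffled = Chem.RenumberAtoms(mol, order)
    return Chem.MolToSmiles(shuffled, canonical=False)


def heavy_atom_count(smiles: str) -> int:
    """Number of non-hydrogen atoms."""
    return _mol_from_smiles(smiles).GetNumHeavyAtoms()


def is_mixture(smiles: str) -> bool:
    """True iff the parsed structure has more than one disconnected fragment.

    Detection is structural, not textual: ``"C1.C1"`` reconnects through its
    ring-closure digits into a single fragment and is not a mixture.
    """
    return len(Chem.GetMolFrags(_mol_from_smiles(smiles))) > 1


def murcko_scaffold(smiles: str) -> str:
    """Canonical SMILES of the Bemis-Murcko scaffold; "" for acyclic input."""
    mol = _mol_from_smiles(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def make_record(
    smiles: str,
    label: float | None = None,
    class_id: int | None = None,
) -> MoleculeRecord:
    """Canonicalize ``smiles`` and wrap it in a non-augmented record."""
    canonical = canonicalize(smiles)
    return MoleculeRecord(
        raw_smiles=canonical,
        canonical_smiles=canonical,
        label=label,
        class_id=class_id,
        is_augmented=False,
    )


def curate_corpus(
    records: Iterable[str],
    max_heavy_atoms: int = DEFAULT_MAX_HEAVY_ATOMS,
    deduplicate: bool = True,
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Filter and canonicalize a raw SMILES corpus.

    Applied in order: parse/validity filter, mixture filter, heavy-atom
    filter (strictly more than ``max_heavy_atoms`` removed), standardize +
    canonicalize, then duplicate removal on the canonical form (first
    occurrence kept). Unparsable entries are counted, never raised.
    """
    if max_heavy_atoms < 1:
        raise ValueError("max_heavy_atoms must be >= 1")
    report = CurationReport()
    retained: list[MoleculeRecord] = []
    seen: set[str] = set()
    for raw in records:
        report.n_input += 1
        mol = Chem.MolFromSmiles(raw) if raw else None
        if mol is None:
            report.n_removed_invalid += 1
            continue
        if len(Chem.GetMolFrags(mol)) > 1:
            report.n_removed_mixture += 1
            continue
        if mol.GetNumHeavyAtoms() > max_heavy_atoms:
            report.n_removed_heavy_atoms += 1
            continue
        canonical = Chem.MolToSmiles(rdMolStandardize.Cleanup(mol))
        if deduplicate and canonical in seen:
            report.n_removed_duplicate += 1
            continue
        seen.add(canonical)
        retained.append(
            MoleculeRecord(raw_smiles=canonical, canonical_smiles=canonical)
        )
    report.n_retained = len(retained)
    report.validate()
    return retained, report


# ---------------------------------------------------------------------------
# Corpus I/O


def read_smi(path: str | Path) -> list[str]:
    """Read a .smi file: one SMILES per line, optional whitespace-separated id."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            out.append(line.split()[0])
    return out


def write_smi(records: Sequence[MoleculeRecord | str], path: str | Path) -> None:
    lines = [
        r if isinstance(r, str) else r.canonical_smiles for r in records
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_labeled_csv(
    path: str | Path,
    smiles_column: str = "smiles",
    label_column: str | None = "label",
    task: str = "regression",
) -> list[MoleculeRecord]:
    """Read a labeled QSAR dataset from CSV (UTF-8, header required).

    Invalid SMILES abort with :class:`InvalidSMILESError`: silently dropping
    rows would corrupt label alignment in a supervised dataset.
    """
    records: list[MoleculeRecord] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or smiles_column not in reader.fieldnames:
            raise ValueError(f"CSV is missing the SMILES column {smiles_column!r}")
        if label_column is not None and label_column not in reader.fieldnames:
            raise ValueError(f"CSV is missing the label column {label_column!r}")
        for row in reader:
            smiles = row[smiles_column]
            label = None
            class_id = None
            if label_column is not None:
                value = row[label_column]
                if task == "classification":
                    class_id = int(float(value))
                else:
                    label = float(value)
            records.append(make_record(smiles, label=label, class_id=class_id))
    return records


def write_labeled_csv(
    records: Sequence[MoleculeRecord],
    path: str | Path,
    parent_ids: Sequence[int] | None = None,
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["smiles", "label", "parent_id", "is_augmented"])
        for i, rec in enumerate(records):
            label = rec.label if rec.label is not None else rec.class_id
            parent = parent_ids[i] if parent_ids is not None else i
            writer.writerow([rec.raw_smiles, label, parent, int(rec.is_augmented)])
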