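"""Character-level SMILES tokenization, vocabulary, numericalization.

Tokenization rules: every bracket expression ``[...]`` is a single token
(``[nH]``, ``[O-]``, ``[Te]`` ...), the two-character halogens ``Cl`` and
``Br`` are single tokens, two-digit ring closures ``%NN`` are single tokens,
and every other character is its own token. The concatenation of the tokens
reproduces the input exactly, so tokenization is lossless.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from molfinetune.errors import TokenizationError

PAD, UNK, BOS, EOS = "<pad>", "<unk>", "<bos>", "<eos>"
RESERVED = (PAD, UNK, BOS, EOS)
PAD_INDEX, UNK_INDEX, BOS_INDEX, EOS_INDEX = 0, 1, 2, 3


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into character-level tokens.

    Raises :class:`TokenizationError` on an unmatched ``[``.
    """
    if not smiles:
        raise TokenizationError("cannot tokenize empty text")
    tokens: list[str] = []
    i = 0
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            end = smiles.find("]", i)
            if end == -1:
                raise TokenizationError(f"unmatched '[' in {smiles!r}")
            tokens.append(smiles[i : end + 1])
            i = end + 1
        elif ch in ("C", "B") and smiles.startswith(("Cl", "Br"), i):
            tokens.append(smiles[i : i + 2])
            i += 2
        elif ch == "%" and i + 2 < n and smiles[i + 1 : i + 3].isdigit():
            tokens.append(smiles[i : i + 3])
            i += 3
        else:
            tokens.append(ch)
            i += 1
    return tokens


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token inventory with reserved specials at indices 0..3."""

    tokens: tuple[str, ...]

    def __post_init__(self):
        if tuple(self.tokens[:4]) != RESERVED:
            raise ValueError(f"vocabulary must start with {RESERVED}")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary contains duplicate tokens")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def index(self) -> dict[str, int]:
        return {tok: i for i, tok in enumerate(self.tokens)}

    def to_json(self, path: str | Path) -> None:
        payload = {"reserved": list(RESERVED), "tokens": list(self.tokens[4:])}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        payload = json.loads(Path(path).read_text())
        if tuple(payload["reserved"]) != RESERVED:
            raise ValueError("vocabulary file has an unexpected reserved block")
        return cls(tokens=tuple(payload["reserved"]) + tuple(payload["tokens"]))


@dataclass(frozen=True)
class TokenSequence:
    tokens: tuple[str, ...]
    indices: tuple[int, ...]

    def __post_init__(self):
        if len(self.tokens) != len(self.indices):
            raise ValueError("tokens and indices must align 1:1")


def build_vocab(
    corpus: Iterable[Sequence[str]], min_freq: int = 1
) -> Vocabulary:
    """Vocabulary of all corpus tokens with frequency >= ``min_freq``.

    Tokens are ordered by descending frequency, ties broken lexicographically,
    after the four reserved specials; deterministic for a fixed corpus.
    """
    counts: Counter[str] = Counter()
    n_seqs = 0
    for seq in corpus:
        counts.update(seq)
        n_seqs += 1
    if n_seqs == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    kept = sorted(
        (tok for tok, c in counts.items() if c >= min_freq),
        key=lambda tok: (-counts[tok], tok),
    )
    return Vocabulary(tokens=RESERVED + tuple(kept))


def numericalize(
    tokens: Sequence[str], vocab: Vocabulary, add_bos_eos: bool = True
) -> TokenSequence:
    """Map tokens to vocabulary indices; unknown tokens map to UNK."""
    index = vocab.index
    toks = list(tokens)
    if add_bos_eos:
        toks = [BOS, *toks, EOS]
    idx = [index.get(tok, UNK_INDEX) for tok in toks]
    out_tokens = [vocab.tokens[i] for i in idx]
    return TokenSequence(tokens=tuple(out_tokens), indices=tuple(idx))


def denumericalize(seq: TokenSequence | Sequence[int], vocab: Vocabulary) -> list[str]:
    """Inverse of :func:`numericalize` on UNK-free input; strips specials."""
    indices = seq.indices if isinstance(seq, TokenSequence) else seq
    out = []
    for i in indices:
        if not 0 <= i < len(vocab):
            raise IndexError(f"index {i} out of range for vocabulary of {len(vocab)}")
        if i in (PAD_INDEX, BOS_INDEX, EOS_INDEX):
            continue
        out.append(vocab.tokens[i])
    return out
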