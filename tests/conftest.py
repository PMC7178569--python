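import pytest

from molfinetune.synthetic import SynthSpec, generate_corpus, generate_regression_dataset
from molfinetune.tokenizer import build_vocab, tokenize


@pytest.fixture(scope="session")
def small_corpus():
    """Fifty distinct synthetic molecules (session-wide fixture)."""
    return generate_corpus(SynthSpec(n_molecules=50, seed=3))


@pytest.fixture(scope="session")
def small_smiles(small_corpus):
    return [r.canonical_smiles for r in small_corpus]


@pytest.fixture(scope="session")
def small_vocab(small_smiles):
    return build_vocab([tokenize(s) for s in small_smiles])


@pytest.fixture(scope="session")
def regression_data():
    """Synthetic labeled regression set with its ground-truth table."""
    return generate_regression_dataset(SynthSpec(n_molecules=120, seed=11))
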