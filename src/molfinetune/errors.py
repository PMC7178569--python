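"""Exception types shared across the package."""


class MolFineTuneError(Exception):
    """Base class for package errors."""


class InvalidSMILESError(MolFineTuneError):
    """A SMILES string could not be parsed into a valid structure."""

    def __init__(self, smiles: str, message: str = "invalid SMILES"):
        self.smiles = smiles
        super().__init__(f"{message}: {smiles!r}")


class TokenizationError(MolFineTuneError):
    """A SMILES string violates the tokenization grammar (e.g. unmatched '[')."""


class ConfigurationError(MolFineTuneError):
    """Inconsistent or invalid model/training configuration."""


class TransferError(MolFineTuneError):
    """Weight transfer between models with incompatible shapes."""


class GenerationError(MolFineTuneError):
    """The synthetic generator cannot satisfy the requested specification."""
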