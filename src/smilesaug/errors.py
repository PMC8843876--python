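"""Exception hierarchy shared across the package."""


class SmilesAugError(Exception):
    """Base class for all package errors."""


class SmilesParseError(SmilesAugError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, message: str | None = None):
        self.smiles = smiles
        super().__init__(message or f"unparseable SMILES: {smiles!r}")


class SchemaError(SmilesAugError):
    """An input table is missing a required column."""


class ConfigError(SmilesAugError):
    """A configuration value is inconsistent with the data."""


class VocabularyError(SmilesAugError):
    """A character outside the fitted character set was encountered."""

    def __init__(self, character: str, position: int, smiles: str):
        self.character = character
        self.position = position
        super().__init__(
            f"out-of-vocabulary character {character!r} at position {position} in {smiles!r}"
        )


class EncodingError(SmilesAugError):
    """A string or matrix violates the encoding contract."""


class MalformedSampleError(SmilesAugError):
    """A one-hot matrix violates the row-sum invariants."""


class TrainingError(SmilesAugError):
    """Model training failed (e.g. diverged to NaN loss)."""
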