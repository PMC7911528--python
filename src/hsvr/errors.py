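"""Exception hierarchy."""


class HsvrError(Exception):
    """Base class for package errors."""


class SchemaError(HsvrError):
    """A required column is missing or mistyped in an input table."""


class ValidationError(HsvrError):
    """An invariant of the data model is violated (duplicate ids, bad rows)."""


class StructureError(HsvrError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, message: str | None = None):
        self.smiles = smiles
        super().__init__(message or f"unparsable SMILES: {smiles!r}")


class IncompatibleModelError(HsvrError):
    """A serialized model artifact cannot be loaded by this package version."""
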