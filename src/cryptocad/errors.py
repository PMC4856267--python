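"""Exception hierarchy for the pipeline.

All package errors derive from :class:`CryptoCADError` so callers can catch
one base class at the CLI boundary.
"""


class CryptoCADError(Exception):
    """Base class for all package errors."""


class FormatError(CryptoCADError):
    """Input file exists but is not in an accepted format."""


class ValidationError(CryptoCADError):
    """A record or table violates the declared schema."""


class ParameterError(CryptoCADError):
    """A caller-supplied parameter is outside its valid range."""


class DegenerateInputError(CryptoCADError):
    """The input is formally valid but the operation is undefined on it
    (constant image, empty mask, zero-variance marginals...)."""


class ContractError(CryptoCADError):
    """An operation was called on an object violating its preconditions."""


class TrainingError(CryptoCADError):
    """The classifier cannot be trained on the given data."""
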