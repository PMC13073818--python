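"""Exception hierarchy shared across the package."""


class AtpBindError(Exception):
    """Base class for all package errors."""


class FormatError(AtpBindError):
    """Malformed input file content."""


class AlignmentError(FormatError):
    """Per-residue annotations do not align with the sequence."""


class ContractError(AtpBindError):
    """A function precondition was violated by the caller."""


class ConfigError(AtpBindError):
    """Invalid configuration."""


class DataError(AtpBindError):
    """Input data cannot support the requested computation."""


class CapabilityError(AtpBindError):
    """A required optional capability (e.g. the language-model adapter) is absent."""


class IntegrityError(AtpBindError):
    """A stored artifact is corrupt or inconsistent."""
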