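"""Exception hierarchy for lyase-profile."""


class LyaseProfileError(Exception):
    """Base class for all package errors."""


class MalformedInputError(LyaseProfileError):
    """A structure or sequence document could not be interpreted."""


class FastaError(MalformedInputError):
    """A FASTA record is empty or contains illegal characters."""


class AssemblyError(LyaseProfileError):
    """Requested biological-assembly expansion is not possible."""


class ConfigurationError(LyaseProfileError):
    """Invalid analysis configuration (unknown matrix, empty anchor set, ...)."""


class ConsistencyError(LyaseProfileError):
    """Derived objects do not refer back to the model they were computed from."""


class UnknownElementError(LyaseProfileError):
    """An atom's element has no entry in the van der Waals radii table."""


class GenerationError(LyaseProfileError):
    """A synthetic-data specification could not be satisfied."""
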