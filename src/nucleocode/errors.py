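"""Package-specific exception types."""


class NucleocodeError(Exception):
    """Base class for all package errors."""


class ConfigError(NucleocodeError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class UnknownChromosomeError(NucleocodeError, KeyError):
    """An interval or read refers to a chromosome absent from the sizes table."""


class ShapeError(NucleocodeError, ValueError):
    """An input container has the wrong dimensions for the requested operation."""
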