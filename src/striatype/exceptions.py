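"""Exception hierarchy shared across the package."""


class StriatypeError(Exception):
    """Base class for all package errors."""


class ValidationError(StriatypeError):
    """A data structure or file violates the documented schema."""


class FormatError(StriatypeError):
    """A file could not be parsed in the expected on-disk format."""


class MissingDependencyError(StriatypeError):
    """An optional adapter was invoked without its third-party backend."""


class ExtractionError(StriatypeError):
    """A feature could not be computed from the available sweeps."""


class SpecError(StriatypeError):
    """A generator specification is internally inconsistent."""


class SimulationError(StriatypeError):
    """Numerical failure during simulation (non-finite state)."""
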