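"""Exception hierarchy.

Every error raised by this package derives from :class:`MetadissError`, so
callers can catch one type at pipeline level while tests can assert on the
specific failure mode.
"""


class MetadissError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MetadissError, ValueError):
    """A parameter violates its documented precondition."""


class SelectionError(MetadissError, KeyError):
    """A chain/residue/atom selection matched nothing."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class EmptyInputError(MetadissError, ValueError):
    """An input file or container holds no usable records."""


class InsufficientDataError(MetadissError, ValueError):
    """Too few samples for the requested estimate."""


class InsufficientReplicatesError(InsufficientDataError):
    """Too few independent runs for a resampling-based error estimate."""


class DegenerateFitError(MetadissError, ValueError):
    """The data cannot constrain the requested fit (e.g. constant series)."""


class DegenerateFrameError(MetadissError, ValueError):
    """Coordinates are (nearly) collinear; no unique axis system exists."""


class AlignmentError(MetadissError, ValueError):
    """Two series that must share a time axis have different lengths."""


class FormatError(MetadissError, ValueError):
    """A text file violates its expected column format."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class RadiusTableError(MetadissError, KeyError):
    """An element has no van der Waals radius in the active table."""

    def __str__(self) -> str:
        return self.args[0] if self.args else ""


class TopologyError(MetadissError, ValueError):
    """Required atoms/residues are missing from the topology."""


class AnnotationError(MetadissError, ValueError):
    """A residue lacks a required annotation (e.g. secondary structure)."""


class NumericalError(MetadissError, ArithmeticError):
    """A numerical routine left its domain (overflow, non-finite value)."""


class ConnectivityError(MetadissError, ValueError):
    """The microstate transition graph has no usable connected set."""


class UndefinedCorrelationError(MetadissError, ValueError):
    """Correlation is undefined (zero variance in one of the variables)."""
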