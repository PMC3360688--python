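"""Exception hierarchy.

All package-specific failures derive from :class:`CytoEmdError` so callers can
catch one base class; each subclass also derives from the closest builtin
(``ValueError``/``RuntimeError``) for idiomatic handling.
"""


class CytoEmdError(Exception):
    """Base class for all cytoemd errors."""


class FormatError(CytoEmdError, ValueError):
    """A file or table violates the expected layout (missing/duplicate columns)."""


class ParseError(FormatError):
    """A cell of an input file could not be parsed; message names the row."""


class SchemaError(CytoEmdError, ValueError):
    """Two objects that must agree (channels, node sets, sample ids) do not."""


class DegenerateInputError(CytoEmdError, ValueError):
    """Input is structurally valid but degenerate for the operation (e.g. one
    cell where two are needed, zero variance where a rescale is requested)."""


class InfeasibleRetentionError(CytoEmdError, ValueError):
    """Downsampling cannot retain the requested number of cells."""


class ParameterError(CytoEmdError, ValueError):
    """A tuning parameter is out of its valid range."""


class ConfigurationError(CytoEmdError, ValueError):
    """A run configuration is unusable (e.g. a training class is absent)."""


class StructuralError(CytoEmdError, ValueError):
    """A graph/tree argument violates a structural precondition (disconnected)."""


class NumericalError(CytoEmdError, RuntimeError):
    """An external numerical solver failed to converge."""
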