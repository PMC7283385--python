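"""Exception hierarchy.

Every error raised by this package derives from :class:`EchoBCError`, so
callers can catch one type at a pipeline boundary.  The subclasses map onto
the failure modes of the processing stages: bad scalar parameters, degenerate
waveforms or flow sets, invalid cross-section geometry, incomplete
configuration, and unreadable external files.
"""


class EchoBCError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EchoBCError, ValueError):
    """A scalar argument is outside its admissible range."""


class DegenerateWaveformError(EchoBCError, ValueError):
    """A waveform has no usable span or content (e.g. zero period)."""


class DegenerateInputError(EchoBCError, ValueError):
    """An input set is degenerate for the requested operation
    (e.g. zero summed outlet peak, no solvable scaling factor)."""


class InvalidGeometryError(EchoBCError, ValueError):
    """A cross-section contour is self-intersecting or degenerate."""


class ConfigurationError(EchoBCError, ValueError):
    """Required inputs (sites, ratios, areas, files) are missing."""


class ParseError(EchoBCError, ValueError):
    """An external text file could not be parsed; carries a line number
    where applicable."""


class InvalidComparisonError(EchoBCError, ValueError):
    """Two sampled profiles cannot be compared (disjoint ranges, zero
    reference norm)."""
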