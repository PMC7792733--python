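"""Exception hierarchy.

All strainpost errors derive from :class:`StrainpostError` so callers can
catch the package's failures with one clause; the subclasses distinguish
malformed files, physiologically impossible inputs, and caller mistakes.
"""


class StrainpostError(Exception):
    """Base class for all errors raised by strainpost."""


class TraceFormatError(StrainpostError, ValueError):
    """The trace file does not conform to the expected dialect
    (missing time column, unparseable header, ...)."""


class TraceDataError(StrainpostError, ValueError):
    """The file parsed but its content is unusable
    (ragged rows, non-monotone time, empty analysis window, ...)."""


class EventOrderError(StrainpostError, ValueError):
    """Valve-event / ECG-landmark times violate the physiological ordering
    of the cardiac cycle."""


class UsageError(StrainpostError, ValueError):
    """The caller combined arguments in an unsupported way."""


class ConfigError(StrainpostError, ValueError):
    """The study configuration is incomplete for the requested view option."""


class DegenerateSampleError(StrainpostError, ValueError):
    """A statistical routine received a sample it cannot handle
    (constant values, too few observations)."""
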