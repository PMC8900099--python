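"""Exception hierarchy for pvasync.

All package-specific errors derive from :class:`PvasyncError` so callers can
catch everything the pipeline may raise with a single handler, while the
command-line layer maps input problems (:class:`FormatError`,
:class:`DataError`, :class:`ConfigError`) to exit code 2 and treats
per-breath analysis failures (:class:`InfeasibleError`,
:class:`UnsegmentableError`) as non-fatal, logged events.
"""


class PvasyncError(Exception):
    """Base class for all pvasync errors."""


class FormatError(PvasyncError):
    """Input file cannot be parsed (missing columns, bad units, empty file)."""


class DataError(PvasyncError):
    """Input parses but violates a data contract (non-monotone time, ...)."""


class ConfigError(PvasyncError):
    """Invalid configuration or simulator scenario parameters."""


class InfeasibleError(PvasyncError):
    """Reconstruction is not feasible for this breath.

    Raised when a required segment or breakpoint is missing from the
    measured loop (for example the lower inflection point Vm1 is absent
    because a large effort began before the ventilator cycle), or when
    mapped parameters violate their physical constraints.  Carries an
    optional breath identifier for reporting.
    """

    def __init__(self, message: str, breath_id=None):
        super().__init__(message)
        self.breath_id = breath_id


class UnsegmentableError(InfeasibleError):
    """Half-cycle has too little dynamic range or too few samples to fit."""


class MetricError(PvasyncError):
    """A metric is undefined for the given inputs (e.g. zero reference area)."""
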