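"""Exception hierarchy.

Everything raised on bad user input derives from :class:`ProtprofError` so the
CLI can map failures to exit codes (config errors vs. data errors) without
pattern-matching on messages.
"""


class ProtprofError(Exception):
    """Base class for all package errors."""


class ConfigError(ProtprofError, ValueError):
    """A run/simulation configuration is invalid or inconsistent."""


class DataError(ProtprofError, ValueError):
    """Base class for errors caused by the data themselves."""


class InputError(DataError):
    """An argument violates a documented precondition."""


class FormatError(DataError):
    """A file does not conform to the expected tabular format."""


class LayoutError(DataError):
    """Plate layout violates an invariant (ragged grids, missing controls)."""


class AlignmentError(DataError):
    """Two traces that must share a timepoint grid do not."""


class PairingError(DataError):
    """Records that must refer to the same sample do not match."""


class IntegrityError(DataError):
    """Duplicate or conflicting records for the same logical cell."""


class ReportError(ProtprofError, ValueError):
    """A report bundle is missing a required member."""
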