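"""Exception types shared across the package."""


class FearloopError(Exception):
    """Base class for all package-specific errors."""


class IncompleteSessionError(FearloopError):
    """A required stream (EEG, HR or markers) is missing from a session."""


class ClockError(FearloopError):
    """Stream timestamps are non-monotone or streams do not overlap."""


class MontageError(FearloopError):
    """Channel labels do not match the expected montage."""


class FilterError(FearloopError):
    """Filter specification invalid for the given sampling rate."""


class InsufficientDataError(FearloopError):
    """Not enough signal to perform the requested operation."""
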