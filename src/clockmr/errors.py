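"""Exception hierarchy shared across the package."""


class ClockMRError(Exception):
    """Base class for all package errors."""


class ConfigError(ClockMRError):
    """A configuration problem: missing columns, bad parameters, bad plans."""


class DataError(ClockMRError):
    """Invalid or inconsistent input data (bad rows, duplicate rsids, ...)."""


class InsufficientInstrumentsError(DataError):
    """Too few instruments for the requested estimator."""
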