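"""Exception hierarchy shared across the pipeline."""


class MeiodecayError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MeiodecayError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(MeiodecayError):
    """A file parsed, but its content violates the expected structure."""


class AnalysisError(MeiodecayError):
    """A computation's preconditions are not met by the data."""


class NoDescentError(AnalysisError):
    """The smoothed signal has no decreasing stretch in the searched interval."""
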