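"""Exception hierarchy shared across the pipeline."""


class ImmunopipeError(Exception):
    """Base class for all package errors."""


class FormatError(ImmunopipeError):
    """Malformed or inconsistent on-disk input."""


class ParameterError(ImmunopipeError):
    """Invalid argument or configuration value."""


class FitError(ImmunopipeError):
    """A model fit failed after all retries."""
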