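"""Exception hierarchy shared across the package."""


class SleepUQError(Exception):
    """Base class for all package errors."""


class ValidationError(SleepUQError, ValueError):
    """An input violated a documented precondition or invariant."""


class FormatError(SleepUQError, ValueError):
    """A file did not conform to the expected on-disk schema."""
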