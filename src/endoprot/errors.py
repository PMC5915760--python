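"""Exception types shared across the pipeline."""


class EndoprotError(Exception):
    """Base class for all pipeline errors."""


class FormatError(EndoprotError, ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(EndoprotError, ValueError):
    """Input values violate a documented precondition."""
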