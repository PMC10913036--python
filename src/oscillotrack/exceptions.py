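"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A parameter violates its documented precondition."""


class DegenerateInputError(ValueError):
    """Input is formally valid but carries no usable information (e.g. silent audio)."""


class OverlapError(ValueError):
    """Token placement would overlap successive tokens in a stimulus train."""
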