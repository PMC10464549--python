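"""Exception hierarchy shared across the pipeline."""


class ModsiteError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(ModsiteError, ValueError):
    """A precondition on user input was violated."""


class FormatError(ModsiteError, ValueError):
    """An input file does not carry the information the operation needs."""


class EmptyInputError(ModsiteError, ValueError):
    """No usable records remain after filtering."""


class UnidentifiableError(ModsiteError, ValueError):
    """The requested estimate is not identifiable from the given data."""
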