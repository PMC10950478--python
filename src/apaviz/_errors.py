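"""Exception hierarchy shared by all apaviz modules."""


class ApavizError(Exception):
    """Base class for all apaviz errors."""


class SchemaError(ApavizError):
    """A required column is missing from an input table."""


class IdAlignmentError(ApavizError):
    """Row/column ids of a count matrix do not match the metadata keys."""


class ValidationError(ApavizError):
    """An input value violates a container invariant (e.g. negative count)."""


class UnknownIdError(ApavizError, KeyError):
    """A requested site/observation/gene/group id does not exist."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class ParameterError(ApavizError, ValueError):
    """A parameter value is out of its documented range."""
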