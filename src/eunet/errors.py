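"""Exception hierarchy shared across the package."""


class EUNetError(Exception):
    """Base class for all package-specific errors."""


class NotationParseError(EUNetError):
    """The architecture notation string violates the grammar."""

    def __init__(self, message: str, position: int | None = None, token: str | None = None):
        self.position = position
        self.token = token
        if token is not None and position is not None:
            message = f"{message} (token {token!r} at position {position})"
        super().__init__(message)


class SpecValidationError(EUNetError):
    """A syntactically valid notation describes an inconsistent architecture."""


class GraphConfigError(EUNetError):
    """A LayerGraph cannot be built under the requested configuration."""


class ShapeError(EUNetError):
    """Shape inference found inconsistent tensor shapes."""


class RealizationError(EUNetError):
    """A LayerGraph contains an operation the numeric backend cannot realize."""
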