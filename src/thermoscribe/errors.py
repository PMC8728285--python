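"""Exception hierarchy."""


class ThermoscribeError(Exception):
    """Base class for all package errors."""


class ValidationError(ThermoscribeError, ValueError):
    """Invalid domain object or argument."""


class RegistryConflictError(ThermoscribeError):
    """An identifier is already bound to a different compound."""


class UnknownCompoundError(ThermoscribeError, KeyError):
    """Identifier cannot be resolved in the registry."""

    def __init__(self, identifier: str, suggestions: list[str] | None = None):
        self.identifier = identifier
        self.suggestions = suggestions or []
        msg = f"unknown compound identifier {identifier!r}"
        if self.suggestions:
            msg += f" (nearest matches: {', '.join(self.suggestions)})"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg by default
        return self.args[0]


class ReactionSyntaxError(ThermoscribeError, ValueError):
    """Reaction string does not match the grammar."""

    def __init__(self, message: str, text: str = "", position: int | None = None):
        self.text = text
        self.position = position
        if position is not None:
            message = f"{message} (at position {position} in {text!r})"
        super().__init__(message)


class EstimationError(ThermoscribeError):
    """Reaction cannot be scored by the trained model."""


class PathwayInfeasibleError(ThermoscribeError):
    """The driving-force linear program is infeasible or unbounded."""
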