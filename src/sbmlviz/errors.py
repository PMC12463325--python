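"""Exception hierarchy for sbmlviz."""


class SbmlVizError(Exception):
    """Base class for all sbmlviz errors."""


class ParseError(SbmlVizError):
    """Raised when SBML XML cannot be parsed."""


class ValidationError(SbmlVizError):
    """Raised when a document violates a structural invariant on read/write."""


class ParameterError(SbmlVizError):
    """Raised for invalid user-supplied parameters."""


class UnknownColorError(SbmlVizError):
    """Raised when a color name cannot be resolved.

    Carries `suggestions`, the nearest known color names.
    """

    def __init__(self, name: str, suggestions: list[str]):
        self.name = name
        self.suggestions = suggestions
        hint = f"; did you mean: {', '.join(suggestions)}?" if suggestions else ""
        super().__init__(f"unknown color {name!r}{hint}")


class UnknownElementError(SbmlVizError):
    """Raised when a model/layout element id does not resolve."""


class CapabilityError(SbmlVizError):
    """Raised when an operation is outside the supported feature set."""
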