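"""Exception hierarchy shared across the toolkit."""


class SdpkitError(Exception):
    """Base class for all toolkit errors."""


class DialectSyntaxError(SdpkitError):
    """Raised on malformed dialect input; carries line/column of the offender."""

    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class UndeclaredNameError(SdpkitError):
    """A class or role name is used without a matching declaration."""


class UnknownNameError(SdpkitError):
    """A query refers to a name absent from the ontology signature."""


class UnknownRoleError(SdpkitError):
    """A relation mapping refers to a role absent from the ontology."""


class NotEntailedError(SdpkitError):
    """An explanation was requested for a subsumption that does not hold."""


class NotAmbiguousError(SdpkitError):
    """Disambiguation was requested for a class that is already committed
    (or unsatisfiable)."""


class NameCollisionError(SdpkitError):
    """A generated class name collides with a declared one."""


class SizeGuardError(SdpkitError):
    """The naive oracle was invoked on an ontology above its size guard."""


class InvalidParamsError(SdpkitError):
    """Random-ontology parameters are out of range."""


class UnknownFixtureError(SdpkitError):
    """build_fixture was called with a name outside the catalogue."""
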