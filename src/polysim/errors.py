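"""Exception hierarchy for polysim."""


class PolysimError(Exception):
    """Base class for all polysim errors."""


class ValidationError(PolysimError):
    """A value or declaration violates a structural constraint."""


class UnknownComponentError(PolysimError, KeyError):
    """A name refers to a chemical, sequence, family or switch that does
    not exist in the system."""

    def __str__(self) -> str:  # KeyError quotes its args; keep a plain message
        return PolysimError.__str__(self)


class ConsistencyError(PolysimError):
    """Internal bookkeeping (class membership, filters, occupancy) was
    found in an inconsistent state."""


class ImpossibleReactionError(PolysimError):
    """A reaction was asked to fire with zero propensity (no eligible
    reactant or particle)."""


class UnmatchedReleaseError(PolysimError):
    """A release fired for a particle whose (origin family, position) pair
    matches no product interval."""


class NoReactionError(PolysimError):
    """The total propensity is zero: no reaction can be selected."""


class ParseError(PolysimError):
    """Model-definition file could not be parsed.

    Carries the file name and 1-based line number of the offending record.
    """

    def __init__(self, filename: str, line: int, message: str):
        self.filename = filename
        self.line = line
        super().__init__(f"{filename}:{line}: {message}")
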