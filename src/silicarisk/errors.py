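"""Exception hierarchy shared across the package."""


class SilicaRiskError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SilicaRiskError, ValueError):
    """A value violates a documented precondition (e.g. nonpositive LOD)."""


class UnknownLevelError(SilicaRiskError, KeyError):
    """A scenario supplies a categorical level absent from the fitted model.

    Carries the offending variable and level so callers can report precisely;
    silent coercion to the reference level is never performed.
    """

    def __init__(self, variable: str, level: str):
        self.variable = variable
        self.level = level
        super().__init__(f"unknown level {level!r} for variable {variable!r}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"unknown level {self.level!r} for variable {self.variable!r}"


class RankDeficiencyError(SilicaRiskError):
    """The design matrix is rank deficient; lists the aliased terms."""

    def __init__(self, aliased_terms):
        self.aliased_terms = list(aliased_terms)
        super().__init__(f"rank-deficient design; aliased terms: {self.aliased_terms}")


class InsufficientDataError(SilicaRiskError):
    """A categorical level has fewer observations than the configured minimum."""

    def __init__(self, variable: str, level: str, count: int, minimum: int):
        self.variable = variable
        self.level = level
        self.count = count
        self.minimum = minimum
        super().__init__(
            f"level {level!r} of {variable!r} has {count} observation(s); "
            f"minimum cell count is {minimum}"
        )


class SchemaVersionError(SilicaRiskError):
    """A serialized document does not match the expected schema."""


class ConsistencyError(SilicaRiskError):
    """Two inputs that must agree (e.g. scenario vs estimate CSP) do not."""


class NotFoundError(SilicaRiskError, KeyError):
    """An archive lookup failed (unknown or tombstoned ECP id)."""


class RenderError(SilicaRiskError):
    """A document is missing a section required for rendering."""
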