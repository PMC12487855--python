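"""Exception types raised by screenstate.

All inherit from ValueError so callers that only care about "bad input"
can catch one base class.
"""


class ScreenStateError(ValueError):
    """Base class for all screenstate errors."""


class InsufficientControlsError(ScreenStateError):
    """Fewer non-targeting control elements than an operation requires."""


class InsufficientReplicatesError(ScreenStateError):
    """A replicate-based test was asked for with fewer than two replicates."""


class MissingConditionError(ScreenStateError):
    """The count table lacks a condition a phenotype needs (T0/vehicle/drug)."""


class MissingGenesError(ScreenStateError):
    """No gene of a signature is present in the expression matrix."""

    def __init__(self, signature: str, missing: list[str]):
        self.signature = signature
        self.missing = list(missing)
        super().__init__(
            f"signature {signature!r}: none of its genes are in the matrix "
            f"(missing: {', '.join(self.missing[:10])}"
            + ("..." if len(self.missing) > 10 else "")
            + ")"
        )


class AmbiguousMappingError(ScreenStateError):
    """An explicit ortholog map contains conflicting duplicate pairs."""


class NoOverlapError(ScreenStateError):
    """An ortholog map shares no genes with the score tables."""


class ConfigError(ScreenStateError):
    """A pipeline configuration is invalid (unknown stage, missing key)."""
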