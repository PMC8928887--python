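"""Exception hierarchy used across the package."""

from __future__ import annotations


class ADBMError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ADBMError, ValueError):
    """A delimited-text input violates the expected layout or an invariant."""


class DegenerateWebError(ADBMError, ValueError):
    """The observed web has no links or no absences, so the TSS is undefined."""


class TraitRangeError(ADBMError, ValueError):
    """An allometric power overflowed the floating-point range."""


class AcceptanceExhaustedError(ADBMError, RuntimeError):
    """Rejection sampling hit the proposal cap before reaching ``n_accept``.

    Carries the best (minimum) distance seen so the caller can tell whether
    the tolerance sits below the model's attainable distance for the instance.
    """

    def __init__(self, message: str, best_distance: float, attempts: int):
        super().__init__(message)
        self.best_distance = best_distance
        self.attempts = attempts


class ThresholdSelectionError(ADBMError, RuntimeError):
    """No grid tolerance produced a connectance interval covering the target.

    ``table`` holds the per-tolerance interval table for diagnosis.
    """

    def __init__(self, message: str, table=None):
        super().__init__(message)
        self.table = table
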