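"""Exception hierarchy.

Every rejection a user can trigger maps to a distinct class so the CLI can
emit machine-readable error bodies and tests can assert on the failure mode,
not on message text.
"""

from __future__ import annotations

import json
from typing import Any


class RadonDoseError(Exception):
    """Base class for all errors raised by this package."""

    def to_json(self) -> str:
        return json.dumps({"error": type(self).__name__, "message": str(self)})


class ValidationError(RadonDoseError):
    """An input value violates a precondition (negative dose, bad status...)."""


class ConfigError(ValidationError):
    """A parameter file is malformed or contains unknown keys."""


class ConflictError(RadonDoseError):
    """An identifier is already registered."""


class NotFoundError(RadonDoseError):
    """A referenced worker, site or job does not exist."""


class IntegrityError(RadonDoseError):
    """Cross-references are dangling (jobs pointing at unknown sites/workers)."""

    def __init__(self, message: str, dangling: list[str] | None = None):
        super().__init__(message)
        self.dangling = dangling or []


class PlanningBlockedError(RadonDoseError):
    """The site's radon measurement is not valid for planning."""


class DoseLimitError(RadonDoseError):
    """A planned job or edit would push at least one worker over their limit.

    ``violations`` lists one dict per offending worker with the full
    comparison: accumulated dose, job increment, and applicable limit.
    """

    def __init__(self, violations: list[dict[str, Any]]):
        self.violations = violations
        parts = [
            f"{v['worker_id']}: {v['accumulated']:.6g} + {v['increment']:.6g} mSv "
            f"exceeds limit {v['limit']:.6g} mSv"
            for v in violations
        ]
        super().__init__("dose limit exceeded for " + "; ".join(parts))

    def to_json(self) -> str:
        return json.dumps(
            {
                "error": type(self).__name__,
                "message": str(self),
                "violations": self.violations,
            }
        )


class InfeasibleError(RadonDoseError):
    """Fewer available workers than the assignment requires."""

    def __init__(self, message: str, available: int, required: int):
        super().__init__(message)
        self.available = available
        self.required = required


class StateMachineError(RadonDoseError):
    """An input is inconsistent with the current regulatory workflow state."""


class InvalidRangeError(RadonDoseError):
    """A reporting period has end before start."""


class SchemaError(RadonDoseError):
    """A persisted file has a malformed row; ``line`` is 1-based."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DuplicateIdError(SchemaError):
    """A persisted file repeats an identifier that must be unique."""


class DateFormatError(SchemaError):
    """A persisted date field is not ISO-8601."""
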