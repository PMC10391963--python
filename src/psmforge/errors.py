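"""Exception hierarchy.

Every error carries a short machine-readable ``code`` so CLI and batch
callers (e.g. the DSA sweep) can classify failures without string-matching
messages.
"""

from __future__ import annotations


class PSMForgeError(Exception):
    """Base class for all package errors."""

    code: str = "error"

    def __init__(self, message: str, **context):
        super().__init__(message)
        self.context = context


class TemplateIncompleteError(PSMForgeError):
    """A required sheet or column is missing from the input template."""

    code = "template-incomplete"


class InvalidCurveError(PSMForgeError):
    """A digitized curve violates its invariants (e.g. rising survival)."""

    code = "invalid-curve"


class InvalidParameterError(PSMForgeError):
    """A scalar parameter is outside its admissible domain."""

    code = "invalid-parameter"


class InvalidRangeError(PSMForgeError):
    """A sensitivity-analysis range does not bracket its base value."""

    code = "invalid-range"


class ReconstructionInfeasibleError(PSMForgeError):
    """No non-negative censoring count can reproduce the published
    number at risk in some interval."""

    code = "reconstruction-infeasible"


class InvalidScheduleError(PSMForgeError):
    """A resource-use schedule has overlapping or ill-formed phases."""

    code = "invalid-schedule"


class DegenerateArmsError(PSMForgeError):
    """An arm has no events, so a hazard ratio cannot be estimated."""

    code = "degenerate-arms"


class InsufficientEventsError(PSMForgeError):
    """Too few distinct event times for the proportional-hazards test."""

    code = "insufficient-events"


class LogicalInconsistencyError(PSMForgeError):
    """OS fell below PFS at an evaluated cycle boundary; the engine halts
    rather than silently clamping."""

    code = "logical-inconsistency"

    def __init__(self, message: str, cycle: int | None = None, **context):
        super().__init__(message, **context)
        self.cycle = cycle
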