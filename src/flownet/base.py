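"""Shared constants and exception hierarchy.

Every ward-transfer network carries a single reserved sentinel node,
:data:`EXIT`, representing discharge from hospital.  Real ward names may
never collide with it; readers enforce this.
"""

from __future__ import annotations

EXIT = "EXIT"
"""Reserved name of the virtual exit node (discharge)."""

#: Canonical column order for per-event transfer logs.
EVENT_COLUMNS = ["patient_id", "timestamp", "site", "source_ward", "target_ward"]

#: Canonical column order for weekly aggregate tables.
WEEKLY_COLUMNS = ["week_start", "site", "source_ward", "target_ward", "count"]

#: Canonical column order for daily A&E performance series.
PERFORMANCE_COLUMNS = ["date", "site", "performance_pct", "arrivals"]

#: Minute-resolution timestamp format used in all CSV output.
TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M"


class FlowNetError(Exception):
    """Base class for all flownet errors."""


class FormatError(FlowNetError, ValueError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class RowParseError(FormatError):
    """One or more data rows could not be parsed under strict mode.

    Attributes
    ----------
    lines : list of int
        1-based line numbers of the offending rows (header is line 1).
    """

    def __init__(self, message: str, lines: list[int]):
        super().__init__(message)
        self.lines = list(lines)


class UsageError(FlowNetError, ValueError):
    """An operation was called with arguments outside its contract."""


class ValidationError(FlowNetError, ValueError):
    """A domain object violates one of its invariants."""


class ChainError(FlowNetError):
    """A patient's transfer records do not form a contiguous ward chain."""

    def __init__(self, patient_id: str, detail: str):
        super().__init__(f"broken transfer chain for patient {patient_id!r}: {detail}")
        self.patient_id = patient_id


class NodeNotFoundError(FlowNetError, KeyError):
    """A requested ward is absent from the network."""


class UndefinedScoreError(FlowNetError, ValueError):
    """The edge-weight variability score is undefined (fewer than two edges)."""


class SiteAssignmentError(FlowNetError, ValueError):
    """Wards without a site assignment were encountered under strict mode."""

    def __init__(self, wards: list[str]):
        super().__init__(f"no site assignment for wards: {sorted(wards)}")
        self.wards = sorted(wards)


class InvariantError(FlowNetError):
    """An internal cross-object invariant was violated (e.g. core ⊄ month)."""


class StageError(FlowNetError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
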