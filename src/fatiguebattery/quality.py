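"""Pre-specified participant exclusion rules.

A participant is excluded when any of the following holds:

* they gave no response on strictly more than 25% of trials across all
  blocks pooled (visual-search trials cannot be omitted but still count in
  the denominator);
* every response they did give was the same single key ('k' throughout or
  'd' throughout);
* either BRUMS form shows an engagement flag (all items at the same extreme,
  or completed in under one second per item).
"""

from __future__ import annotations

from dataclasses import dataclass

from .brums import TOO_FAST, UNIFORM_EXTREME, brums_quality_flags
from .simulate import SessionData

OMISSION_GT_25PCT = "OMISSION_GT_25PCT"
SINGLE_KEY = "SINGLE_KEY"
BRUMS_UNIFORM_EXTREME = "BRUMS_UNIFORM_EXTREME"
BRUMS_TOO_FAST = "BRUMS_TOO_FAST"

OMISSION_THRESHOLD = 0.25


class InvalidSessionError(ValueError):
    """A session without any trials cannot be quality-checked."""


@dataclass(frozen=True, slots=True)
class ExclusionReport:
    participant_id: str
    excluded: bool
    reasons: frozenset[str]


def _session_report(session: SessionData) -> ExclusionReport:
    if not session.trials:
        raise InvalidSessionError(
            f"session {session.participant_id!r} contains no trials"
        )
    reasons: set[str] = set()

    n_total = len(session.trials)
    n_omitted = sum(1 for t in session.trials if t.response is None)
    if n_omitted / n_total > OMISSION_THRESHOLD:
        reasons.add(OMISSION_GT_25PCT)

    keys = {t.response for t in session.trials if t.response is not None}
    if len(keys) == 1:
        reasons.add(SINGLE_KEY)

    for form in (session.pre_brums, session.post_brums):
        flags = brums_quality_flags(form)
        if UNIFORM_EXTREME in flags:
            reasons.add(BRUMS_UNIFORM_EXTREME)
        if TOO_FAST in flags:
            reasons.add(BRUMS_TOO_FAST)

    return ExclusionReport(
        participant_id=session.participant_id,
        excluded=bool(reasons),
        reasons=frozenset(reasons),
    )


def apply_exclusions(sessions: list[SessionData]) -> list[ExclusionReport]:
    """Quality-check every session; a report is excluded iff it has reasons."""
    if not sessions:
        raise ValueError("sessions must be non-empty")
    return [_session_report(s) for s in sessions]


def retained_sessions(
    sessions: list[SessionData], reports: list[ExclusionReport]
) -> list[SessionData]:
    """Filter sessions down to participants that survived exclusion."""
    excluded = {r.participant_id for r in reports if r.excluded}
    return [s for s in sessions if s.participant_id not in excluded]
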