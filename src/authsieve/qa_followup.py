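"""Ongoing quality assurance after enrollment.

Follow-up surveys every three months re-collect an age (or date of birth) and
optional alternate contact information.  Three QA operations run on the
enrolled cohort: follow-up age verification against the baseline date of
birth, cross-matching of alternate phones/emails against every other
participant's primary contact (dual-enrollment screening), and administrative
discontinuation.  Discontinued participants' canonical contacts stay in the
registry so they can never re-enroll.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .auto_battery import age_in_whole_years
from .cohort_model import (
    FLAG,
    PASS,
    CheckResult,
    FollowUpRecord,
    ThresholdConfig,
    ValidationError,
)
from .matching import CanonicalContact, MatchResult, Registry, canonicalize_email, \
    canonicalize_phone, match_field

DISCONTINUATION_REASONS = (
    "lost_contact",
    "voluntary_withdrawal",
    "enrollment_error",
    "incarceration",
    "deceased",
    "other_unanticipated",
    "fraud_confirmed",
)

# fraud_confirmed is this package's extra category for fraud-driven removals;
# exports map it onto the standard administrative vocabulary
EXPORT_REASON = {r: r for r in DISCONTINUATION_REASONS} | {
    "fraud_confirmed": "other_unanticipated"
}


@dataclass
class DiscontinuationRecord:
    participant_id: str
    reason: str
    noted_on: date

    def __post_init__(self) -> None:
        if self.reason not in DISCONTINUATION_REASONS:
            raise ValidationError(f"unknown discontinuation reason {self.reason!r}")


def check_followup_age(baseline_dob: date, followup: FollowUpRecord) -> CheckResult:
    """Compare the age implied by a follow-up report with the baseline DOB.

    A reported DOB wins over a reported integer age when both are present.
    Agreement passes; disagreement flags for a study-team determination; a
    wave reporting neither is marked not applicable.
    """
    on = followup.completed_at.date()
    expected = age_in_whole_years(baseline_dob, on)
    if followup.reported_dob is not None:
        implied = age_in_whole_years(followup.reported_dob, on)
        source = f"dob {followup.reported_dob.isoformat()}"
    elif followup.reported_age is not None:
        implied = followup.reported_age
        source = "reported age"
    else:
        return CheckResult("followup_age", PASS, reason="no age reported this wave")
    if implied == expected:
        return CheckResult("followup_age", PASS)
    return CheckResult(
        "followup_age", FLAG,
        f"wave {followup.wave_months}: {source} implies {implied}, baseline DOB implies {expected}",
        evidence={"implied": implied, "expected": expected, "wave": followup.wave_months},
    )


@dataclass(frozen=True)
class AlternatePair:
    """A dual-enrollment review pair: one participant's alternate contact
    matching another participant's primary contact."""

    participant_a: str
    participant_b: str
    match: MatchResult


def _canonical_alt_emails(followups: Iterable[FollowUpRecord],
                          config: ThresholdConfig) -> set[str]:
    out = set()
    for f in followups:
        if f.alt_email:
            out.add(canonicalize_email(f.alt_email, config))
    return out


def _canonical_alt_phones(followups: Iterable[FollowUpRecord]) -> set[str]:
    out = set()
    for f in followups:
        if f.alt_phone:
            out.add(canonicalize_phone(f.alt_phone))
    return out


def cross_match_alternates(
    contacts: Mapping[str, CanonicalContact],
    followups: Sequence[FollowUpRecord],
    config: ThresholdConfig,
) -> list[AlternatePair]:
    """Match every alternate phone/email against other participants' primaries.

    ``contacts`` maps enrolled participant id → canonical contact (primary
    keys).  Each exact or partial alternate-vs-primary hit across two distinct
    participants is reported once, ordered by (alternate holder, matched id).
    """
    by_pid: dict[str, list[FollowUpRecord]] = {}
    for f in followups:
        by_pid.setdefault(f.participant_id, []).append(f)
    pairs: list[AlternatePair] = []
    for pid_a in sorted(by_pid):
        if pid_a not in contacts:
            continue
        alt_emails = _canonical_alt_emails(by_pid[pid_a], config)
        alt_phones = _canonical_alt_phones(by_pid[pid_a])
        if not alt_emails and not alt_phones:
            continue
        for pid_b in sorted(contacts):
            if pid_b == pid_a:
                continue
            other = contacts[pid_b]
            for alt in sorted(alt_emails):
                m = match_field(alt, other.email_key, "email", config, other_id=pid_b)
                if m:
                    pairs.append(AlternatePair(pid_a, pid_b, m))
            for alt in sorted(alt_phones):
                for primary in sorted(other.phone_keys):
                    m = match_field(alt, primary, "phone", config, other_id=pid_b)
                    if m:
                        pairs.append(AlternatePair(pid_a, pid_b, m))
    return pairs


class EnrollmentLedger:
    """Enrolled participants, their discontinuations, and the blocking registry."""

    def __init__(self, registry: Registry):
        self.registry = registry
        self._enrolled: set[str] = set()
        self.discontinuations: dict[str, DiscontinuationRecord] = {}

    def enroll(self, contact: CanonicalContact) -> None:
        self._enrolled.add(contact.participant_id)
        if contact.participant_id not in self.registry:
            self.registry.add(contact)

    def is_enrolled(self, participant_id: str) -> bool:
        return participant_id in self._enrolled and participant_id not in self.discontinuations

    def discontinue(
        self, participant_id: str, reason: str, noted_on: date
    ) -> DiscontinuationRecord:
        """Remove a participant from active follow-up.

        The canonical contact stays in the registry, so a fresh dossier with
        the same keys still resolves as a duplicate.  Repeat discontinuation
        is an idempotent no-op (with a warning).
        """
        if participant_id not in self._enrolled:
            raise ValidationError(f"cannot discontinue unknown participant {participant_id!r}")
        if participant_id in self.discontinuations:
            warnings.warn(
                f"participant {participant_id} already discontinued", stacklevel=2
            )
            return self.discontinuations[participant_id]
        record = DiscontinuationRecord(participant_id, reason, noted_on)
        self.discontinuations[participant_id] = record
        return record


def write_discontinuations(
    records: Sequence[DiscontinuationRecord], path: str | Path
) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "reason": EXPORT_REASON[r.reason],
            "internal_reason": r.reason,
            "noted_on": r.noted_on.isoformat(),
        }
        for r in sorted(records, key=lambda r: r.participant_id)
    ]
    pd.DataFrame(
        rows, columns=["participant_id", "reason", "internal_reason", "noted_on"]
    ).to_csv(path, index=False)
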