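"""Checklist-driven manual authentication stage.

Records the automated battery refers to manual review are worked through a
six-item checklist (time stamp, age comparison, duplicate check, survey
pattern check, social-media check, zip check).  Flag-level findings carried
over from the battery pre-populate their items as pending; human (here:
evidence-driven) resolutions mark each pending item pass, fail or
``resolved_explainable`` with a mandatory note.  A case reaches one of three
dispositions:

* ``failed_duplicate_no_checklist`` — an exact duplicate confirmed before the
  checklist is worked (e.g. a within-batch duplicate surfacing once earlier
  cases from the same batch are on file),
* ``failed_checklist`` — at least one checklist item failed,
* ``enrolled`` — every item pass/resolved and the email verification loop
  (30-day window, weekly reminders) completed in time.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .cohort_model import (
    FAIL,
    FLAG,
    PASS,
    AutoDecision,
    AuditLog,
    CheckResult,
    LookupTables,
    ParticipantDossier,
    STATUS_REFERRED_MANUAL,
    ThresholdConfig,
    ValidationError,
)
from .matching import (
    EXACT,
    AddressKey,
    Registry,
    canonicalize_dossier,
    partial_match_address,
)
from .pattern_detect import ConflictRule, pattern_review

# checklist items
ITEM_TIME = "time_stamp"
ITEM_AGE = "age_comparison"
ITEM_DUPLICATE = "duplicate_check"
ITEM_PATTERN = "pattern_check"
ITEM_SOCIAL = "social_media_check"
ITEM_ZIP = "zip_check"
CHECKLIST_ITEMS = (ITEM_TIME, ITEM_AGE, ITEM_DUPLICATE, ITEM_PATTERN, ITEM_SOCIAL, ITEM_ZIP)

# item states
PENDING = "pending"
RESOLVED_EXPLAINABLE = "resolved_explainable"
NOT_APPLICABLE = "not_applicable"
ITEM_OUTCOMES = (PENDING, PASS, FAIL, RESOLVED_EXPLAINABLE, NOT_APPLICABLE)

# dispositions
ENROLLED = "enrolled"
FAILED_CHECKLIST = "failed_checklist"
FAILED_DUPLICATE_NO_CHECKLIST = "failed_duplicate_no_checklist"
DISPOSITIONS = (ENROLLED, FAILED_CHECKLIST, FAILED_DUPLICATE_NO_CHECKLIST)

# which checklist item a carried battery flag lands on; location-consistency
# flags (IP state vs mailing, screen vs baseline, unknown location, zip
# mismatch) share the zip/location item, and near-threshold completion flags
# trigger the survey pattern review
FLAG_TO_ITEM = {
    "completion_time": ITEM_TIME,
    "age_consistency": ITEM_AGE,
    "duplicate": ITEM_DUPLICATE,
    "completion_score": ITEM_PATTERN,
    "pattern": ITEM_PATTERN,
    "social_media": ITEM_SOCIAL,
    "zip_mismatch": ITEM_ZIP,
    "ip_country": ITEM_ZIP,
    "ip_state_vs_mailing": ITEM_ZIP,
    "ip_screen_vs_baseline": ITEM_ZIP,
    "sms_code": ITEM_TIME,
    "eligibility": ITEM_AGE,
}

EMAIL_PENDING = "pending"
EMAIL_VERIFIED = "verified"
EMAIL_EXPIRED = "expired"


@dataclass
class VerificationState:
    issued_on: date
    responded_on: date | None = None
    reminders_sent: list[date] = field(default_factory=list)
    status: str = EMAIL_PENDING


def issue_verification(issued_on: date) -> VerificationState:
    return VerificationState(issued_on=issued_on)


def email_verification_step(
    state: VerificationState,
    now: date,
    response: bool = False,
    config: ThresholdConfig | None = None,
) -> VerificationState:
    """Advance the email-verification lifecycle to ``now``.

    Weekly reminders accrue at 7-day marks since issuance while the state is
    pending and inside the 30-day window; a response on or before day 30
    verifies, and any later date without a response expires the attempt (the
    participant is not enrolled).
    """
    config = config or ThresholdConfig()
    if state.status != EMAIL_PENDING:
        return state
    if response and now < state.issued_on:
        raise ValidationError("email response precedes issuance")
    window = config.email_window_days
    period = config.reminder_period_days
    new = replace(state, reminders_sent=list(state.reminders_sent))
    k = 1
    while True:
        mark = state.issued_on + timedelta(days=k * period)
        days = k * period
        if days > window or mark > now or (response and mark >= now):
            break
        if mark not in new.reminders_sent:
            new.reminders_sent.append(mark)
        k += 1
    elapsed = (now - state.issued_on).days
    if response:
        if elapsed <= window:
            new.responded_on = now
            new.status = EMAIL_VERIFIED
        else:
            new.status = EMAIL_EXPIRED
    elif elapsed > window:
        new.status = EMAIL_EXPIRED
    return new


@dataclass
class ChecklistItem:
    item: str
    outcome: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.item not in CHECKLIST_ITEMS:
            raise ValidationError(f"unknown checklist item {self.item!r}")
        if self.outcome not in ITEM_OUTCOMES:
            raise ValidationError(f"unknown item outcome {self.outcome!r}")
        if self.outcome == RESOLVED_EXPLAINABLE and not self.note:
            raise ValidationError(f"{self.item}: resolved_explainable requires a note")


@dataclass
class ManualCase:
    participant_id: str
    items: dict[str, ChecklistItem]
    disposition: str | None = None
    email_verification: VerificationState | None = None

    def pending_items(self) -> list[str]:
        return [name for name, item in self.items.items() if item.outcome == PENDING]

    def failed_items(self) -> list[str]:
        return [name for name, item in self.items.items() if item.outcome == FAIL]


def build_checklist(decision: AutoDecision, dossier: ParticipantDossier) -> ManualCase:
    """Open a manual case: carried flags pre-populate their items as pending,
    the social check opens pending only when a handle was provided (it is not
    a participation requirement), and everything else starts as pass."""
    if decision.status != STATUS_REFERRED_MANUAL:
        raise ValidationError(
            f"build_checklist requires a referred_manual decision, got {decision.status}"
        )
    items = {name: ChecklistItem(name, PASS) for name in CHECKLIST_ITEMS}
    items[ITEM_SOCIAL] = ChecklistItem(
        ITEM_SOCIAL,
        PENDING if dossier.contact.social_handles else NOT_APPLICABLE,
        note="" if dossier.contact.social_handles else "no handle provided",
    )
    for flag in decision.flags_carried:
        name = FLAG_TO_ITEM.get(flag.check_id)
        if name is None:
            continue
        items[name] = ChecklistItem(name, PENDING, note=flag.reason)
    return ManualCase(decision.participant_id, items)


def verify_zip(
    address_key: AddressKey | None,
    lookups: LookupTables,
    registry: Registry | None = None,
    config: ThresholdConfig | None = None,
) -> CheckResult:
    """Compare the submitted zip with the gazetteer zip for the street/city.

    A mismatch flags the case and triggers a review for similar addresses
    (partial-street matches against the registry, attached as evidence); an
    address absent from the gazetteer flags "unknown".
    """
    if address_key is None or not address_key.street_key:
        return CheckResult("zip_mismatch", FLAG, "no street address to verify")
    indexed = lookups.gazetteer.get((address_key.street_key, address_key.city_key))
    if indexed is None:
        return CheckResult(
            "zip_mismatch", FLAG, "address unknown to gazetteer",
            evidence={"street": address_key.street_key, "city": address_key.city_key},
        )
    if indexed != address_key.zip:
        similar: list[str] = []
        if registry is not None:
            similar = [
                entry.participant_id
                for entry in registry
                if entry.address_key is not None
                and partial_match_address(address_key, entry.address_key) != "none"
            ]
        return CheckResult(
            "zip_mismatch", FLAG,
            f"submitted zip {address_key.zip} != indexed zip {indexed}",
            evidence={"indexed_zip": indexed, "similar_addresses": sorted(similar)},
        )
    return CheckResult("zip_mismatch", PASS)


@dataclass
class SocialEvidence:
    """Structured facts read off a (modeled) public social-media profile."""

    age: int | None = None
    gender: str | None = None
    location_state: str | None = None
    handle_exists: bool = True


def apply_social_evidence(
    case: ManualCase,
    evidence: SocialEvidence,
    dossier: ParticipantDossier,
) -> ManualCase:
    """Resolve the social-media item from profile facts.

    Any provided fact contradicting the dossier (age, gender, location) fails
    the item; facts that corroborate pass it; a profile with no usable facts
    leaves it pending for a human note.
    """
    if not dossier.contact.social_handles:
        case.items[ITEM_SOCIAL] = ChecklistItem(ITEM_SOCIAL, NOT_APPLICABLE, "no handle provided")
        return case
    contradictions = []
    corroborations = 0
    if evidence.age is not None:
        if evidence.age != dossier.screening.reported_age_years:
            contradictions.append(
                f"profile age {evidence.age} vs reported {dossier.screening.reported_age_years}"
            )
        else:
            corroborations += 1
    if evidence.gender is not None:
        if evidence.gender != dossier.screening.gender_identity:
            contradictions.append(
                f"profile gender {evidence.gender} vs reported {dossier.screening.gender_identity}"
            )
        else:
            corroborations += 1
    if evidence.location_state is not None:
        if dossier.contact.state and evidence.location_state != dossier.contact.state:
            contradictions.append(
                f"profile location {evidence.location_state} vs mailing state "
                f"{dossier.contact.state}"
            )
        else:
            corroborations += 1
    if contradictions:
        case.items[ITEM_SOCIAL] = ChecklistItem(ITEM_SOCIAL, FAIL, "; ".join(contradictions))
    elif corroborations:
        case.items[ITEM_SOCIAL] = ChecklistItem(ITEM_SOCIAL, PASS, "profile corroborates")
    # else: no usable facts — item stays as it was (pending)
    return case


def resolve_case(
    case: ManualCase,
    resolutions: Sequence[tuple[str, str, str]] = (),
) -> ManualCase:
    """Apply human resolutions to every pending item and set the disposition.

    Any item left failing yields ``failed_checklist``; otherwise enrollment
    requires the email verification to have completed within its window.  An
    unresolved pending item is a contract error.
    """
    for name, outcome, note in resolutions:
        if name not in case.items:
            raise ValidationError(f"resolution for unknown item {name!r}")
        if case.items[name].outcome != PENDING:
            continue
        if outcome not in (PASS, FAIL, RESOLVED_EXPLAINABLE, NOT_APPLICABLE):
            raise ValidationError(f"bad resolution outcome {outcome!r}")
        case.items[name] = ChecklistItem(name, outcome, note)
    pending = case.pending_items()
    if pending:
        raise ValidationError(f"unresolved pending item(s): {', '.join(pending)}")
    if case.failed_items():
        case.disposition = FAILED_CHECKLIST
    else:
        email = case.email_verification
        if email is not None and email.status == EMAIL_VERIFIED:
            case.disposition = ENROLLED
        elif email is not None and email.status == EMAIL_EXPIRED:
            case.disposition = FAILED_CHECKLIST
        else:
            raise ValidationError(
                f"case {case.participant_id}: cannot enroll without a completed "
                "email verification"
            )
    return case


@dataclass
class ManualEvidence:
    """Generator-planted (or operator-supplied) inputs for one manual case."""

    social: SocialEvidence | None = None
    email_response_day: int | None = 3  # days after issuance; None = never responds
    resolutions: list[tuple[str, str, str]] = field(default_factory=list)


def run_manual_stage(
    decisions: Sequence[AutoDecision],
    dossiers: Mapping[str, ParticipantDossier],
    evidence: Mapping[str, ManualEvidence],
    registry: Registry,
    lookups: LookupTables,
    config: ThresholdConfig,
    rules: Sequence[ConflictRule] = (),
    audit: AuditLog | None = None,
) -> list[ManualCase]:
    """Work every referred decision through the manual checklist in id order.

    A session registry (main registry plus every case processed so far in this
    run) catches within-batch duplicates: an exact contact match confirmed
    before the checklist is worked closes the case as
    ``failed_duplicate_no_checklist``.  The survey pattern review runs for any
    case carrying flags (which includes near-threshold completion).  All
    contacts — enrolled or failed — are retained to block re-entry.
    """
    session = copy.deepcopy(registry)
    cases: list[ManualCase] = []
    referred = sorted(
        (d for d in decisions if d.status == STATUS_REFERRED_MANUAL),
        key=lambda d: d.participant_id,
    )
    for decision in referred:
        dossier = dossiers[decision.participant_id]
        probe = canonicalize_dossier(dossier, config)
        ev = evidence.get(decision.participant_id, ManualEvidence())

        exact = [m for m in session.find_duplicates(probe, config) if m.kind == EXACT]
        if exact:
            items = {
                name: ChecklistItem(name, NOT_APPLICABLE, "duplicate confirmed before checklist")
                for name in CHECKLIST_ITEMS
            }
            case = ManualCase(
                decision.participant_id, items, disposition=FAILED_DUPLICATE_NO_CHECKLIST
            )
            if audit is not None:
                audit.record(decision.participant_id, CheckResult(
                    "duplicate", FAIL, "exact duplicate confirmed during manual processing",
                    evidence={"matches": [f"{m.field}:{m.other_id}" for m in exact]},
                ))
            cases.append(case)
            session.add(probe)
            continue

        case = build_checklist(decision, dossier)

        zip_result = verify_zip(probe.address_key, lookups, registry=session, config=config)
        if audit is not None:
            audit.record(decision.participant_id, zip_result)
        if zip_result.outcome == FLAG and case.items[ITEM_ZIP].outcome == PASS:
            case.items[ITEM_ZIP] = ChecklistItem(ITEM_ZIP, PENDING, zip_result.reason)

        if ev.social is not None:
            case = apply_social_evidence(case, ev.social, dossier)
        if case.items[ITEM_SOCIAL].outcome == PENDING and not any(
            name == ITEM_SOCIAL for name, _, _ in ev.resolutions
        ):
            case.items[ITEM_SOCIAL] = ChecklistItem(
                ITEM_SOCIAL, NOT_APPLICABLE, "no usable public profile facts"
            )

        if decision.flags_carried:
            review = pattern_review(dossier.baseline, config, rules)
            if audit is not None:
                audit.record(decision.participant_id, review)
            if review.outcome == FAIL:
                case.items[ITEM_PATTERN] = ChecklistItem(ITEM_PATTERN, FAIL, review.reason)
            elif case.items[ITEM_PATTERN].outcome == PENDING:
                case.items[ITEM_PATTERN] = ChecklistItem(
                    ITEM_PATTERN, PASS, "survey review clean"
                )

        issued = dossier.baseline.ended_at.date()
        state = issue_verification(issued)
        if ev.email_response_day is not None:
            state = email_verification_step(
                state, issued + timedelta(days=ev.email_response_day), response=True,
                config=config,
            )
        else:
            state = email_verification_step(
                state, issued + timedelta(days=config.email_window_days + 1), config=config,
            )
        case.email_verification = state

        case = resolve_case(case, ev.resolutions)
        if audit is not None:
            for name, item in sorted(case.items.items()):
                if item.outcome == FAIL:
                    audit.record(decision.participant_id, CheckResult(
                        "pattern" if name == ITEM_PATTERN else "duplicate"
                        if name == ITEM_DUPLICATE else "completion_time"
                        if name == ITEM_TIME else "age_consistency"
                        if name == ITEM_AGE else "social_media"
                        if name == ITEM_SOCIAL else "zip_mismatch",
                        FAIL, item.note or "checklist item failed",
                    ))
        cases.append(case)
        session.add(probe)
    return cases


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_CASE_COLUMNS = (
    ["participant_id", "disposition"]
    + [f"item_{name}" for name in CHECKLIST_ITEMS]
    + [f"note_{name}" for name in CHECKLIST_ITEMS]
    + ["email_status"]
)


def write_manual_cases(cases: Sequence[ManualCase], path: str | Path) -> None:
    rows = []
    for case in sorted(cases, key=lambda c: c.participant_id):
        row = {"participant_id": case.participant_id, "disposition": case.disposition or ""}
        for name in CHECKLIST_ITEMS:
            row[f"item_{name}"] = case.items[name].outcome
            row[f"note_{name}"] = case.items[name].note
        row["email_status"] = (
            case.email_verification.status if case.email_verification else ""
        )
        rows.append(row)
    pd.DataFrame(rows, columns=_CASE_COLUMNS).to_csv(path, index=False)


def read_manual_cases(path: str | Path) -> list[ManualCase]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    cases = []
    for row in frame.to_dict("records"):
        items = {
            name: ChecklistItem(name, row[f"item_{name}"], row[f"note_{name}"])
            for name in CHECKLIST_ITEMS
        }
        cases.append(ManualCase(row["participant_id"], items, row["disposition"] or None))
    return cases


_EVIDENCE_COLUMNS = [
    "participant_id", "social_age", "social_gender", "social_location",
    "email_response_day", "resolutions",
]


def write_manual_evidence(evidence: Mapping[str, ManualEvidence], path: str | Path) -> None:
    rows = []
    for pid in sorted(evidence):
        ev = evidence[pid]
        rows.append({
            "participant_id": pid,
            "social_age": "" if ev.social is None or ev.social.age is None else ev.social.age,
            "social_gender": "" if ev.social is None or ev.social.gender is None else ev.social.gender,
            "social_location": (
                "" if ev.social is None or ev.social.location_state is None
                else ev.social.location_state
            ),
            "email_response_day": "" if ev.email_response_day is None else ev.email_response_day,
            "resolutions": json.dumps(ev.resolutions) if ev.resolutions else "",
        })
    pd.DataFrame(rows, columns=_EVIDENCE_COLUMNS).to_csv(path, index=False)


def read_manual_evidence(path: str | Path) -> dict[str, ManualEvidence]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    out: dict[str, ManualEvidence] = {}
    for row in frame.to_dict("records"):
        social = None
        if row["social_age"] or row["social_gender"] or row["social_location"]:
            social = SocialEvidence(
                age=int(row["social_age"]) if row["social_age"] else None,
                gender=row["social_gender"] or None,
                location_state=row["social_location"] or None,
            )
        resolutions = [
            tuple(entry) for entry in json.loads(row["resolutions"])
        ] if row["resolutions"] else []
        out[row["participant_id"]] = ManualEvidence(
            social=social,
            email_response_day=(
                int(row["email_response_day"]) if row["email_response_day"] else None
            ),
            resolutions=resolutions,
        )
    return out
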