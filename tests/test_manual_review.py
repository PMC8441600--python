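"""Manual checklist lifecycle: flags → pending items → resolutions → disposition,
zip verification, social evidence, and the email-verification window."""

from datetime import date, timedelta

import pytest

from authsieve.cohort_model import AutoDecision, CheckResult, ThresholdConfig, ValidationError
from authsieve.manual_review import (
    CHECKLIST_ITEMS,
    ENROLLED,
    FAILED_CHECKLIST,
    FAILED_DUPLICATE_NO_CHECKLIST,
    ITEM_AGE,
    ITEM_PATTERN,
    ITEM_SOCIAL,
    ITEM_TIME,
    ITEM_ZIP,
    ManualCase,
    ChecklistItem,
    SocialEvidence,
    apply_social_evidence,
    build_checklist,
    email_verification_step,
    issue_verification,
    resolve_case,
    run_manual_stage,
    verify_zip,
)
from authsieve.matching import parse_address
from authsieve.synth_cohort import ArchetypeSpec, generate_cohort

CONFIG = ThresholdConfig()


def _referred(flags=(), with_handle=True, seed=51):
    cohort = generate_cohort([ArchetypeSpec("clean", 1)], seed=seed)
    dossier = cohort.dossiers[0]
    if with_handle:
        dossier.contact.social_handles.setdefault("chirper", "user_fixture")
    else:
        dossier.contact.social_handles = {}
    decision = AutoDecision(
        dossier.participant_id, "referred_manual",
        [CheckResult(check_id, "flag", "carried") for check_id in flags],
    )
    return decision, dossier, cohort


# -- checklist construction -------------------------------------------------


def test_build_checklist_maps_flags_to_pending_items():
    decision, dossier, _ = _referred(["completion_time"], with_handle=False)
    case = build_checklist(decision, dossier)
    assert case.items[ITEM_TIME].outcome == "pending"
    assert case.items[ITEM_SOCIAL].outcome == "not_applicable"
    for name in (ITEM_AGE, ITEM_PATTERN, ITEM_ZIP):
        assert case.items[name].outcome == "pass"


def test_build_checklist_fast_path_and_multi_flag():
    decision, dossier, _ = _referred([], with_handle=False)
    assert build_checklist(decision, dossier).pending_items() == []
    decision, dossier, _ = _referred(["age_consistency", "pattern"], with_handle=False)
    case = build_checklist(decision, dossier)
    assert sorted(case.pending_items()) == sorted([ITEM_AGE, ITEM_PATTERN])


def test_build_checklist_rejects_wrong_status():
    decision, dossier, _ = _referred()
    decision.status = "duplicate"
    with pytest.raises(ValidationError):
        build_checklist(decision, dossier)


# -- zip verification -------------------------------------------------------


def test_verify_zip_outcomes(default_cohort):
    lookups = default_cohort.lookups
    (street, city), zip_code = next(iter(lookups.gazetteer.items()))
    good = parse_address("12", street, city, "GA", zip_code)
    assert verify_zip(good, lookups).outcome == "pass"
    bad = parse_address("12", street, city, "GA", "00000")
    result = verify_zip(bad, lookups, registry=default_cohort.registry, config=CONFIG)
    assert result.outcome == "flag" and "similar_addresses" in result.evidence
    unknown = parse_address("12", "Nowhere Boulevard", "atlantis", "GA", "00000")
    assert "unknown" in verify_zip(unknown, lookups).reason


# -- social-media evidence --------------------------------------------------


def test_social_evidence_corroboration_contradiction_and_absence():
    decision, dossier, _ = _referred()
    age = dossier.screening.reported_age_years
    case = build_checklist(decision, dossier)
    case = apply_social_evidence(case, SocialEvidence(age=age), dossier)
    assert case.items[ITEM_SOCIAL].outcome == "pass"

    case = build_checklist(decision, dossier)
    case = apply_social_evidence(case, SocialEvidence(age=25), dossier)
    assert case.items[ITEM_SOCIAL].outcome == "fail"

    case = build_checklist(decision, dossier)
    case = apply_social_evidence(case, SocialEvidence(), dossier)
    assert case.items[ITEM_SOCIAL].outcome == "pending"  # no usable facts

    _, no_handle, _ = _referred(with_handle=False)
    case = build_checklist(decision, dossier)
    case = apply_social_evidence(case, SocialEvidence(age=age), no_handle)
    assert case.items[ITEM_SOCIAL].outcome == "not_applicable"


# -- email verification window ----------------------------------------------


def test_email_response_on_day_30_verifies():
    state = issue_verification(date(2018, 6, 1))
    state = email_verification_step(state, date(2018, 6, 1) + timedelta(days=30), response=True)
    assert state.status == "verified"


def test_email_window_closes_after_day_30_with_weekly_reminders():
    issued = date(2018, 6, 1)
    state = issue_verification(issued)
    state = email_verification_step(state, issued + timedelta(days=31))
    assert state.status == "expired"
    assert [(d - issued).days for d in state.reminders_sent] == [7, 14, 21, 28]


def test_email_prompt_response_sends_no_reminders():
    state = issue_verification(date(2018, 6, 1))
    state = email_verification_step(state, date(2018, 6, 2), response=True)
    assert state.status == "verified" and state.reminders_sent == []


def test_email_response_before_issuance_is_an_error():
    state = issue_verification(date(2018, 6, 1))
    with pytest.raises(ValidationError):
        email_verification_step(state, date(2018, 5, 31), response=True)


# -- case resolution --------------------------------------------------------


def _verified_state():
    state = issue_verification(date(2018, 6, 1))
    return email_verification_step(state, date(2018, 6, 4), response=True)


def test_resolved_explainable_with_verified_email_enrolls():
    decision, dossier, _ = _referred(["completion_time"], with_handle=False)
    case = build_checklist(decision, dossier)
    case.email_verification = _verified_state()
    case = resolve_case(
        case, [(ITEM_TIME, "resolved_explainable", "travel; confirmed by contact")]
    )
    assert case.disposition == ENROLLED


def test_any_failed_item_fails_the_checklist():
    decision, dossier, _ = _referred(["pattern"], with_handle=False)
    case = build_checklist(decision, dossier)
    case.email_verification = _verified_state()
    case = resolve_case(case, [(ITEM_PATTERN, "fail", "straight-lined block")])
    assert case.disposition == FAILED_CHECKLIST


def test_unresolved_pending_item_is_a_contract_error():
    decision, dossier, _ = _referred(["completion_time"], with_handle=False)
    case = build_checklist(decision, dossier)
    case.email_verification = _verified_state()
    with pytest.raises(ValidationError, match="pending"):
        resolve_case(case, [])


def test_resolved_explainable_requires_a_note():
    with pytest.raises(ValidationError):
        ChecklistItem(ITEM_TIME, "resolved_explainable", "")


def test_no_enrollment_without_verified_email():
    decision, dossier, _ = _referred([], with_handle=False)
    case = build_checklist(decision, dossier)
    state = issue_verification(date(2018, 6, 1))
    case.email_verification = email_verification_step(state, date(2018, 7, 10))
    case = resolve_case(case, [])
    assert case.email_verification.status == "expired"
    assert case.disposition == FAILED_CHECKLIST


# -- full manual stage ------------------------------------------------------


def test_manual_stage_catches_within_batch_duplicates():
    cohort = generate_cohort(
        [
            ArchetypeSpec("clean", 12),
            ArchetypeSpec("exact_duplicate", 2, (("stage", "manual"),)),
        ],
        seed=61,
    )
    from authsieve.auto_battery import run_battery

    decisions = run_battery(cohort.dossiers, cohort.registry, cohort.lookups, cohort.config)
    assert all(d.status == "referred_manual" for d in decisions)
    cases = run_manual_stage(
        decisions, {d.participant_id: d for d in cohort.dossiers},
        cohort.manual_evidence, cohort.registry, cohort.lookups,
        cohort.config, cohort.conflict_rules,
    )
    dispositions = [c.disposition for c in cases]
    assert dispositions.count(FAILED_DUPLICATE_NO_CHECKLIST) == 2
    assert dispositions.count(ENROLLED) == 12


def test_dispositions_partition_the_manual_cohort(default_run):
    _, decisions, cases = default_run
    referred = sum(1 for d in decisions if d.status == "referred_manual")
    assert len(cases) == referred
    assert all(c.disposition in (ENROLLED, FAILED_CHECKLIST, FAILED_DUPLICATE_NO_CHECKLIST)
               for c in cases)
    assert all(len(c.items) == len(CHECKLIST_ITEMS) for c in cases)


def test_every_enrollment_has_a_verified_email(default_run):
    _, _, cases = default_run
    for case in cases:
        if case.disposition == ENROLLED:
            assert case.email_verification.status == "verified"
            assert not case.failed_items()


def test_reason_multiplicity_bound(default_run):
    """Non-exclusive failure reasons: summed reason tallies are at least the
    checklist-failure count (equality only when no case has two reasons)."""
    _, _, cases = default_run
    failures = [c for c in cases if c.disposition == FAILED_CHECKLIST]
    reason_sum = sum(
        1 for c in failures for item in c.items.values() if item.outcome == "fail"
    )
    assert reason_sum >= len(failures)
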