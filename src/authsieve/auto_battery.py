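"""The automated (electronic) authentication battery and its precedence rule.

Every baseline-starting dossier runs the full battery — eligibility recheck,
duplicate search, IP-location consistency, screener-age vs date-of-birth
comparison, completion time and completion scores — and receives exactly one
mutually exclusive status:

1. ``eligibility_fail``  — failed the eligibility recheck,
2. ``duplicate``         — exact contact match against the registry,
3. ``ip_foreign``        — baseline IP geolocates outside the United States,
4. ``completion_fail``   — below the hard completion-score gates,
5. ``cluster_case``      — partial-street address cluster (no exact duplicate),
6. ``referred_manual``   — everything else, carrying its flag-level results to
   the manual stage.

The precedence order mirrors the reporting order of the automated-status table
and makes the partition deterministic when a record trips several checks.
Flag-level findings (state mismatches, near-threshold completion, age
discrepancies, speeders, partial matches) never exclude on their own; they
route the record to manual review.
"""

from __future__ import annotations

from datetime import date, datetime
from typing import Sequence

from .cohort_model import (
    FAIL,
    FLAG,
    PASS,
    AutoDecision,
    AuditLog,
    CheckResult,
    LookupTables,
    ParticipantDossier,
    STATUS_CLUSTER_CASE,
    STATUS_COMPLETION_FAIL,
    STATUS_DUPLICATE,
    STATUS_ELIGIBILITY_FAIL,
    STATUS_IP_FOREIGN,
    STATUS_REFERRED_MANUAL,
    ThresholdConfig,
    ValidationError,
)
from .matching import EXACT, Registry, canonicalize_dossier


def verify_sms_code(
    issued: str,
    entered: str | None,
    attempt_log: list | None = None,
    config: ThresholdConfig | None = None,
) -> CheckResult:
    """Check the SMS verification code typed back during screening.

    A wrong entry flags the attempt and notifies the study team (support
    event appended to ``attempt_log``); no entry at all is a fail, since the
    screener cannot be continued without the code.
    """
    config = config or ThresholdConfig()
    if not (issued.isdigit() and len(issued) == config.code_digits):
        raise ValidationError(
            f"issued code {issued!r} is not a {config.code_digits}-digit code"
        )
    if entered is None:
        return CheckResult("sms_code", FAIL, "no code entered; screening blocked")
    if entered == issued:
        return CheckResult("sms_code", PASS)
    if attempt_log is not None:
        attempt_log.append({"event": "support_notified", "entered": entered})
    return CheckResult(
        "sms_code", FLAG, "incorrect code entered; support offered",
        evidence={"entered": entered},
    )


def recheck_eligibility(dossier: ParticipantDossier, config: ThresholdConfig) -> CheckResult:
    """Re-apply the eligibility criteria to the screening answers.

    Eligible: age within [min_age, max_age]; assigned male at birth and
    identifying as a man; same-sex attracted; not HIV-positive; inside the
    recruitment region when region gating is enabled; enrollment-quota
    predicate satisfied when quota gating is enabled.
    """
    s = dossier.screening
    reasons = []
    if not (config.min_age <= s.reported_age_years <= config.max_age):
        reasons.append(f"age {s.reported_age_years} outside [{config.min_age}, {config.max_age}]")
    if not (s.sex_assigned_at_birth == "male" and s.gender_identity == "man"):
        reasons.append("not an assigned-male participant identifying as a man")
    if not s.same_sex_attracted:
        reasons.append("did not report same-sex attraction")
    if s.hiv_status == "positive":
        reasons.append("HIV positive at baseline")
    if config.recruitment_states is not None and s.zip:
        state = dossier.contact.state
        if state and state not in config.recruitment_states:
            reasons.append(f"state {state} outside recruitment region")
    if config.quota_gating and not s.quota_ok:
        reasons.append("enrollment quota criteria not met")
    if reasons:
        return CheckResult("eligibility", FAIL, "; ".join(reasons))
    return CheckResult("eligibility", PASS)


def age_in_whole_years(dob: date, on: date) -> int:
    """Civil (whole-year) age: calendar-year difference, decremented when the
    birthday has not yet occurred."""
    return on.year - dob.year - ((on.month, on.day) < (dob.month, dob.day))


def check_age_consistency(
    reported_age: int, dob: date, completed_at: date
) -> CheckResult:
    """Compare the screener-reported age with the age implied by the baseline
    date of birth at questionnaire completion."""
    if (completed_at - dob).days > 120 * 366:
        raise ValidationError(f"dob {dob} is more than 120 years before {completed_at}")
    computed = age_in_whole_years(dob, completed_at)
    if computed == reported_age:
        return CheckResult("age_consistency", PASS)
    evidence = {"reported": reported_age, "computed": computed, "dob": dob.isoformat()}
    reason = f"reported {reported_age}, computed {computed}"
    if completed_at < dob <= date.fromordinal(completed_at.toordinal() + 31):
        reason += " (explainable: future DOB)"
        evidence["explainable"] = "future DOB"
    return CheckResult("age_consistency", FLAG, reason, evidence=evidence)


def check_ip_location(
    screen_ip: str,
    baseline_ip: str,
    mailing_state: str,
    geo: LookupTables,
) -> list[CheckResult]:
    """Three location-consistency results.

    (a) ``ip_country``: fail only when the baseline IP confirmedly geolocates
    outside the US; an unmapped IP flags "unknown location" instead.
    (b) ``ip_state_vs_mailing``: flag when the (US) baseline-IP state differs
    from the mailing-address state.
    (c) ``ip_screen_vs_baseline``: flag when the screening and baseline IPs
    geolocate to different states.
    """
    results: list[CheckResult] = []
    base_loc = geo.locate(baseline_ip)
    screen_loc = geo.locate(screen_ip)

    if base_loc is None:
        results.append(CheckResult(
            "ip_country", FLAG, "unknown location", evidence={"ip": baseline_ip},
        ))
    elif base_loc[0] != "US":
        results.append(CheckResult(
            "ip_country", FAIL, f"baseline IP outside the United States ({base_loc[0]})",
            evidence={"ip": baseline_ip, "country": base_loc[0]},
        ))
    else:
        results.append(CheckResult("ip_country", PASS))

    if base_loc is None:
        results.append(CheckResult(
            "ip_state_vs_mailing", FLAG, "unknown location", evidence={"ip": baseline_ip},
        ))
    elif base_loc[0] == "US" and mailing_state and base_loc[1] != mailing_state:
        results.append(CheckResult(
            "ip_state_vs_mailing", FLAG,
            f"IP state {base_loc[1]} differs from mailing state {mailing_state}",
            evidence={"ip_state": base_loc[1], "mailing_state": mailing_state},
        ))
    else:
        results.append(CheckResult("ip_state_vs_mailing", PASS))

    if screen_loc is None:
        results.append(CheckResult(
            "ip_screen_vs_baseline", FLAG, "unknown location", evidence={"ip": screen_ip},
        ))
    elif base_loc is not None and screen_loc != base_loc:
        results.append(CheckResult(
            "ip_screen_vs_baseline", FLAG,
            f"screening IP locates to {screen_loc[1] or screen_loc[0]}, "
            f"baseline IP to {base_loc[1] or base_loc[0]}",
            evidence={"screen": screen_loc, "baseline": base_loc},
        ))
    else:
        results.append(CheckResult("ip_screen_vs_baseline", PASS))
    return results


def check_completion_time(
    started_at: datetime, ended_at: datetime, config: ThresholdConfig
) -> CheckResult:
    """Flag questionnaires finished in under ``min_minutes`` (speeders, bots)
    or over ``max_hours`` (abandoned/unattended sessions)."""
    seconds = (ended_at - started_at).total_seconds()
    if seconds < 0:
        raise ValidationError("negative completion duration")
    minutes = seconds / 60.0
    if minutes < config.min_minutes:
        return CheckResult(
            "completion_time", FLAG, "too fast",
            evidence={"minutes": round(minutes, 2), "threshold": config.min_minutes},
        )
    if minutes > config.max_hours * 60:
        return CheckResult(
            "completion_time", FLAG, "unusually long",
            evidence={"hours": round(minutes / 60, 2), "threshold_hours": config.max_hours},
        )
    return CheckResult("completion_time", PASS)


def score_completion(
    subset: Sequence[int | None],
    outcome: Sequence[int | None],
    config: ThresholdConfig,
) -> tuple[CheckResult, int, int]:
    """Answered-item gates on the random subset and primary-outcome blocks.

    Hard fail below ``ceil(0.60·27)=17`` or ``ceil(0.70·62)=44`` answered;
    flag (manual review) when past the fail gates but below the 80% band
    (``ceil(0.80·27)=22`` / ``ceil(0.80·62)=50``); else pass.  Returns the
    result plus both answered counts.
    """
    if len(subset) != config.subset_n or len(outcome) != config.outcome_n:
        raise ValidationError(
            f"slot counts {len(subset)}/{len(outcome)} do not match "
            f"{config.subset_n}/{config.outcome_n}"
        )
    a_subset = sum(1 for v in subset if v is not None)
    a_outcome = sum(1 for v in outcome if v is not None)
    evidence = {
        "answered_subset": a_subset, "answered_outcome": a_outcome,
        "fail_min": (config.subset_fail_min, config.outcome_fail_min),
        "flag_min": (config.subset_flag_min, config.outcome_flag_min),
    }
    if a_subset < config.subset_fail_min or a_outcome < config.outcome_fail_min:
        result = CheckResult(
            "completion_score", FAIL,
            f"answered {a_subset}/{config.subset_n} and {a_outcome}/{config.outcome_n}",
            evidence=evidence,
        )
    elif a_subset < config.subset_flag_min or a_outcome < config.outcome_flag_min:
        result = CheckResult(
            "completion_score", FLAG,
            f"near threshold: {a_subset}/{config.subset_n}, {a_outcome}/{config.outcome_n}",
            evidence=evidence,
        )
    else:
        result = CheckResult("completion_score", PASS, evidence=evidence)
    return result, a_subset, a_outcome


def run_automated_battery(
    dossier: ParticipantDossier,
    registry: Registry,
    geo: LookupTables,
    config: ThresholdConfig,
    audit: AuditLog | None = None,
) -> AutoDecision:
    """Run every automated check on one dossier and assign its single status.

    All check results are audited when an audit log is supplied.  Validation
    errors raised by individual checks are converted to flag-level results and
    carried to the manual stage rather than silently dropped.
    """
    results: list[CheckResult] = []

    def run(fn, *args) -> CheckResult | None:
        try:
            return fn(*args)
        except ValidationError as exc:
            results.append(CheckResult(
                fn_check_ids[fn], FLAG, f"check error: {exc}",
            ))
            return None

    fn_check_ids = {
        recheck_eligibility: "eligibility",
        check_age_consistency: "age_consistency",
        check_completion_time: "completion_time",
        score_completion: "completion_score",
    }

    if not dossier.screening.code_verified:
        results.append(CheckResult("sms_code", FLAG, "phone number never verified"))
    else:
        results.append(CheckResult("sms_code", PASS))

    eligibility = run(recheck_eligibility, dossier, config)
    if eligibility is not None:
        results.append(eligibility)

    probe = canonicalize_dossier(dossier, config)
    matches = registry.find_duplicates(probe, config)
    exact = [m for m in matches if m.kind == EXACT]
    partial = [m for m in matches if m.kind != EXACT]
    if exact:
        results.append(CheckResult(
            "duplicate", FAIL,
            "exact contact match against registry",
            evidence={"matches": [f"{m.field}:{m.other_id}" for m in exact]},
        ))
    elif partial:
        results.append(CheckResult(
            "duplicate", FLAG,
            "partial contact match against registry",
            evidence={"matches": [f"{m.field}:{m.other_id} ({m.detail})" for m in partial]},
        ))
    else:
        results.append(CheckResult("duplicate", PASS))

    results.extend(check_ip_location(
        dossier.screening.ip, dossier.baseline.ip, dossier.contact.state, geo,
    ))

    age = run(
        check_age_consistency,
        dossier.screening.reported_age_years,
        dossier.baseline.dob,
        dossier.baseline.ended_at.date(),
    )
    if age is not None:
        results.append(age)

    time_result = run(
        check_completion_time, dossier.baseline.started_at, dossier.baseline.ended_at, config
    )
    if time_result is not None:
        results.append(time_result)

    try:
        score, _, _ = score_completion(
            dossier.baseline.random_subset_responses,
            dossier.baseline.primary_outcome_responses,
            config,
        )
        results.append(score)
    except ValidationError as exc:
        results.append(CheckResult("completion_score", FLAG, f"check error: {exc}"))

    clustered, members = registry.detect_cluster(probe, config)

    if audit is not None:
        for r in results:
            audit.record(dossier.participant_id, r)

    by_id = {r.check_id: r for r in results}

    # precedence: mutually exclusive status
    if by_id["eligibility"].outcome == FAIL:
        status = STATUS_ELIGIBILITY_FAIL
    elif by_id["duplicate"].outcome == FAIL:
        status = STATUS_DUPLICATE
    elif by_id["ip_country"].outcome == FAIL:
        status = STATUS_IP_FOREIGN
    elif by_id["completion_score"].outcome == FAIL:
        status = STATUS_COMPLETION_FAIL
    elif clustered:
        status = STATUS_CLUSTER_CASE
    else:
        status = STATUS_REFERRED_MANUAL

    flags = [r for r in results if r.outcome == FLAG]
    if clustered and status == STATUS_CLUSTER_CASE and audit is not None:
        audit.record(
            dossier.participant_id,
            CheckResult("duplicate", FLAG, "address cluster", evidence={"members": members}),
        )
    return AutoDecision(dossier.participant_id, status, flags)


def run_battery(
    cohort: Sequence[ParticipantDossier],
    registry: Registry,
    geo: LookupTables,
    config: ThresholdConfig,
    audit: AuditLog | None = None,
) -> list[AutoDecision]:
    """Bulk automated authentication of one batch against a registry snapshot.

    The batch is judged against the registry as it stood when the run started
    (the thrice-weekly bulk model); within-batch duplicates are the manual
    stage's session registry's job.
    """
    return [run_automated_battery(d, registry, geo, config, audit) for d in cohort]
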