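"""Automated battery checks: boundaries, precedence, and the status partition."""

from collections import Counter
from datetime import date, datetime, timedelta, timezone

import pytest

from authsieve.auto_battery import (
    age_in_whole_years,
    check_age_consistency,
    check_completion_time,
    check_ip_location,
    recheck_eligibility,
    run_automated_battery,
    run_battery,
    score_completion,
    verify_sms_code,
)
from authsieve.cohort_model import (
    AUTO_STATUSES,
    FAIL,
    FLAG,
    LookupTables,
    PASS,
    ThresholdConfig,
    ValidationError,
)
from authsieve.synth_cohort import ArchetypeSpec, generate_cohort

CONFIG = ThresholdConfig()
TS = datetime(2018, 6, 1, 12, 0, tzinfo=timezone.utc)


# -- SMS verification -------------------------------------------------------


def test_sms_code_pass_flag_fail():
    assert verify_sms_code("123", "123").outcome == PASS
    log = []
    wrong = verify_sms_code("123", "321", attempt_log=log)
    assert wrong.outcome == FLAG and log[0]["event"] == "support_notified"
    assert verify_sms_code("123", "123", attempt_log=log).outcome == PASS  # later retry
    assert verify_sms_code("123", None).outcome == FAIL
    with pytest.raises(ValidationError):
        verify_sms_code("12a", "123")


# -- eligibility recheck ----------------------------------------------------


def _dossier(**overrides):
    cohort = generate_cohort([ArchetypeSpec("clean", 1)], seed=5)
    dossier = cohort.dossiers[0]
    for key, value in overrides.items():
        obj, attr = key.split("__")
        setattr(getattr(dossier, obj), attr, value)
    return dossier


@pytest.mark.parametrize(
    "overrides, expected",
    [
        ({}, PASS),
        ({"screening__reported_age_years": 19}, FAIL),
        ({"screening__reported_age_years": 12}, FAIL),
        ({"screening__hiv_status": "positive"}, FAIL),
        ({"screening__same_sex_attracted": False}, FAIL),
        ({"screening__gender_identity": "woman"}, FAIL),
        ({"screening__quota_ok": False}, FAIL),
    ],
)
def test_recheck_eligibility(overrides, expected):
    assert recheck_eligibility(_dossier(**overrides), CONFIG).outcome == expected


def test_region_gating_only_when_enabled():
    dossier = _dossier()
    dossier.contact.state = "TX"
    assert recheck_eligibility(dossier, CONFIG).outcome == PASS
    gated = ThresholdConfig(recruitment_states=("GA", "MI", "PA", "NY"))
    assert recheck_eligibility(dossier, gated).outcome == FAIL


# -- age comparison ---------------------------------------------------------


def test_age_whole_years_decrements_before_birthday():
    assert age_in_whole_years(date(2002, 3, 10), date(2018, 6, 1)) == 16
    assert age_in_whole_years(date(2002, 7, 10), date(2018, 6, 1)) == 15
    assert age_in_whole_years(date(2002, 6, 1), date(2018, 6, 1)) == 16  # birthday counts


def test_age_consistency_outcomes():
    assert check_age_consistency(16, date(2002, 3, 10), date(2018, 6, 1)).outcome == PASS
    far_off = check_age_consistency(15, date(1990, 1, 1), date(2018, 6, 1))
    assert far_off.outcome == FLAG and far_off.evidence["computed"] == 28
    future = check_age_consistency(17, date(2018, 6, 15), date(2018, 6, 1))
    assert future.outcome == FLAG and future.evidence.get("explainable") == "future DOB"
    with pytest.raises(ValidationError):
        check_age_consistency(16, date(1800, 1, 1), date(2018, 6, 1))


# -- IP location ------------------------------------------------------------


GEO = LookupTables(geoip={
    "1.1.1.1": ("US", "GA"),
    "2.2.2.2": ("US", "NY"),
    "3.3.3.3": ("CA", "ON"),
})


def _ip_outcomes(screen, baseline, mailing):
    return {r.check_id: r.outcome for r in check_ip_location(screen, baseline, mailing, GEO)}


def test_ip_all_consistent_passes():
    assert _ip_outcomes("1.1.1.1", "1.1.1.1", "GA") == {
        "ip_country": PASS, "ip_state_vs_mailing": PASS, "ip_screen_vs_baseline": PASS,
    }


def test_foreign_baseline_ip_fails_country_only():
    outcomes = _ip_outcomes("3.3.3.3", "3.3.3.3", "GA")
    assert outcomes["ip_country"] == FAIL
    assert outcomes["ip_screen_vs_baseline"] == PASS


def test_state_mismatches_flag():
    assert _ip_outcomes("1.1.1.1", "1.1.1.1", "NY")["ip_state_vs_mailing"] == FLAG
    assert _ip_outcomes("1.1.1.1", "2.2.2.2", "NY")["ip_screen_vs_baseline"] == FLAG


def test_unmapped_ip_flags_never_fails():
    outcomes = _ip_outcomes("9.9.9.9", "9.9.9.9", "GA")
    assert set(outcomes.values()) == {FLAG}


# -- completion time --------------------------------------------------------


@pytest.mark.parametrize(
    "minutes, expected",
    [
        (19 + 59 / 60, FLAG),       # 19 min 59 s: under the gate
        (20.0, PASS),               # exactly 20 min passes (strict inequality)
        (45.0, PASS),
        (72 * 60, PASS),            # exactly 72 h passes
        (73 * 60, FLAG),            # beyond the long-duration bound
    ],
)
def test_completion_time_boundaries(minutes, expected):
    result = check_completion_time(TS, TS + timedelta(minutes=minutes), CONFIG)
    assert result.outcome == expected


def test_negative_duration_is_an_error():
    with pytest.raises(ValidationError):
        check_completion_time(TS, TS - timedelta(minutes=1), CONFIG)


# -- completion scores ------------------------------------------------------


def _responses(answered, total):
    return [3] * answered + [None] * (total - answered)


@pytest.mark.parametrize(
    "a27, a62, expected",
    [
        (16, 62, FAIL),   # below 17/27
        (17, 43, FAIL),   # below 44/62
        (17, 44, FLAG),   # past fail gates but below the 80% band (22/50)
        (21, 62, FLAG),
        (27, 49, FLAG),
        (22, 50, PASS),   # at the 80% band exactly
        (27, 62, PASS),
    ],
)
def test_completion_score_gates(a27, a62, expected):
    result, na, nb = score_completion(_responses(a27, 27), _responses(a62, 62), CONFIG)
    assert (na, nb) == (a27, a62)
    assert result.outcome == expected


def test_completion_score_slot_count_mismatch():
    with pytest.raises(ValidationError):
        score_completion(_responses(26, 26), _responses(62, 62), CONFIG)


# -- battery precedence and partition ---------------------------------------


def test_exact_duplicate_takes_precedence_over_speeder_flag():
    cohort = generate_cohort(
        [ArchetypeSpec("exact_duplicate", 1, (("field", "email"),))], seed=23
    )
    dossier = cohort.dossiers[0]
    dossier.baseline.ended_at = dossier.baseline.started_at + timedelta(minutes=5)
    decision = run_automated_battery(dossier, cohort.registry, cohort.lookups, cohort.config)
    assert decision.status == "duplicate"


def test_clean_record_is_referred_with_zero_flags():
    cohort = generate_cohort([ArchetypeSpec("clean", 10)], seed=31)
    decisions = run_battery(cohort.dossiers, cohort.registry, cohort.lookups, cohort.config)
    assert all(d.status == "referred_manual" and d.flags_carried == [] for d in decisions)


def test_battery_is_deterministic_and_partitions_the_cohort(default_cohort):
    cohort = default_cohort
    first = run_battery(cohort.dossiers, cohort.registry, cohort.lookups, cohort.config)
    second = run_battery(cohort.dossiers, cohort.registry, cohort.lookups, cohort.config)
    assert [(d.participant_id, d.status) for d in first] == [
        (d.participant_id, d.status) for d in second
    ]
    counts = Counter(d.status for d in first)
    assert sum(counts.values()) == len(cohort.dossiers)
    assert set(counts) <= set(AUTO_STATUSES)


def test_each_archetype_yields_its_intended_status():
    """Sensitivity: each planted anomaly lands on its Table-1 status; truth
    labels are recovered exactly."""
    mix = [
        ArchetypeSpec("clean", 5),
        ArchetypeSpec("underage", 2),
        ArchetypeSpec("overage", 2),
        ArchetypeSpec("not_same_sex_attracted", 2),
        ArchetypeSpec("hiv_positive", 2),
        ArchetypeSpec("quota_fail", 2),
        ArchetypeSpec("exact_duplicate", 6),
        ArchetypeSpec("foreign_ip", 2),
        ArchetypeSpec("low_completion_subset", 2),
        ArchetypeSpec("low_completion_outcome", 2),
        ArchetypeSpec("wisteria_cluster", 4),
        ArchetypeSpec("speeder", 2),
        ArchetypeSpec("state_mismatch_ip", 2),
    ]
    cohort = generate_cohort(mix, seed=41)
    decisions = run_battery(cohort.dossiers, cohort.registry, cohort.lookups, cohort.config)
    for decision in decisions:
        assert decision.status == cohort.truth[decision.participant_id].expected_status
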