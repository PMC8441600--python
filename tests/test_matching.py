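"""Canonicalization, exact/partial matching, and registry duplicate search."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from authsieve.cohort_model import ThresholdConfig, ValidationError
from authsieve.matching import (
    EXACT,
    PARTIAL,
    Registry,
    canonicalize_dossier,
    canonicalize_email,
    canonicalize_name,
    canonicalize_phone,
    detect_cluster,
    find_duplicates,
    match_contacts,
    match_field,
    parse_address,
    partial_match_address,
)
from authsieve.synth_cohort import ArchetypeSpec, generate_cohort

CONFIG = ThresholdConfig()


@pytest.mark.parametrize(
    "raw, expected",
    [
        (" A.B+x@Mail.COM ", "a.b@mail.com"),
        ("a@b.com", "a@b.com"),
        ("Tagless+promo+x@Example.org", "tagless@example.org"),
    ],
)
def test_canonicalize_email(raw, expected):
    assert canonicalize_email(raw, CONFIG) == expected


def test_canonicalize_email_rejects_malformed():
    for bad in ("no-at-sign", "two@@ats", "a@b@c"):
        with pytest.raises(ValidationError):
            canonicalize_email(bad, CONFIG)


def test_canonicalize_email_keeps_plus_tag_when_disabled():
    config = ThresholdConfig(strip_plus_tags=False)
    assert canonicalize_email("a+b@x.com", config) == "a+b@x.com"


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("(404) 555-0123", "4045550123"),
        ("+1 404 555 0123", "4045550123"),
        ("1-404-555-0123", "4045550123"),
    ],
)
def test_canonicalize_phone(raw, expected):
    assert canonicalize_phone(raw) == expected


def test_canonicalize_phone_rejects_wrong_length():
    for bad in ("55501", "404555012345"):
        with pytest.raises(ValidationError):
            canonicalize_phone(bad)


def test_canonicalize_name_examples():
    assert canonicalize_name("  J.  Doe ") == "j doe"
    assert canonicalize_name("JDOE") == canonicalize_name("jdoe")
    assert canonicalize_name("") == ""


@given(st.text(max_size=40))
@settings(derandomize=True, max_examples=200)
def test_name_canonicalization_idempotent(raw):
    once = canonicalize_name(raw)
    assert canonicalize_name(once) == once


@given(st.emails())
@settings(derandomize=True, max_examples=200)
def test_email_canonicalization_idempotent(raw):
    try:
        once = canonicalize_email(raw, CONFIG)
    except ValidationError:
        return
    assert canonicalize_email(once, CONFIG) == once


def test_street_suffix_normalization():
    a = parse_address("12", "Wisteria St", "Springfield", "GA", "30301")
    b = parse_address("12", "Wisteria Street", "Springfield", "GA", "30301")
    assert a.street_key == "wisteria street"
    assert a == b


def test_partial_match_address_cases():
    a = parse_address("12", "Wisteria Street", "Springfield", "GA", "30301")
    b = parse_address("14", "Wisteria St", "Springfield", "GA", "30301")
    c = parse_address("12", "Maple Street", "Springfield", "GA", "30301")
    assert partial_match_address(a, b) == "partial_street"  # only house differs
    assert partial_match_address(a, a) == "exact"
    assert partial_match_address(a, c) == "none"  # same city/zip, other street


def test_match_field_rules():
    m = match_field("jdoe1@x.com", "jdoe2@x.com", "email", CONFIG)
    assert m is not None and m.kind == PARTIAL and m.similarity < 1
    assert match_field("4045550123", "4045550124", "phone", CONFIG) is None
    m = match_field("handlex", "handlex", "handle", CONFIG)
    assert m is not None and m.kind == EXACT and m.similarity == 1.0
    assert match_field("", "", "name", CONFIG) is None  # empty keys never match
    # cross-domain one-edit emails do not partially match
    assert match_field("jdoe@x.com", "jdoe@y.com", "email", CONFIG) is None


_KEYS = st.text(alphabet="abcdef@.", min_size=0, max_size=12)


@given(_KEYS, _KEYS, st.sampled_from(["name", "email", "phone", "ip", "handle"]))
@settings(derandomize=True, max_examples=300)
def test_match_field_is_symmetric(a, b, field):
    ma = match_field(a, b, field, CONFIG)
    mb = match_field(b, a, field, CONFIG)
    assert (ma is None) == (mb is None)
    if ma is not None:
        assert (ma.kind, ma.similarity) == (mb.kind, mb.similarity)


def _brute_force(probe, registry, config):
    """Quadratic all-pairs oracle: compare the probe against every registry
    entry directly, with no blocking or indexing."""
    out = []
    for entry in registry:
        out.extend(match_contacts(probe, entry, config))
    return out


def test_find_duplicates_equals_brute_force_on_random_cohort():
    """Indexed registry search returns exactly the all-pairs match set on a
    500-record cohort carrying planted exact and partial duplicates."""
    cohort = generate_cohort(
        [
            ArchetypeSpec("clean", 450),
            ArchetypeSpec("exact_duplicate", 30),
            ArchetypeSpec("partial_duplicate", 20),
        ],
        seed=97,
    )
    total = 0
    for dossier in cohort.dossiers:
        probe = canonicalize_dossier(dossier, cohort.config)
        fast = find_duplicates(probe, cohort.registry, cohort.config)
        slow = _brute_force(probe, cohort.registry, cohort.config)
        assert sorted(fast, key=repr) == sorted(slow, key=repr)
        total += len(fast)
    assert total >= 50  # every planted duplicate produced at least one match


def test_similarity_bounds_partition_exact_and_partial(default_cohort):
    for dossier in default_cohort.dossiers[:300]:
        for m in find_duplicates(dossier, default_cohort.registry, default_cohort.config):
            if m.kind == EXACT:
                assert m.similarity == 1.0
            else:
                assert m.similarity < 1.0


def test_detect_cluster_threshold_behaviour():
    reg = Registry()
    make = lambda pid, house: canonicalize_dossier(
        _address_dossier(pid, house), CONFIG
    )
    probe = make("X", "99")
    reg.add(make("A", "1"))
    reg.add(make("B", "2"))
    hit, members = detect_cluster(probe, reg, CONFIG)
    assert not hit and members == ["A", "B"]  # below the default threshold of 3
    reg.add(make("C", "3"))
    hit, members = detect_cluster(probe, reg, CONFIG)
    assert hit and members == ["A", "B", "C"]
    # degenerate config: any partial-street match clusters
    hit, _ = detect_cluster(probe, Registry([make("A", "1")]),
                            ThresholdConfig(cluster_min_size=1))
    assert hit


def _address_dossier(pid, house):
    from authsieve.cohort_model import (
        BaselineRecord, ContactRecord, ParticipantDossier, ScreeningRecord,
    )
    from datetime import date, datetime, timezone

    ts = datetime(2018, 6, 1, tzinfo=timezone.utc)
    contact = ContactRecord(
        participant_id=pid, preferred_name=f"name {pid}", email=f"{pid.lower()}@x.com",
        phone_primary="404555" + f"{sum(ord(ch) for ch in pid) % 10000:04d}",
        house_number=house, street="Wisteria Street", city="Springfield",
        state="GA", zip="30301", submitted_at=ts,
    )
    screening = ScreeningRecord(
        screener_id=pid, reported_age_years=16, sex_assigned_at_birth="male",
        gender_identity="man", same_sex_attracted=True, hiv_status="negative",
        zip="30301", ip="10.0.0.1", started_at=ts, ended_at=ts,
    )
    baseline = BaselineRecord(
        participant_id=pid, dob=date(2002, 1, 1), ip="10.0.0.1",
        started_at=ts, ended_at=ts,
        random_subset_responses=[3] * 27, primary_outcome_responses=[3] * 62,
    )
    return ParticipantDossier(contact, screening, baseline)


def test_cross_slot_phone_match():
    """A new primary phone equal to an enrolled participant's secondary
    phone is an exact phone match."""
    enrolled = _address_dossier("E", "1")
    enrolled.contact.phone_alts = ["404-555-9999"]
    probe = _address_dossier("N", "50")
    probe.contact.street = "Maple Road"
    probe.contact.phone_primary = "(404) 555-9999"
    reg = Registry([canonicalize_dossier(enrolled, CONFIG)])
    matches = find_duplicates(probe, reg, CONFIG)
    assert any(m.field == "phone" and m.kind == EXACT and m.other_id == "E" for m in matches)


def test_empty_registry_means_unique():
    probe = _address_dossier("N", "5")
    assert find_duplicates(probe, Registry(), CONFIG) == []
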