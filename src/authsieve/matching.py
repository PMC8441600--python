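"""Contact canonicalization and exact/partial duplicate detection.

Every new enrollment attempt is compared against a registry of prior attempts
and currently enrolled participants across six field families: preferred name,
email, phone numbers (primary and alternates, cross-slot), mailing address,
social-media handles and IP addresses.  Names and emails admit partial matches
within a small edit-distance budget; phones, IPs and handles match exact-only;
addresses admit the partial-street match (same street/city/state/zip, different
house number) that underpins cluster detection.

Matching is deterministic and auditable: canonicalizers are idempotent, the
street-suffix synonym table is fixed, and the indexed lookup used here is
required (and tested) to agree with a quadratic all-pairs comparison.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import pandas as pd

from .cohort_model import (
    ContactRecord,
    ParticipantDossier,
    ThresholdConfig,
    ValidationError,
)

EXACT = "exact"
PARTIAL = "partial"

MATCH_FIELDS = ("email", "phone", "ip", "address", "handle", "name")

# fixed street-suffix synonym table; the final street token is normalised to
# the long form so "Wisteria St" and "Wisteria Street" share one key
STREET_SUFFIXES = {
    "st": "street", "street": "street",
    "rd": "road", "road": "road",
    "ave": "avenue", "avenue": "avenue",
    "blvd": "boulevard", "boulevard": "boulevard",
    "ln": "lane", "lane": "lane",
    "dr": "drive", "drive": "drive",
    "ct": "court", "court": "court",
}

_PUNCT_RE = re.compile(r"[^\w\s]")
_WS_RE = re.compile(r"\s+")


def edit_distance(a: str, b: str) -> int:
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


# ---------------------------------------------------------------------------
# canonicalizers (all idempotent)
# ---------------------------------------------------------------------------


def canonicalize_email(raw: str, config: ThresholdConfig | None = None) -> str:
    """Lowercase/trim an email; optionally strip a ``+tag`` from the local part."""
    strip_plus = True if config is None else config.strip_plus_tags
    email = raw.strip().lower()
    if email.count("@") != 1:
        raise ValidationError(f"malformed email {raw!r}: expected exactly one '@'")
    local, domain = email.split("@")
    if not local or not domain or " " in email:
        raise ValidationError(f"malformed email {raw!r}")
    if strip_plus:
        local = local.split("+", 1)[0]
    return f"{local}@{domain}"


def canonicalize_phone(raw: str) -> str:
    """Reduce a raw phone string to its canonical 10-digit key."""
    if not raw:
        raise ValidationError("empty phone")
    digits = re.sub(r"\D", "", raw)
    if len(digits) == 11 and digits.startswith("1"):
        digits = digits[1:]
    if len(digits) != 10:
        raise ValidationError(f"phone {raw!r}: canonical form has {len(digits)} digits, want 10")
    return digits


def canonicalize_name(raw: str) -> str:
    """Lowercase, strip punctuation and collapse whitespace.

    An empty key is allowed and never participates in matching.
    """
    return _WS_RE.sub(" ", _PUNCT_RE.sub(" ", raw.lower())).strip()


def _street_key(street: str) -> str:
    key = canonicalize_name(street)
    tokens = key.split()
    if tokens and tokens[-1] in STREET_SUFFIXES:
        tokens[-1] = STREET_SUFFIXES[tokens[-1]]
    return " ".join(tokens)


@dataclass(frozen=True)
class AddressKey:
    house_number: str
    street_key: str
    city_key: str
    state: str
    zip: str

    @property
    def street_group(self) -> tuple[str, str, str, str]:
        """Blocking key shared by all houses on one street."""
        return (self.street_key, self.city_key, self.state, self.zip)


def parse_address(house_number: str, street: str, city: str, state: str, zip_code: str) -> AddressKey:
    return AddressKey(
        house_number=house_number.strip().lower(),
        street_key=_street_key(street),
        city_key=canonicalize_name(city),
        state=state.strip().upper(),
        zip=zip_code.strip(),
    )


NONE = "none"
PARTIAL_STREET = "partial_street"


def partial_match_address(a: AddressKey, b: AddressKey) -> str:
    """``exact`` iff all five components equal; ``partial_street`` iff only the
    house number differs (same street, city, state, zip); else ``none``."""
    if not a.street_key or not b.street_key:
        return NONE
    if a == b:
        return EXACT
    if a.street_group == b.street_group and a.house_number != b.house_number:
        return PARTIAL_STREET
    return NONE


# ---------------------------------------------------------------------------
# canonical contacts and match results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CanonicalContact:
    participant_id: str
    name_key: str
    email_key: str
    phone_keys: frozenset[str]
    address_key: AddressKey | None
    handle_keys: frozenset[tuple[str, str]]
    ip_keys: frozenset[str]


def canonicalize_contact(
    contact: ContactRecord,
    ips: Iterable[str] = (),
    config: ThresholdConfig | None = None,
) -> CanonicalContact:
    phones = set()
    for raw in [contact.phone_primary, *contact.phone_alts]:
        if raw:
            phones.add(canonicalize_phone(raw))
    address = None
    if contact.street:
        address = parse_address(
            contact.house_number, contact.street, contact.city, contact.state, contact.zip
        )
    return CanonicalContact(
        participant_id=contact.participant_id,
        name_key=canonicalize_name(contact.preferred_name),
        email_key=canonicalize_email(contact.email, config) if contact.email else "",
        phone_keys=frozenset(phones),
        address_key=address,
        handle_keys=frozenset(
            (platform.lower(), handle.lower())
            for platform, handle in contact.social_handles.items()
            if handle
        ),
        ip_keys=frozenset(ip for ip in ips if ip),
    )


def canonicalize_dossier(
    dossier: ParticipantDossier, config: ThresholdConfig | None = None
) -> CanonicalContact:
    return canonicalize_contact(
        dossier.contact,
        ips=(dossier.screening.ip, dossier.baseline.ip),
        config=config,
    )


@dataclass(frozen=True)
class MatchResult:
    kind: str  # exact | partial
    field: str  # email | phone | ip | address | handle | name
    other_id: str
    similarity: float
    detail: str = ""

    def __post_init__(self) -> None:
        if self.kind == EXACT and self.similarity != 1.0:
            raise ValidationError("exact match must have similarity 1")
        if self.kind == PARTIAL and not self.similarity < 1.0:
            raise ValidationError("partial match must have similarity < 1")


def _string_similarity(a: str, b: str, dist: int) -> float:
    return 1.0 - dist / max(len(a), len(b), 1)


def match_field(
    a: str, b: str, field_name: str, config: ThresholdConfig, other_id: str = ""
) -> MatchResult | None:
    """Compare two canonical keys of one field family.

    Equality is an exact match for every family.  Names and emails additionally
    admit a partial match within the configured edit budget (emails: same
    domain, edits confined to the local part).  Empty keys never match.
    Symmetric in its two key arguments.
    """
    if not a or not b:
        return None
    if a == b:
        return MatchResult(EXACT, field_name, other_id, 1.0)
    if field_name == "name":
        dist = edit_distance(a, b)
        if dist <= config.name_edit_max:
            return MatchResult(
                PARTIAL, field_name, other_id, _string_similarity(a, b, dist),
                detail=f"name within {dist} edit(s)",
            )
    elif field_name == "email":
        la, _, da = a.partition("@")
        lb, _, db = b.partition("@")
        if da == db:
            dist = edit_distance(la, lb)
            if dist <= config.email_edit_max:
                return MatchResult(
                    PARTIAL, field_name, other_id, _string_similarity(a, b, dist),
                    detail=f"same domain, local part within {dist} edit(s)",
                )
    return None


_ADDRESS_PARTIAL_SIMILARITY = 0.8  # 4 of 5 address components equal


def match_contacts(
    a: CanonicalContact, b: CanonicalContact, config: ThresholdConfig
) -> list[MatchResult]:
    """All exact and partial matches between two canonical contacts.

    This is the quadratic-oracle building block: `find_duplicates` against any
    registry must equal the union of `match_contacts` over all registry entries.
    """
    out: list[MatchResult] = []
    m = match_field(a.name_key, b.name_key, "name", config, b.participant_id)
    if m:
        out.append(m)
    m = match_field(a.email_key, b.email_key, "email", config, b.participant_id)
    if m:
        out.append(m)
    for phone in sorted(a.phone_keys & b.phone_keys):
        out.append(MatchResult(EXACT, "phone", b.participant_id, 1.0, detail=phone))
    for ip in sorted(a.ip_keys & b.ip_keys):
        out.append(MatchResult(EXACT, "ip", b.participant_id, 1.0, detail=ip))
    for platform, handle in sorted(a.handle_keys & b.handle_keys):
        out.append(MatchResult(EXACT, "handle", b.participant_id, 1.0, detail=f"{platform}:{handle}"))
    if a.address_key and b.address_key:
        verdict = partial_match_address(a.address_key, b.address_key)
        if verdict == EXACT:
            out.append(MatchResult(EXACT, "address", b.participant_id, 1.0))
        elif verdict == PARTIAL_STREET:
            out.append(
                MatchResult(
                    PARTIAL, "address", b.participant_id, _ADDRESS_PARTIAL_SIMILARITY,
                    detail="same street, different house number",
                )
            )
    return out


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

FULL_SCAN_LIMIT = 10_000


class Registry:
    """Canonical contacts of everyone already evaluated for enrollment.

    Both enrolled participants and prior (failed) attempts are kept: either
    blocks re-entry.  Lookups are index-backed (exact keys hashed; partial
    emails blocked by domain, partial addresses by street group) with a plain
    scan for partial names while the registry is small; above
    ``FULL_SCAN_LIMIT`` entries name partials block on key length.
    """

    def __init__(self, entries: Iterable[CanonicalContact] = ()):
        self._entries: dict[str, CanonicalContact] = {}
        self._by_email: dict[str, set[str]] = {}
        self._by_domain: dict[str, set[str]] = {}
        self._by_phone: dict[str, set[str]] = {}
        self._by_ip: dict[str, set[str]] = {}
        self._by_handle: dict[tuple[str, str], set[str]] = {}
        self._by_street: dict[tuple, set[str]] = {}
        self._by_name: dict[str, set[str]] = {}
        for e in entries:
            self.add(e)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, participant_id: str) -> bool:
        return participant_id in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def add(self, entry: CanonicalContact) -> None:
        if entry.participant_id in self._entries:
            raise ValidationError(f"registry: duplicate id {entry.participant_id}")
        self._entries[entry.participant_id] = entry
        pid = entry.participant_id
        if entry.email_key:
            self._by_email.setdefault(entry.email_key, set()).add(pid)
            self._by_domain.setdefault(entry.email_key.partition("@")[2], set()).add(pid)
        for phone in entry.phone_keys:
            self._by_phone.setdefault(phone, set()).add(pid)
        for ip in entry.ip_keys:
            self._by_ip.setdefault(ip, set()).add(pid)
        for hk in entry.handle_keys:
            self._by_handle.setdefault(hk, set()).add(pid)
        if entry.address_key:
            self._by_street.setdefault(entry.address_key.street_group, set()).add(pid)
        if entry.name_key:
            self._by_name.setdefault(entry.name_key, set()).add(pid)

    def get(self, participant_id: str) -> CanonicalContact:
        return self._entries[participant_id]

    # -- candidate generation ------------------------------------------------

    def _candidates(self, probe: CanonicalContact, config: ThresholdConfig) -> set[str]:
        ids: set[str] = set()
        if probe.email_key:
            ids |= self._by_email.get(probe.email_key, set())
            ids |= self._by_domain.get(probe.email_key.partition("@")[2], set())
        for phone in probe.phone_keys:
            ids |= self._by_phone.get(phone, set())
        for ip in probe.ip_keys:
            ids |= self._by_ip.get(ip, set())
        for hk in probe.handle_keys:
            ids |= self._by_handle.get(hk, set())
        if probe.address_key:
            ids |= self._by_street.get(probe.address_key.street_group, set())
        if probe.name_key:
            if len(self) < FULL_SCAN_LIMIT:
                budget = config.name_edit_max
                for name, holders in self._by_name.items():
                    if abs(len(name) - len(probe.name_key)) <= budget and (
                        name == probe.name_key
                        or edit_distance(name, probe.name_key) <= budget
                    ):
                        ids |= holders
            else:
                ids |= self._by_name.get(probe.name_key, set())
        ids.discard(probe.participant_id)
        return ids

    def find_duplicates(
        self, probe: CanonicalContact, config: ThresholdConfig
    ) -> list[MatchResult]:
        out: list[MatchResult] = []
        for pid in sorted(self._candidates(probe, config)):
            out.extend(match_contacts(probe, self._entries[pid], config))
        return out

    def detect_cluster(
        self, probe: CanonicalContact, config: ThresholdConfig
    ) -> tuple[bool, list[str]]:
        """True iff >= ``cluster_min_size`` registry addresses partial-street
        match the probe's address (same street, different house number)."""
        if probe.address_key is None:
            return False, []
        members = sorted(
            pid
            for pid in self._by_street.get(probe.address_key.street_group, set())
            if pid != probe.participant_id
            and partial_match_address(probe.address_key, self._entries[pid].address_key)
            == PARTIAL_STREET
        )
        return len(members) >= config.cluster_min_size, members

    # -- persistence ---------------------------------------------------------

    _COLUMNS = [
        "participant_id", "name_key", "email_key", "phone_keys", "house_number",
        "street_key", "city_key", "state", "zip", "handle_keys", "ip_keys",
    ]

    def save(self, path) -> None:
        rows = []
        for e in sorted(self._entries.values(), key=lambda e: e.participant_id):
            ak = e.address_key
            rows.append({
                "participant_id": e.participant_id,
                "name_key": e.name_key,
                "email_key": e.email_key,
                "phone_keys": ";".join(sorted(e.phone_keys)),
                "house_number": ak.house_number if ak else "",
                "street_key": ak.street_key if ak else "",
                "city_key": ak.city_key if ak else "",
                "state": ak.state if ak else "",
                "zip": ak.zip if ak else "",
                "handle_keys": ";".join(f"{p}:{h}" for p, h in sorted(e.handle_keys)),
                "ip_keys": ";".join(sorted(e.ip_keys)),
            })
        pd.DataFrame(rows, columns=self._COLUMNS).to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "Registry":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        reg = cls()
        for row in frame.to_dict("records"):
            address = None
            if row["street_key"]:
                address = AddressKey(
                    row["house_number"], row["street_key"], row["city_key"],
                    row["state"], row["zip"],
                )
            handles = frozenset(
                tuple(part.split(":", 1)) for part in row["handle_keys"].split(";") if part
            )
            reg.add(CanonicalContact(
                participant_id=row["participant_id"],
                name_key=row["name_key"],
                email_key=row["email_key"],
                phone_keys=frozenset(p for p in row["phone_keys"].split(";") if p),
                address_key=address,
                handle_keys=handles,
                ip_keys=frozenset(p for p in row["ip_keys"].split(";") if p),
            ))
        return reg


def _as_canonical(record, config: ThresholdConfig) -> CanonicalContact:
    if isinstance(record, CanonicalContact):
        return record
    if isinstance(record, ParticipantDossier):
        return canonicalize_dossier(record, config)
    if isinstance(record, ContactRecord):
        return canonicalize_contact(record, config=config)
    raise TypeError(f"cannot canonicalize {type(record).__name__}")


def _as_registry(registry) -> Registry:
    return registry if isinstance(registry, Registry) else Registry(registry)


def find_duplicates(record, registry, config: ThresholdConfig) -> list[MatchResult]:
    """All exact and partial matches of one attempt against the registry.

    Phone comparisons are cross-slot: a new primary number matching a registry
    entry's alternate number (or vice versa) is an exact phone match.  An empty
    result means the attempt is unique.
    """
    return _as_registry(registry).find_duplicates(_as_canonical(record, config), config)


def detect_cluster(record, registry, config: ThresholdConfig) -> tuple[bool, list[str]]:
    return _as_registry(registry).detect_cluster(_as_canonical(record, config), config)
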