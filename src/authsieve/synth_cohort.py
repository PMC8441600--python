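"""Seeded generator of synthetic enrollment cohorts with planted anomalies.

Each generated record belongs to exactly one labeled archetype: either
``clean`` (satisfies every automated and manual check) or an anomaly class
that violates exactly the check it is named for.  The default archetype mix
reproduces the study's enrollment composition at desk scale: 1224
baseline-starting dossiers that the automated battery partitions into
32 eligibility failures (30 quota + 2 HIV-positive), 177 exact duplicates
against the registry, 8 foreign-IP records, 252 completion-score failures,
23 street-cluster attempts, and 732 referrals to manual review; the manual
stage then resolves those 732 into 9 within-batch duplicates (no checklist),
123 checklist failures (reason tallies 33 time stamp / 20 age / 28 duplicate /
33 pattern / 20 social, overlapping), and 600 enrollments.

All identities are drawn from deterministic word lists keyed by the seed; no
real personal data is ever produced.  Identifier codes carry a check digit so
that distinct synthetic names and emails are always at least two edits apart —
partial (one-edit) matches occur only where an archetype plants them.  The
generator also emits the matching lookup tables (every IP geolocated as its
archetype requires; every address gazetteered with its own zip), a registry of
prior attempts and enrolled participants, per-case manual-review evidence, and
a truth table mapping each participant to its archetype and expected outcome —
the truth table is never read by the pipeline itself.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .auto_battery import age_in_whole_years
from .cohort_model import (
    BaselineRecord,
    ContactRecord,
    LookupTables,
    ParticipantDossier,
    ScreeningRecord,
    STATUS_CLUSTER_CASE,
    STATUS_COMPLETION_FAIL,
    STATUS_DUPLICATE,
    STATUS_ELIGIBILITY_FAIL,
    STATUS_IP_FOREIGN,
    STATUS_REFERRED_MANUAL,
    ThresholdConfig,
    ValidationError,
    write_cohort,
)
from .manual_review import (
    ENROLLED,
    FAILED_CHECKLIST,
    FAILED_DUPLICATE_NO_CHECKLIST,
    ITEM_AGE,
    ITEM_DUPLICATE,
    ITEM_TIME,
    ITEM_ZIP,
    RESOLVED_EXPLAINABLE,
    ManualEvidence,
    SocialEvidence,
    write_manual_evidence,
)
from .matching import Registry, canonicalize_contact
from .pattern_detect import ConflictRule
from .report import FunnelCounts

ARCHETYPES = (
    "clean",
    "underage",
    "overage",
    "not_same_sex_attracted",
    "hiv_positive",
    "quota_fail",
    "exact_duplicate",
    "partial_duplicate",
    "foreign_ip",
    "state_mismatch_ip",
    "speeder",
    "slow_outlier",
    "low_completion_subset",
    "low_completion_outcome",
    "flag_band_completion",
    "age_inconsistent",
    "straightliner",
    "zigzagger",
    "conflicted",
    "wisteria_cluster",
    "social_contradicted",
    "email_nonresponder",
)


@dataclass(frozen=True)
class ArchetypeSpec:
    archetype: str
    count: int
    params: tuple = ()  # (key, value) pairs; tuple keeps the spec hashable

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValidationError(f"unknown archetype {self.archetype!r}")
        if self.count < 0:
            raise ValidationError("archetype count must be nonnegative")

    @property
    def param_map(self) -> dict:
        return dict(self.params)


@dataclass(frozen=True)
class TruthLabel:
    archetype: str
    variant: str
    expected_status: str
    expected_disposition: str | None


@dataclass
class SyntheticCohort:
    dossiers: list[ParticipantDossier]
    truth: dict[str, TruthLabel]
    lookups: LookupTables
    registry: Registry
    manual_evidence: dict[str, ManualEvidence]
    funnel_counts: FunnelCounts
    conflict_rules: list[ConflictRule]
    config: ThresholdConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = write_cohort(self.dossiers, self.lookups, out, self.config)
        paths["registry"] = out / "registry.csv"
        self.registry.save(paths["registry"])
        paths["truth"] = out / "truth.csv"
        pd.DataFrame(
            [
                {
                    "participant_id": pid,
                    "archetype": t.archetype,
                    "variant": t.variant,
                    "expected_status": t.expected_status,
                    "expected_disposition": t.expected_disposition or "",
                }
                for pid, t in sorted(self.truth.items())
            ],
            columns=["participant_id", "archetype", "variant",
                     "expected_status", "expected_disposition"],
        ).to_csv(paths["truth"], index=False)
        paths["manual_evidence"] = out / "manual_evidence.csv"
        write_manual_evidence(self.manual_evidence, paths["manual_evidence"])
        paths["rules"] = out / "rules.yaml"
        paths["rules"].write_text(yaml.safe_dump([
            {"kind": r.kind, "item_a": r.item_a, "item_b": r.item_b, "param": r.param}
            for r in self.conflict_rules
        ]))
        paths["config"] = out / "config.yaml"
        self.config.to_yaml(paths["config"])
        paths["funnel"] = out / "funnel.json"
        paths["funnel"].write_text(json.dumps(
            {stage: getattr(self.funnel_counts, stage) for stage in FunnelCounts.STAGES},
            indent=2,
        ))
        return paths


# ---------------------------------------------------------------------------
# deterministic word lists (synthetic identities only)
# ---------------------------------------------------------------------------

FIRST_NAMES = (
    "alden barrett casey devon ellis flynn gray harper indigo jules kendall "
    "lane morgan noel oakley parker quinn reese sage taylor urban vesper "
    "wren avery blair corey drew emory frankie greer hollis jamie kerry "
    "logan marley nicky onyx peyton river skyler tatum"
).split()

LAST_NAMES = (
    "ashford bellamy colfax dunmore ellery fairbanks goodwin hale iverson "
    "jennings kessler lockwood merritt norwood ottley prescott quimby "
    "ramsden sheffield thatcher underhill vance whitfield yates abernathy "
    "blackwood crowley davenport easton fenwick gardner holloway ingram "
    "jarvis kingsley larkspur moreland newberry ogden pembroke"
).split()

STREET_NAMES = (
    "maple oak cedar birch elm willow aspen juniper magnolia laurel holly "
    "cypress sycamore chestnut poplar hawthorn dogwood linden alder spruce "
    "hickory walnut mulberry catalpa hemlock beech sequoia redwood cottonwood "
    "buckeye ironwood tamarack basswood boxelder hornbeam sassafras sumac "
    "viburnum winterberry yellowwood"
).split()

EMAIL_DOMAINS = (
    "example.com", "mail.example.org", "inbox.example.net",
    "post.example.info", "web.example.co",
)

# recruitment region: state -> cities
REGION = {
    "GA": ("atlanta", "savannah", "macon"),
    "MI": ("detroit", "lansing", "flint"),
    "PA": ("philadelphia", "pittsburgh", "erie"),
    "NY": ("albany", "buffalo", "rochester"),
}
CITIES = tuple((city, state) for state, cities in REGION.items() for city in cities)
STATES = tuple(REGION)
FOREIGN_LOCATION = ("CA", "ON")  # Ontario, Canada

WISTERIA_STREET = "Wisteria Street"
WISTERIA_CITY, WISTERIA_STATE = "springfield", "GA"

_BASE_DAY = datetime(2018, 4, 2, 14, 0, tzinfo=timezone.utc)


def default_conflict_rules() -> list[ConflictRule]:
    """Near-duplicate item pairs that honest responses keep within one scale
    point; a spread wider than 3 is logged as a conflicting answer."""
    return [
        ConflictRule("max_abs_difference", "po_10", "po_11", 3),
        ConflictRule("max_abs_difference", "po_30", "po_31", 3),
        ConflictRule("max_abs_difference", "po_50", "po_51", 3),
    ]


_RULE_ECHO_ITEMS = {("po_10", "po_11"), ("po_30", "po_31"), ("po_50", "po_51")}


def default_funnel_counts() -> FunnelCounts:
    return FunnelCounts(
        visitors=19709, screened=13931, eligible=3253, consented=2544,
        contact_verified=1324, started_baseline=1224, referred_manual=732,
        enrolled=600,
    )


def default_archetype_specs() -> list[ArchetypeSpec]:
    """The default mix reproducing the study's enrollment composition."""
    return [
        # automated-stage exclusions (492)
        ArchetypeSpec("quota_fail", 30),
        ArchetypeSpec("hiv_positive", 2),
        ArchetypeSpec("exact_duplicate", 177),
        ArchetypeSpec("foreign_ip", 8),
        ArchetypeSpec("low_completion_subset", 126),
        ArchetypeSpec("low_completion_outcome", 126),
        ArchetypeSpec("wisteria_cluster", 23),
        # manual-stage: enrolled (600)
        ArchetypeSpec("clean", 540),
        ArchetypeSpec("state_mismatch_ip", 30, (("resolution", "explainable"),)),
        ArchetypeSpec("slow_outlier", 30, (("resolution", "explainable"),)),
        # manual-stage: no-checklist duplicates (9)
        ArchetypeSpec("exact_duplicate", 9, (("stage", "manual"),)),
        # manual-stage: checklist failures (123; reasons overlap)
        ArchetypeSpec("speeder", 25),
        ArchetypeSpec("slow_outlier", 3, (("resolution", "fail"),)),
        ArchetypeSpec("speeder", 5, (("second", "straightliner"),)),
        ArchetypeSpec("age_inconsistent", 17),
        ArchetypeSpec("age_inconsistent", 3, (("second", "partial_duplicate"),)),
        ArchetypeSpec("partial_duplicate", 22),
        ArchetypeSpec("partial_duplicate", 3, (("second", "social_contradicted"),)),
        ArchetypeSpec("straightliner", 14),
        ArchetypeSpec("zigzagger", 8),
        ArchetypeSpec("conflicted", 6),
        ArchetypeSpec("social_contradicted", 17),
    ]


# ---------------------------------------------------------------------------
# generator internals
# ---------------------------------------------------------------------------


def _code(v: int) -> str:
    """Zero-padded id code with a mod-10 digit-sum check digit, so two distinct
    codes always differ in at least two positions (edit distance >= 2)."""
    s = f"{v % 100000:05d}"
    return s + str(sum(int(c) for c in s) % 10)


class _Mint:
    """Allocates globally unique synthetic identities and locations.

    A seed-derived offset shifts every serial so that different seeds produce
    different names, emails, phones and IPs while uniqueness within one run is
    preserved."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self._offset = rng.randrange(50_000)
        self._ip_offset = rng.randrange(1 << 20)
        self._serial = 0
        self._ip_serial = 0
        self._zip_serial = 0
        self._zips: dict[tuple[str, str], str] = {}
        self.geoip: dict[str, tuple[str, str]] = {}
        self.gazetteer: dict[tuple[str, str], str] = {}
        self.zip_index: dict[str, tuple[str, str]] = {}

    def identity(self) -> dict:
        v = self._offset + self._serial
        digits7 = f"{(1_000_000 + self._offset * 37 + self._serial) % 10_000_000:07d}"
        self._serial += 1
        code = _code(v)
        first = FIRST_NAMES[v % len(FIRST_NAMES)]
        last = LAST_NAMES[(v // len(FIRST_NAMES)) % len(LAST_NAMES)]
        return {
            "name": f"{first.capitalize()} {last.capitalize()}-{code}",
            "email": f"{first}.{last}{code}@{EMAIL_DOMAINS[v % len(EMAIL_DOMAINS)]}",
            "phone": f"404{digits7}",
            "alt_phone": f"678{digits7}",
            "handle": f"user_{code}",
            "house": str(100 + v),
        }

    def ip(self, country: str, state: str) -> str:
        i = (self._ip_offset + self._ip_serial) & 0xFFFFFF
        self._ip_serial += 1
        addr = f"10.{(i >> 16) & 255}.{(i >> 8) & 255}.{i & 255}"
        self.geoip[addr] = (country, state)
        return addr

    def zip_for(self, street_key: str, city: str, state: str) -> str:
        key = (street_key, city)
        if key not in self._zips:
            self._zip_serial += 1
            zip_code = f"{30000 + self._zip_serial:05d}"
            self._zips[key] = zip_code
            self.gazetteer[key] = zip_code
            self.zip_index.setdefault(zip_code, (city, state))
        return self._zips[key]


@dataclass
class _Person:
    """A fully materialised synthetic enrollment attempt, pre-archetype."""

    pid: str = ""
    name: str = ""
    email: str = ""
    phone: str = ""
    phone_alts: list[str] = field(default_factory=list)
    handle: str | None = None
    house: str = ""
    street: str = ""
    city: str = ""
    state: str = ""
    zip: str = ""
    ip_screen: str = ""
    ip_baseline: str = ""
    reported_age: int = 16
    dob: date = date(2002, 1, 1)
    sex: str = "male"
    gender: str = "man"
    same_sex_attracted: bool = True
    hiv_status: str = "negative"
    quota_ok: bool = True
    screen_start: datetime = _BASE_DAY
    screen_end: datetime = _BASE_DAY
    base_start: datetime = _BASE_DAY
    base_end: datetime = _BASE_DAY
    subset: list[int | None] = field(default_factory=list)
    outcome: list[int | None] = field(default_factory=list)
    evidence: ManualEvidence = field(default_factory=lambda: ManualEvidence(resolutions=[]))

    def to_dossier(self) -> ParticipantDossier:
        contact = ContactRecord(
            participant_id=self.pid,
            preferred_name=self.name,
            email=self.email,
            phone_primary=self.phone,
            phone_alts=list(self.phone_alts),
            house_number=self.house,
            street=self.street,
            city=self.city,
            state=self.state,
            zip=self.zip,
            social_handles={"chirper": self.handle} if self.handle else {},
            submitted_at=self.screen_end,
        )
        screening = ScreeningRecord(
            screener_id=self.pid,
            reported_age_years=self.reported_age,
            sex_assigned_at_birth=self.sex,
            gender_identity=self.gender,
            same_sex_attracted=self.same_sex_attracted,
            hiv_status=self.hiv_status,
            zip=self.zip,
            ip=self.ip_screen,
            started_at=self.screen_start,
            ended_at=self.screen_end,
            code_verified=True,
            consented=True,
            quota_ok=self.quota_ok,
        )
        baseline = BaselineRecord(
            participant_id=self.pid,
            dob=self.dob,
            ip=self.ip_baseline,
            started_at=self.base_start,
            ended_at=self.base_end,
            random_subset_responses=list(self.subset),
            primary_outcome_responses=list(self.outcome),
        )
        return ParticipantDossier(contact, screening, baseline)


def _dob_for_age(age: int, on: date, rng: random.Random) -> date:
    dob = on - timedelta(days=age * 365 + rng.randint(40, 300))
    while age_in_whole_years(dob, on) > age:
        dob += timedelta(days=20)
    while age_in_whole_years(dob, on) < age:
        dob -= timedelta(days=20)
    return dob


def _likert_block(n: int, rng: random.Random, config: ThresholdConfig,
                  echo_pairs: bool = False) -> list[int | None]:
    values: list[int | None] = [
        rng.randint(config.likert_min, config.likert_max) for _ in range(n)
    ]
    if echo_pairs:
        # keep the conflict-rule item pairs within one scale point of each other
        for a, b in _RULE_ECHO_ITEMS:
            ia, ib = int(a.split("_")[1]) - 1, int(b.split("_")[1]) - 1
            values[ib] = min(
                config.likert_max,
                max(config.likert_min, values[ia] + rng.choice((-1, 0, 1))),
            )
    return values


def _blank_out(block: list[int | None], keep: int, rng: random.Random,
               protected: Sequence[int] = ()) -> None:
    """Blank responses in place until exactly ``keep`` answered items remain."""
    answered = [i for i, v in enumerate(block) if v is not None and i not in protected]
    to_blank = len([v for v in block if v is not None]) - keep
    if to_blank < 0:
        raise ValidationError("cannot keep more items than exist")
    for i in rng.sample(answered, to_blank):
        block[i] = None


class _Generator:
    def __init__(self, seed: int, config: ThresholdConfig):
        if seed is None:
            raise ValidationError("generate_cohort requires a fixed seed")
        self.rng = random.Random(seed)
        self.config = config
        self.mint = _Mint(self.rng)
        self.registry = Registry()
        self.registry_people: list[_Person] = []

    # -- base fabric ---------------------------------------------------------

    def base_person(self, i: int) -> _Person:
        rng, config = self.rng, self.config
        ident = self.mint.identity()
        city, state = CITIES[rng.randrange(len(CITIES))]
        street = f"{STREET_NAMES[rng.randrange(len(STREET_NAMES))].capitalize()} Street"
        street_key = street.lower()
        zip_code = self.mint.zip_for(street_key, city, state)
        ip = self.mint.ip("US", state)
        screen_start = _BASE_DAY + timedelta(days=i % 120, minutes=(i * 7) % 540)
        screen_end = screen_start + timedelta(minutes=rng.randint(4, 9))
        base_start = screen_end + timedelta(minutes=rng.randint(2, 30))
        base_end = base_start + timedelta(minutes=rng.randint(24, 44), seconds=rng.randint(0, 59))
        age = rng.randint(config.min_age, config.max_age)
        person = _Person(
            name=ident["name"],
            email=ident["email"],
            phone=ident["phone"],
            phone_alts=[ident["alt_phone"]] if rng.random() < 0.3 else [],
            handle=ident["handle"] if rng.random() < 0.6518 else None,
            house=ident["house"],
            street=street,
            city=city,
            state=state,
            zip=zip_code,
            ip_screen=ip,
            ip_baseline=ip,
            reported_age=age,
            dob=_dob_for_age(age, base_end.date(), rng),
            screen_start=screen_start,
            screen_end=screen_end,
            base_start=base_start,
            base_end=base_end,
            subset=_likert_block(config.subset_n, rng, config),
            outcome=_likert_block(config.outcome_n, rng, config, echo_pairs=True),
        )
        person.evidence = ManualEvidence(
            social=(
                SocialEvidence(age=age, gender="man", location_state=state)
                if person.handle else None
            ),
            email_response_day=rng.randint(1, 25),
            resolutions=[],
        )
        return person

    # -- registry ------------------------------------------------------------

    def build_registry(self, n_prior: int = 200) -> None:
        for i in range(n_prior):
            person = self.base_person(i)
            person.pid = f"R{i:04d}"
            person.handle = person.handle or self.mint.identity()["handle"]
            # registry people live on distinct "Road" addresses so cohort
            # street sharing never partial-matches the registry by accident
            street = f"{STREET_NAMES[i % len(STREET_NAMES)].capitalize()} Road"
            city, state = CITIES[(i // len(STREET_NAMES)) % len(CITIES)]
            person.street, person.city, person.state = street, city, state
            person.zip = self.mint.zip_for(street.lower(), city, state)
            person.ip_screen = person.ip_baseline = self.mint.ip("US", state)
            self._register(person)
        # the Wisteria household: one enrolled participant plus two recorded
        # prior attempts by the case-study actor; the actor's attempt reused
        # the enrolled household's secondary phone
        for k in range(3):
            person = self.base_person(n_prior + k)
            person.pid = f"W{k:04d}"
            person.street = WISTERIA_STREET
            person.city, person.state = WISTERIA_CITY, WISTERIA_STATE
            person.house = str(k + 1)
            person.zip = self.mint.zip_for(WISTERIA_STREET.lower(), WISTERIA_CITY, WISTERIA_STATE)
            person.ip_screen = person.ip_baseline = self.mint.ip("US", WISTERIA_STATE)
            if k == 0:
                person.phone_alts = [self.mint.identity()["alt_phone"]]
            elif k == 1:
                person.phone = self.registry_people[-1].phone_alts[0]
            self._register(person)

    def _register(self, person: _Person) -> None:
        dossier = person.to_dossier()
        self.registry.add(canonicalize_contact(
            dossier.contact, ips=(person.ip_screen, person.ip_baseline), config=self.config,
        ))
        self.registry_people.append(person)

    # -- archetype mutations -------------------------------------------------

    def apply_archetype(self, person: _Person, archetype: str, params: dict,
                        dup_cursor: list[int]) -> None:
        rng, config = self.rng, self.config
        if archetype == "clean":
            return
        if archetype == "underage":
            age = params.get("age", config.min_age - 1)
            if config.min_age <= age <= config.max_age:
                raise ValidationError(f"underage archetype with eligible age {age}")
            self._set_age(person, age)
        elif archetype == "overage":
            age = params.get("age", config.max_age + 1)
            if config.min_age <= age <= config.max_age:
                raise ValidationError(f"overage archetype with eligible age {age}")
            self._set_age(person, age)
        elif archetype == "not_same_sex_attracted":
            person.same_sex_attracted = False
        elif archetype == "hiv_positive":
            person.hiv_status = "positive"
        elif archetype == "quota_fail":
            person.quota_ok = False
        elif archetype == "exact_duplicate":
            self._plant_exact_duplicate(person, params, dup_cursor)
        elif archetype == "partial_duplicate":
            self._plant_partial_duplicate(person, params, dup_cursor)
            person.evidence.resolutions.append(
                (ITEM_DUPLICATE, "fail", "confirmed duplicate of a prior attempt")
            )
        elif archetype == "foreign_ip":
            ip = self.mint.ip(*FOREIGN_LOCATION)
            person.ip_screen = person.ip_baseline = ip
        elif archetype == "state_mismatch_ip":
            other = next(s for s in STATES if s != person.state)
            ip = self.mint.ip("US", other)
            person.ip_screen = person.ip_baseline = ip
            if params.get("resolution", "explainable") == "explainable":
                person.evidence.resolutions.append((
                    ITEM_ZIP, RESOLVED_EXPLAINABLE,
                    "IP state differs from mailing state; travel confirmed by contact",
                ))
            else:
                person.evidence.resolutions.append(
                    (ITEM_ZIP, "fail", "location inconsistency unresolved")
                )
        elif archetype == "speeder":
            person.base_end = person.base_start + timedelta(minutes=rng.randint(4, 12))
            person.dob = _dob_for_age(person.reported_age, person.base_end.date(), rng)
            person.evidence.resolutions.append(
                (ITEM_TIME, "fail", "no explanation for implausibly fast completion")
            )
        elif archetype == "slow_outlier":
            person.base_end = person.base_start + timedelta(hours=rng.randint(80, 110))
            person.dob = _dob_for_age(person.reported_age, person.base_end.date(), rng)
            if params.get("resolution", "explainable") == "explainable":
                person.evidence.resolutions.append((
                    ITEM_TIME, RESOLVED_EXPLAINABLE,
                    "long completion; interruption confirmed by contact",
                ))
            else:
                person.evidence.resolutions.append(
                    (ITEM_TIME, "fail", "no explanation for multi-day completion")
                )
        elif archetype == "low_completion_subset":
            _blank_out(person.subset, rng.randint(4, config.subset_fail_min - 1), rng)
        elif archetype == "low_completion_outcome":
            _blank_out(person.outcome, rng.randint(10, config.outcome_fail_min - 1), rng)
        elif archetype == "flag_band_completion":
            _blank_out(
                person.subset,
                rng.randint(config.subset_fail_min, config.subset_flag_min - 1),
                rng,
            )
        elif archetype == "age_inconsistent":
            person.dob = _dob_for_age(
                person.reported_age + rng.choice((3, 4, 7)), person.base_end.date(), rng
            )
            person.evidence.resolutions.append(
                (ITEM_AGE, "fail", "screener age and DOB discrepancy unresolved")
            )
        elif archetype == "straightliner":
            value = rng.randint(config.likert_min, config.likert_max)
            person.subset = [value] * config.subset_n
            _blank_out(person.subset, config.subset_fail_min + 1, rng)
        elif archetype == "zigzagger":
            lo, hi = config.likert_min, config.likert_max
            person.subset = [lo if i % 2 == 0 else hi for i in range(config.subset_n)]
            keep = config.subset_fail_min + 1
            person.subset = person.subset[:keep] + [None] * (config.subset_n - keep)
        elif archetype == "conflicted":
            n_conflicts = params.get("conflicts", 3)
            pairs = sorted(_RULE_ECHO_ITEMS)[:n_conflicts]
            for a, b in pairs:
                ia, ib = int(a.split("_")[1]) - 1, int(b.split("_")[1]) - 1
                person.outcome[ia] = config.likert_min
                person.outcome[ib] = config.likert_max
            protected = [int(x.split("_")[1]) - 1 for pair in pairs for x in pair]
            _blank_out(
                person.outcome,
                rng.randint(config.outcome_fail_min + 2, config.outcome_flag_min - 1),
                rng,
                protected=protected,
            )
        elif archetype == "wisteria_cluster":
            person.street = WISTERIA_STREET
            person.city, person.state = WISTERIA_CITY, WISTERIA_STATE
            person.house = str(100 + dup_cursor[1])
            dup_cursor[1] += 1
            person.zip = self.mint.zip_for(
                WISTERIA_STREET.lower(), WISTERIA_CITY, WISTERIA_STATE
            )
            ip = self.mint.ip("US", WISTERIA_STATE)
            person.ip_screen = person.ip_baseline = ip
        elif archetype == "social_contradicted":
            person.handle = person.handle or self.mint.identity()["handle"]
            person.evidence.social = SocialEvidence(
                age=person.reported_age + rng.choice((5, 7, 9)),
                gender="man",
                location_state=person.state,
            )
        elif archetype == "email_nonresponder":
            person.evidence.email_response_day = None
        else:  # pragma: no cover
            raise ValidationError(f"unhandled archetype {archetype!r}")

        second = params.get("second")
        if second:
            self.apply_archetype(person, second, {}, dup_cursor)

    def _set_age(self, person: _Person, age: int) -> None:
        person.reported_age = age
        person.dob = _dob_for_age(age, person.base_end.date(), self.rng)

    def _plant_exact_duplicate(self, person: _Person, params: dict,
                               dup_cursor: list[int]) -> None:
        if params.get("stage") == "manual":
            return  # source assigned once batch order is fixed
        fields = ("email", "phone", "ip", "address", "handle", "name")
        field_name = params.get("field") or fields[dup_cursor[0] % len(fields)]
        source = self.registry_people[dup_cursor[0] % 200]
        dup_cursor[0] += 1
        if field_name == "email":
            person.email = source.email
        elif field_name == "phone":
            person.phone = source.phone
        elif field_name == "ip":
            person.ip_screen = person.ip_baseline = source.ip_baseline
            self._relocate(person, source.state)  # keep IP state == mailing state
        elif field_name == "handle":
            person.handle = source.handle
        elif field_name == "name":
            person.name = source.name
        elif field_name == "address":
            self._move_to(person, source, same_house=True)

    def _plant_partial_duplicate(self, person: _Person, params: dict,
                                 dup_cursor: list[int]) -> None:
        fields = ("email", "name", "address")
        field_name = params.get("field") or fields[dup_cursor[0] % len(fields)]
        source = self.registry_people[dup_cursor[0] % 200]
        dup_cursor[0] += 1
        if field_name == "email":
            local, _, domain = source.email.partition("@")
            person.email = f"{local[:-1]}x@{domain}" if local[-1] != "x" \
                else f"{local[:-1]}q@{domain}"
        elif field_name == "name":
            person.name = source.name[:-1] + ("x" if source.name[-1] != "x" else "q")
        else:  # address: same street, next house number over
            self._move_to(person, source, same_house=False)

    def _move_to(self, person: _Person, source: _Person, same_house: bool) -> None:
        person.street, person.city, person.state = source.street, source.city, source.state
        person.zip = source.zip
        person.house = source.house if same_house else str(int(source.house) + 1)
        ip = self.mint.ip("US", source.state)
        person.ip_screen = person.ip_baseline = ip
        if person.evidence.social is not None:
            # relocation must not manufacture a social-media contradiction
            person.evidence.social.location_state = person.state

    def _relocate(self, person: _Person, state: str) -> None:
        person.state = state
        person.city = REGION[state][0]
        person.zip = self.mint.zip_for(person.street.lower(), person.city, state)
        if person.evidence.social is not None:
            person.evidence.social.location_state = state


_EXPECTED_STATUS = {
    "underage": STATUS_ELIGIBILITY_FAIL,
    "overage": STATUS_ELIGIBILITY_FAIL,
    "not_same_sex_attracted": STATUS_ELIGIBILITY_FAIL,
    "hiv_positive": STATUS_ELIGIBILITY_FAIL,
    "quota_fail": STATUS_ELIGIBILITY_FAIL,
    "exact_duplicate": STATUS_DUPLICATE,
    "foreign_ip": STATUS_IP_FOREIGN,
    "low_completion_subset": STATUS_COMPLETION_FAIL,
    "low_completion_outcome": STATUS_COMPLETION_FAIL,
    "wisteria_cluster": STATUS_CLUSTER_CASE,
}

_FAIL_DISPOSITION_ARCHETYPES = {
    "speeder", "age_inconsistent", "partial_duplicate", "straightliner",
    "zigzagger", "conflicted", "social_contradicted", "email_nonresponder",
}


def _expected(archetype: str, params: dict) -> tuple[str, str | None]:
    if archetype == "exact_duplicate" and params.get("stage") == "manual":
        return STATUS_REFERRED_MANUAL, FAILED_DUPLICATE_NO_CHECKLIST
    if archetype in _EXPECTED_STATUS:
        return _EXPECTED_STATUS[archetype], None
    if archetype in _FAIL_DISPOSITION_ARCHETYPES:
        return STATUS_REFERRED_MANUAL, FAILED_CHECKLIST
    if archetype in ("state_mismatch_ip", "slow_outlier") and \
            params.get("resolution", "explainable") != "explainable":
        return STATUS_REFERRED_MANUAL, FAILED_CHECKLIST
    return STATUS_REFERRED_MANUAL, ENROLLED


def generate_cohort(
    specs: Sequence[ArchetypeSpec] | None = None,
    seed: int = 20210831,
    config: ThresholdConfig | None = None,
) -> SyntheticCohort:
    """Generate a labeled synthetic cohort plus registry, lookups and evidence.

    Byte-identical output for a given ``(specs, seed, config)``.  Records are
    shuffled before ids are assigned, so archetypes do not cluster in id
    order; different seeds change every identity and field value but never
    whether a record satisfies its archetype's check.
    """
    config = config or ThresholdConfig()
    specs = list(default_archetype_specs() if specs is None else specs)
    gen = _Generator(seed, config)
    gen.build_registry()

    # materialise one (archetype, params) slot per record, then shuffle
    slots: list[tuple[str, dict]] = []
    for spec in specs:
        slots.extend((spec.archetype, spec.param_map) for _ in range(spec.count))
    gen.rng.shuffle(slots)

    # within-batch duplicates surface only after their source is on file, so
    # they take the highest ids (processed last by the manual stage)
    def _is_manual_dup(slot: tuple[str, dict]) -> bool:
        return slot[0] == "exact_duplicate" and slot[1].get("stage") == "manual"

    manual_dups = [s for s in slots if _is_manual_dup(s)]
    if manual_dups:
        slots = [s for s in slots if not _is_manual_dup(s)] + manual_dups
        if sum(1 for a, _ in slots if a == "clean") < len(manual_dups):
            raise ValidationError(
                "manual-stage duplicates need at least as many clean records to copy"
            )

    dup_cursor = [0, 0, 0]  # registry cursor, wisteria house counter, handle counter
    people: list[_Person] = []
    truth: dict[str, TruthLabel] = {}
    for i, (archetype, params) in enumerate(slots):
        person = gen.base_person(1000 + i)
        person.pid = f"P{i:06d}"
        gen.apply_archetype(person, archetype, params, dup_cursor)
        people.append(person)
        status, disposition = _expected(archetype, params)
        variant = ",".join(f"{k}={v}" for k, v in sorted(params.items()))
        truth[person.pid] = TruthLabel(archetype, variant, status, disposition)

    # point each manual-stage duplicate at a distinct earlier clean record
    clean_people = [p for p in people if truth[p.pid].archetype == "clean"]
    cursor = 0
    for person in people:
        label = truth[person.pid]
        if label.archetype == "exact_duplicate" and "stage=manual" in label.variant:
            source = clean_people[cursor]
            cursor += 1
            assert source.pid < person.pid
            person.email = source.email

    lookups = LookupTables(
        geoip=dict(gen.mint.geoip),
        gazetteer=dict(gen.mint.gazetteer),
        zip_index=dict(gen.mint.zip_index),
    )
    dossiers = [p.to_dossier() for p in people]
    for d in dossiers:
        d.validate(config)
    evidence = {p.pid: p.evidence for p in people}
    return SyntheticCohort(
        dossiers=dossiers,
        truth=truth,
        lookups=lookups,
        registry=gen.registry,
        manual_evidence=evidence,
        funnel_counts=default_funnel_counts(),
        conflict_rules=default_conflict_rules(),
        config=config,
    )


def generate_lookup_tables(cohort: SyntheticCohort) -> LookupTables:
    """The lookup tables consistent with a generated cohort (already attached
    to the cohort; exposed for symmetry and for regenerating files)."""
    return cohort.lookups
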