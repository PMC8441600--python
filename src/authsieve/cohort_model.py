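"""Domain records, configuration, and delimited-text I/O for the authentication pipeline.

The unit of judgement is the :class:`ParticipantDossier`: the joined view of one
enrollment attempt built from a contact-information row, a screening-survey row
and a baseline-questionnaire row.  Every automated or manual check consumes a
dossier and emits :class:`CheckResult` objects; the automated stage condenses
them into a single mutually exclusive :class:`AutoDecision` status.

All tables are UTF-8, comma-delimited text with a header row.  Missing values
are encoded as empty fields.  Dates are ISO-8601 (``YYYY-MM-DD``); timestamps
are ISO-8601 with a ``Z`` suffix and are always stored and compared in UTC, so
no outcome depends on the host timezone.  Rows that violate type invariants are
quarantined with row-level diagnostics rather than aborting a batch run.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

# ---------------------------------------------------------------------------
# outcome / status vocabularies
# ---------------------------------------------------------------------------

PASS = "pass"
FLAG = "flag"
FAIL = "fail"
NOT_APPLICABLE = "not_applicable"
OUTCOMES = (PASS, FLAG, FAIL, NOT_APPLICABLE)

CHECK_IDS = (
    "sms_code",
    "eligibility",
    "duplicate",
    "ip_country",
    "ip_state_vs_mailing",
    "ip_screen_vs_baseline",
    "age_consistency",
    "completion_time",
    "completion_score",
    "pattern",
    "zip_mismatch",
    "social_media",
    "email_verification",
    "followup_age",
    "alternate_contact",
)

STATUS_ELIGIBILITY_FAIL = "eligibility_fail"
STATUS_DUPLICATE = "duplicate"
STATUS_IP_FOREIGN = "ip_foreign"
STATUS_COMPLETION_FAIL = "completion_fail"
STATUS_CLUSTER_CASE = "cluster_case"
STATUS_REFERRED_MANUAL = "referred_manual"
AUTO_STATUSES = (
    STATUS_ELIGIBILITY_FAIL,
    STATUS_DUPLICATE,
    STATUS_IP_FOREIGN,
    STATUS_COMPLETION_FAIL,
    STATUS_CLUSTER_CASE,
    STATUS_REFERRED_MANUAL,
)

US_STATES = frozenset(
    """AL AK AZ AR CA CO CT DE FL GA HI ID IL IN IA KS KY LA ME MD MA MI MN MS
    MO MT NE NV NH NJ NM NY NC ND OH OK OR PA RI SC SD TN TX UT VT VA WA WV WI
    WY DC""".split()
)

_ZIP_RE = re.compile(r"^\d{5}$")
_IP_RE = re.compile(r"^\d{1,3}(\.\d{1,3}){3}$")


class ValidationError(ValueError):
    """A value violates a record invariant or an operation precondition."""


class SchemaError(ValueError):
    """An input table is missing a required column."""


class OrphanRecordError(ValueError):
    """A baseline row has no matching contact and/or screening row."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ThresholdConfig:
    """Every tunable threshold of the pipeline, with the study defaults.

    Completion-score gates are stored as fractions and materialised as integer
    minima via ``ceil(frac * n)``: with the default 27-item random subset and
    62-item primary-outcome block this yields hard-fail minima of 17 and 44
    answered items and manual-review minima of 22 and 50.
    """

    min_age: int = 13
    max_age: int = 18
    subset_n: int = 27
    outcome_n: int = 62
    subset_fail_frac: float = 0.60
    outcome_fail_frac: float = 0.70
    manual_flag_frac: float = 0.80
    min_minutes: float = 20.0
    design_minutes: float = 30.0
    max_hours: float = 72.0
    email_window_days: int = 30
    reminder_period_days: int = 7
    code_digits: int = 3
    cluster_min_size: int = 3
    name_edit_max: int = 1
    email_edit_max: int = 1
    strip_plus_tags: bool = True
    likert_min: int = 1
    likert_max: int = 5
    straightline_threshold: float = 0.95
    zigzag_threshold: float = 0.90
    pattern_min_items: int = 10
    # recruitment-region gating and the enrollment-quota predicate are both
    # optional; None disables region gating entirely.
    recruitment_states: tuple[str, ...] | None = None
    quota_gating: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.subset_fail_frac < self.manual_flag_frac <= 1):
            raise ValidationError("require 0 < subset_fail_frac < manual_flag_frac <= 1")
        if not (0 < self.outcome_fail_frac < self.manual_flag_frac <= 1):
            raise ValidationError("require 0 < outcome_fail_frac < manual_flag_frac <= 1")
        if self.min_age > self.max_age:
            raise ValidationError("min_age must not exceed max_age")
        if self.likert_min >= self.likert_max:
            raise ValidationError("likert_min must be below likert_max")
        if self.recruitment_states is not None:
            self.recruitment_states = tuple(self.recruitment_states)

    # integer gate minima (answered-item counts)
    @property
    def subset_fail_min(self) -> int:
        return math.ceil(self.subset_fail_frac * self.subset_n)

    @property
    def outcome_fail_min(self) -> int:
        return math.ceil(self.outcome_fail_frac * self.outcome_n)

    @property
    def subset_flag_min(self) -> int:
        return math.ceil(self.manual_flag_frac * self.subset_n)

    @property
    def outcome_flag_min(self) -> int:
        return math.ceil(self.manual_flag_frac * self.outcome_n)

    @property
    def scale_span(self) -> int:
        return self.likert_max - self.likert_min

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        if data["recruitment_states"] is not None:
            data["recruitment_states"] = list(data["recruitment_states"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


def _parse_ts(raw: str, what: str) -> datetime:
    try:
        ts = datetime.fromisoformat(raw.replace("Z", "+00:00"))
    except ValueError as exc:
        raise ValidationError(f"{what}: bad timestamp {raw!r}") from exc
    if ts.tzinfo is None:
        raise ValidationError(f"{what}: timestamp {raw!r} lacks a UTC offset")
    return ts.astimezone(timezone.utc)


def _fmt_ts(ts: datetime) -> str:
    return ts.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def _parse_date(raw: str, what: str) -> date:
    try:
        return date.fromisoformat(raw)
    except ValueError as exc:
        raise ValidationError(f"{what}: bad date {raw!r}") from exc


def _parse_bool(raw: str, what: str) -> bool:
    low = raw.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    raise ValidationError(f"{what}: bad boolean {raw!r}")


@dataclass
class ContactRecord:
    participant_id: str
    preferred_name: str
    email: str
    phone_primary: str
    phone_alts: list[str] = field(default_factory=list)
    house_number: str = ""
    street: str = ""
    city: str = ""
    state: str = ""
    zip: str = ""
    social_handles: dict[str, str] = field(default_factory=dict)
    submitted_at: datetime = datetime(1970, 1, 1, tzinfo=timezone.utc)

    def validate(self) -> None:
        if not self.participant_id:
            raise ValidationError("contact: empty participant_id")
        if self.zip and not _ZIP_RE.match(self.zip):
            raise ValidationError(f"contact {self.participant_id}: zip {self.zip!r} is not 5 digits")
        if self.state and self.state not in US_STATES:
            raise ValidationError(f"contact {self.participant_id}: unknown state {self.state!r}")


@dataclass
class ScreeningRecord:
    screener_id: str
    reported_age_years: int
    sex_assigned_at_birth: str  # male | female | other
    gender_identity: str  # man | woman | other
    same_sex_attracted: bool
    hiv_status: str  # negative | positive | unknown
    zip: str
    ip: str
    started_at: datetime
    ended_at: datetime
    code_verified: bool = True
    consented: bool = True
    quota_ok: bool = True  # generic enrollment-quota predicate (e.g. race/region quota)

    def validate(self) -> None:
        if self.ended_at < self.started_at:
            raise ValidationError(f"screening {self.screener_id}: ended_at before started_at")
        if not (0 <= self.reported_age_years <= 120):
            raise ValidationError(
                f"screening {self.screener_id}: age {self.reported_age_years} outside [0, 120]"
            )
        if self.sex_assigned_at_birth not in ("male", "female", "other"):
            raise ValidationError(f"screening {self.screener_id}: bad sex_assigned_at_birth")
        if self.gender_identity not in ("man", "woman", "other"):
            raise ValidationError(f"screening {self.screener_id}: bad gender_identity")
        if self.hiv_status not in ("negative", "positive", "unknown"):
            raise ValidationError(f"screening {self.screener_id}: bad hiv_status")


MISSING = None  # a skipped Likert item


@dataclass
class BaselineRecord:
    participant_id: str
    dob: date
    ip: str
    started_at: datetime
    ended_at: datetime
    random_subset_responses: list[int | None]
    primary_outcome_responses: list[int | None]

    @property
    def likert_blocks(self) -> list[tuple[str, list[int | None]]]:
        """Ordered response blocks analysed by the survey pattern review."""
        return [
            ("random_subset", self.random_subset_responses),
            ("primary_outcome", self.primary_outcome_responses),
        ]

    def items(self) -> dict[str, int | None]:
        """Flat item-id → response map (``rs_NN`` / ``po_NN``) for conflict rules."""
        out: dict[str, int | None] = {}
        for i, v in enumerate(self.random_subset_responses, 1):
            out[f"rs_{i:02d}"] = v
        for i, v in enumerate(self.primary_outcome_responses, 1):
            out[f"po_{i:02d}"] = v
        return out

    def validate(self, config: ThresholdConfig) -> None:
        if len(self.random_subset_responses) != config.subset_n:
            raise ValidationError(
                f"baseline {self.participant_id}: subset length "
                f"{len(self.random_subset_responses)} != {config.subset_n}"
            )
        if len(self.primary_outcome_responses) != config.outcome_n:
            raise ValidationError(
                f"baseline {self.participant_id}: outcome length "
                f"{len(self.primary_outcome_responses)} != {config.outcome_n}"
            )
        for v in self.random_subset_responses + self.primary_outcome_responses:
            if v is not None and not (config.likert_min <= v <= config.likert_max):
                raise ValidationError(
                    f"baseline {self.participant_id}: Likert value {v} outside "
                    f"[{config.likert_min}, {config.likert_max}]"
                )
        if self.ended_at < self.started_at:
            raise ValidationError(f"baseline {self.participant_id}: ended_at before started_at")


FOLLOWUP_WAVES = (3, 6, 9, 12, 15)


@dataclass
class FollowUpRecord:
    participant_id: str
    wave_months: int
    reported_dob: date | None
    reported_age: int | None
    alt_phone: str
    alt_email: str
    completed_at: datetime

    def validate(self) -> None:
        if self.wave_months not in FOLLOWUP_WAVES:
            raise ValidationError(
                f"followup {self.participant_id}: wave {self.wave_months} not in {FOLLOWUP_WAVES}"
            )


@dataclass
class ParticipantDossier:
    contact: ContactRecord
    screening: ScreeningRecord
    baseline: BaselineRecord

    @property
    def participant_id(self) -> str:
        return self.baseline.participant_id

    def validate(self, config: ThresholdConfig) -> None:
        self.contact.validate()
        self.screening.validate()
        self.baseline.validate(config)
        if not (
            self.contact.participant_id
            == self.screening.screener_id
            == self.baseline.participant_id
        ):
            raise ValidationError(
                f"dossier {self.baseline.participant_id}: inconsistent identifiers"
            )


@dataclass
class CheckResult:
    check_id: str
    outcome: str
    reason: str = ""
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.check_id not in CHECK_IDS:
            raise ValidationError(f"unknown check_id {self.check_id!r}")
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.outcome in (FLAG, FAIL) and not self.reason:
            raise ValidationError(f"{self.check_id}: outcome {self.outcome} requires a reason")


@dataclass
class AutoDecision:
    participant_id: str
    status: str
    flags_carried: list[CheckResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status not in AUTO_STATUSES:
            raise ValidationError(f"unknown automated status {self.status!r}")


@dataclass
class LookupTables:
    """Offline IP-geolocation and street/zip gazetteer lookups.

    ``geoip`` maps a dotted-quad IP to a ``(country, state)`` pair; ``state`` is
    blank for non-US addresses.  ``gazetteer`` maps a normalised
    ``(street, city)`` pair to its zip code, with a reverse ``zip`` →
    ``(city, state)`` index.
    """

    geoip: dict[str, tuple[str, str]] = field(default_factory=dict)
    gazetteer: dict[tuple[str, str], str] = field(default_factory=dict)
    zip_index: dict[str, tuple[str, str]] = field(default_factory=dict)

    def locate(self, ip: str) -> tuple[str, str] | None:
        return self.geoip.get(ip)


@dataclass
class RejectedRow:
    table: str
    row_index: int
    participant_id: str
    reason: str


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

CONTACT_COLUMNS = [
    "participant_id", "preferred_name", "email", "phone_primary", "phone_alts",
    "house_number", "street", "city", "state", "zip", "social_handles", "submitted_at",
]
SCREENING_COLUMNS = [
    "screener_id", "reported_age_years", "sex_assigned_at_birth", "gender_identity",
    "same_sex_attracted", "hiv_status", "zip", "ip", "started_at", "ended_at",
    "code_verified", "consented", "quota_ok",
]
FOLLOWUP_COLUMNS = [
    "participant_id", "wave_months", "reported_dob", "reported_age",
    "alt_phone", "alt_email", "completed_at",
]


def _baseline_columns(config: ThresholdConfig) -> list[str]:
    cols = ["participant_id", "dob", "ip", "started_at", "ended_at"]
    cols += [f"rs_{i:02d}" for i in range(1, config.subset_n + 1)]
    cols += [f"po_{i:02d}" for i in range(1, config.outcome_n + 1)]
    return cols


def _read_table(path: str | Path, required: Sequence[str], table: str) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {', '.join(missing)}")
    return frame


def _join_semi(values: Iterable[str]) -> str:
    return ";".join(values)


def _split_semi(raw: str) -> list[str]:
    return [v for v in raw.split(";") if v]


def _join_handles(handles: Mapping[str, str]) -> str:
    return ";".join(f"{platform}:{handle}" for platform, handle in sorted(handles.items()))


def _split_handles(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in _split_semi(raw):
        platform, _, handle = part.partition(":")
        out[platform] = handle
    return out


def _contact_from_row(row: Mapping[str, str]) -> ContactRecord:
    return ContactRecord(
        participant_id=row["participant_id"],
        preferred_name=row["preferred_name"],
        email=row["email"],
        phone_primary=row["phone_primary"],
        phone_alts=_split_semi(row["phone_alts"]),
        house_number=row["house_number"],
        street=row["street"],
        city=row["city"],
        state=row["state"],
        zip=row["zip"],
        social_handles=_split_handles(row["social_handles"]),
        submitted_at=_parse_ts(row["submitted_at"], "contact submitted_at"),
    )


def _screening_from_row(row: Mapping[str, str]) -> ScreeningRecord:
    return ScreeningRecord(
        screener_id=row["screener_id"],
        reported_age_years=int(row["reported_age_years"]),
        sex_assigned_at_birth=row["sex_assigned_at_birth"],
        gender_identity=row["gender_identity"],
        same_sex_attracted=_parse_bool(row["same_sex_attracted"], "same_sex_attracted"),
        hiv_status=row["hiv_status"],
        zip=row["zip"],
        ip=row["ip"],
        started_at=_parse_ts(row["started_at"], "screening started_at"),
        ended_at=_parse_ts(row["ended_at"], "screening ended_at"),
        code_verified=_parse_bool(row["code_verified"], "code_verified"),
        consented=_parse_bool(row["consented"], "consented"),
        quota_ok=_parse_bool(row["quota_ok"], "quota_ok"),
    )


def _likert_cell(raw: str) -> int | None:
    return None if raw == "" else int(raw)


def _baseline_from_row(row: Mapping[str, str], config: ThresholdConfig) -> BaselineRecord:
    return BaselineRecord(
        participant_id=row["participant_id"],
        dob=_parse_date(row["dob"], "baseline dob"),
        ip=row["ip"],
        started_at=_parse_ts(row["started_at"], "baseline started_at"),
        ended_at=_parse_ts(row["ended_at"], "baseline ended_at"),
        random_subset_responses=[
            _likert_cell(row[f"rs_{i:02d}"]) for i in range(1, config.subset_n + 1)
        ],
        primary_outcome_responses=[
            _likert_cell(row[f"po_{i:02d}"]) for i in range(1, config.outcome_n + 1)
        ],
    )


def read_lookup_tables(geoip_path: str | Path, gazetteer_path: str | Path) -> LookupTables:
    tables = LookupTables()
    geo = _read_table(geoip_path, ["ip", "country", "state"], "geoip")
    for row in geo.itertuples(index=False):
        if row.ip in tables.geoip:
            raise ValidationError(f"geoip: duplicate key {row.ip}")
        tables.geoip[row.ip] = (row.country, row.state)
    gaz = _read_table(gazetteer_path, ["street", "city", "state", "zip"], "gazetteer")
    for row in gaz.itertuples(index=False):
        key = (row.street.strip().lower(), row.city.strip().lower())
        if key in tables.gazetteer:
            raise ValidationError(f"gazetteer: duplicate street key {key}")
        tables.gazetteer[key] = row.zip
        tables.zip_index.setdefault(row.zip, (row.city, row.state))
    return tables


def read_cohort(
    paths: Mapping[str, str | Path],
    config: ThresholdConfig,
) -> tuple[list[ParticipantDossier], LookupTables, list[RejectedRow]]:
    """Load and join the per-participant tables into dossiers.

    ``paths`` must provide ``contacts``, ``screening``, ``baseline``, ``geoip``
    and ``gazetteer``.  One dossier is produced per baseline row, joined on
    participant id.  Rows that violate type invariants are quarantined into the
    returned reject list (and dossiers depending on them are quarantined too);
    a baseline row whose join key is absent from the contact or screening table
    altogether raises :class:`OrphanRecordError`.
    """
    rejects: list[RejectedRow] = []

    def load(frame: pd.DataFrame, table: str, key: str, parse) -> dict:
        out = {}
        for idx, row in enumerate(frame.to_dict("records")):
            pid = row.get(key, "")
            try:
                rec = parse(row)
                if hasattr(rec, "validate"):
                    try:
                        rec.validate(config)  # type: ignore[call-arg]
                    except TypeError:
                        rec.validate()
                if pid in out:
                    raise ValidationError(f"{table}: duplicate id {pid}")
                out[pid] = rec
            except (ValidationError, ValueError) as exc:
                rejects.append(RejectedRow(table, idx, pid, str(exc)))
        return out

    contacts = load(
        _read_table(paths["contacts"], CONTACT_COLUMNS, "contacts"),
        "contacts", "participant_id", _contact_from_row,
    )
    screenings = load(
        _read_table(paths["screening"], SCREENING_COLUMNS, "screening"),
        "screening", "screener_id", _screening_from_row,
    )
    baselines = load(
        _read_table(paths["baseline"], _baseline_columns(config), "baseline"),
        "baseline", "participant_id", lambda row: _baseline_from_row(row, config),
    )

    rejected_ids = {r.participant_id for r in rejects}
    dossiers: list[ParticipantDossier] = []
    orphans: list[str] = []
    for idx, (pid, baseline) in enumerate(baselines.items()):
        contact = contacts.get(pid)
        screening = screenings.get(pid)
        if contact is None or screening is None:
            if pid in rejected_ids:
                rejects.append(
                    RejectedRow("baseline", idx, pid, "parent contact/screening row rejected")
                )
            else:
                orphans.append(pid)
            continue
        dossiers.append(ParticipantDossier(contact, screening, baseline))
    if orphans:
        raise OrphanRecordError(
            "baseline rows without contact/screening rows: " + ", ".join(sorted(orphans))
        )

    lookups = read_lookup_tables(paths["geoip"], paths["gazetteer"])
    return dossiers, lookups, rejects


def read_followups(path: str | Path) -> tuple[list[FollowUpRecord], list[RejectedRow]]:
    frame = _read_table(path, FOLLOWUP_COLUMNS, "followup")
    records: list[FollowUpRecord] = []
    rejects: list[RejectedRow] = []
    for idx, row in enumerate(frame.to_dict("records")):
        try:
            rec = FollowUpRecord(
                participant_id=row["participant_id"],
                wave_months=int(row["wave_months"]),
                reported_dob=(
                    _parse_date(row["reported_dob"], "followup dob") if row["reported_dob"] else None
                ),
                reported_age=int(row["reported_age"]) if row["reported_age"] else None,
                alt_phone=row["alt_phone"],
                alt_email=row["alt_email"],
                completed_at=_parse_ts(row["completed_at"], "followup completed_at"),
            )
            rec.validate()
            records.append(rec)
        except (ValidationError, ValueError) as exc:
            rejects.append(RejectedRow("followup", idx, row.get("participant_id", ""), str(exc)))
    return records, rejects


def write_cohort(
    dossiers: Sequence[ParticipantDossier],
    lookups: LookupTables,
    out_dir: str | Path,
    config: ThresholdConfig,
) -> dict[str, Path]:
    """Write dossiers + lookup tables back to the canonical CSV layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "contacts": out / "contacts.csv",
        "screening": out / "screening.csv",
        "baseline": out / "baseline.csv",
        "geoip": out / "geoip.csv",
        "gazetteer": out / "gazetteer.csv",
    }

    contact_rows = []
    screening_rows = []
    baseline_rows = []
    for d in dossiers:
        c, s, b = d.contact, d.screening, d.baseline
        contact_rows.append({
            "participant_id": c.participant_id,
            "preferred_name": c.preferred_name,
            "email": c.email,
            "phone_primary": c.phone_primary,
            "phone_alts": _join_semi(c.phone_alts),
            "house_number": c.house_number,
            "street": c.street,
            "city": c.city,
            "state": c.state,
            "zip": c.zip,
            "social_handles": _join_handles(c.social_handles),
            "submitted_at": _fmt_ts(c.submitted_at),
        })
        screening_rows.append({
            "screener_id": s.screener_id,
            "reported_age_years": s.reported_age_years,
            "sex_assigned_at_birth": s.sex_assigned_at_birth,
            "gender_identity": s.gender_identity,
            "same_sex_attracted": str(s.same_sex_attracted).lower(),
            "hiv_status": s.hiv_status,
            "zip": s.zip,
            "ip": s.ip,
            "started_at": _fmt_ts(s.started_at),
            "ended_at": _fmt_ts(s.ended_at),
            "code_verified": str(s.code_verified).lower(),
            "consented": str(s.consented).lower(),
            "quota_ok": str(s.quota_ok).lower(),
        })
        row = {
            "participant_id": b.participant_id,
            "dob": b.dob.isoformat(),
            "ip": b.ip,
            "started_at": _fmt_ts(b.started_at),
            "ended_at": _fmt_ts(b.ended_at),
        }
        for i, v in enumerate(b.random_subset_responses, 1):
            row[f"rs_{i:02d}"] = "" if v is None else v
        for i, v in enumerate(b.primary_outcome_responses, 1):
            row[f"po_{i:02d}"] = "" if v is None else v
        baseline_rows.append(row)

    pd.DataFrame(contact_rows, columns=CONTACT_COLUMNS).to_csv(paths["contacts"], index=False)
    pd.DataFrame(screening_rows, columns=SCREENING_COLUMNS).to_csv(paths["screening"], index=False)
    pd.DataFrame(baseline_rows, columns=_baseline_columns(config)).to_csv(
        paths["baseline"], index=False
    )
    pd.DataFrame(
        [{"ip": ip, "country": c, "state": s} for ip, (c, s) in sorted(lookups.geoip.items())],
        columns=["ip", "country", "state"],
    ).to_csv(paths["geoip"], index=False)
    gaz_rows = []
    for (street, city), zip_code in sorted(lookups.gazetteer.items()):
        city_name, state = lookups.zip_index.get(zip_code, (city, ""))
        gaz_rows.append({"street": street, "city": city, "state": state, "zip": zip_code})
    pd.DataFrame(gaz_rows, columns=["street", "city", "state", "zip"]).to_csv(
        paths["gazetteer"], index=False
    )
    return paths


def write_rejects(rejects: Sequence[RejectedRow], path: str | Path) -> None:
    pd.DataFrame(
        [asdict(r) for r in rejects],
        columns=["table", "row_index", "participant_id", "reason"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# decisions + audit log
# ---------------------------------------------------------------------------


def write_decisions(decisions: Sequence, path: str | Path) -> None:
    """Write automated decisions (or manual cases) one row per participant.

    Rows are ordered by participant id; a duplicated participant id is an
    error, since the pipeline issues exactly one decision per attempt.
    """
    if not decisions:
        raise ValidationError("write_decisions: empty decision list")
    ids = [d.participant_id for d in decisions]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"write_decisions: duplicate participant_id(s) {', '.join(dupes)}")
    rows = []
    for d in sorted(decisions, key=lambda d: d.participant_id):
        if isinstance(d, AutoDecision):
            rows.append({
                "participant_id": d.participant_id,
                "status": d.status,
                "flags": _join_semi(f.check_id for f in d.flags_carried),
            })
        else:  # ManualCase (duck-typed to avoid a circular import)
            rows.append({
                "participant_id": d.participant_id,
                "status": d.disposition,
                "flags": _join_semi(
                    f"{name}={item.outcome}" for name, item in sorted(d.items.items())
                ),
            })
    pd.DataFrame(rows, columns=["participant_id", "status", "flags"]).to_csv(path, index=False)


def read_decisions(path: str | Path) -> list[AutoDecision]:
    frame = _read_table(path, ["participant_id", "status", "flags"], "decisions")
    out = []
    for row in frame.to_dict("records"):
        flags = [
            CheckResult(check_id=cid, outcome=FLAG, reason="carried")
            for cid in _split_semi(row["flags"])
        ]
        out.append(AutoDecision(row["participant_id"], row["status"], flags))
    return out


class AuditLog:
    """Append-only JSON-lines log of every check outcome.

    Each line records the run id, participant id, check id, outcome, reason,
    evidence and a UTC wall-clock timestamp; replaying the file reconstructs
    every decision the pipeline took.
    """

    def __init__(self, path: str | Path, run_id: str = "run-0"):
        self.path = Path(path)
        self.run_id = run_id
        self._fh = open(self.path, "a", encoding="utf-8")

    def record(self, participant_id: str, result: CheckResult) -> None:
        line = {
            "run_id": self.run_id,
            "participant_id": participant_id,
            "check_id": result.check_id,
            "outcome": result.outcome,
            "reason": result.reason,
            "evidence": {k: str(v) for k, v in result.evidence.items()},
            "logged_at": _fmt_ts(datetime.now(timezone.utc)),
        }
        self._fh.write(json.dumps(line, sort_keys=True) + "\n")

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "AuditLog":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_audit(results: Iterable[tuple[str, CheckResult]], path: str | Path,
                run_id: str = "run-0") -> int:
    """Append a stream of (participant_id, CheckResult) pairs; returns line count."""
    n = 0
    with AuditLog(path, run_id=run_id) as log:
        for pid, result in results:
            log.record(pid, result)
            n += 1
    return n


def read_audit(path: str | Path) -> list[dict]:
    lines = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            raw = raw.strip()
            if raw:
                lines.append(json.loads(raw))
    return lines
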