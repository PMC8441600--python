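"""Enrollment-funnel and status-table reporting.

Counts flow down a CONSORT-style funnel (site visitors → screened → eligible →
consented → contact-verified → started baseline → referred to manual review →
enrolled) and three partition tables summarise the pipeline: automated
statuses over the baseline-starting denominator, manual dispositions over the
referred denominator, and (non-exclusive) manual failure reasons over the
checklist-failure denominator.

Percent strings support two conventions — round-half-up and truncation — at a
configurable number of decimals, because published enrollment reports mix
both; the exact-rational arithmetic lives in :func:`percent_format`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Mapping, Sequence

from .cohort_model import (
    AUTO_STATUSES,
    AutoDecision,
    STATUS_REFERRED_MANUAL,
    ValidationError,
)
from .manual_review import (
    CHECKLIST_ITEMS,
    DISPOSITIONS,
    FAIL,
    FAILED_CHECKLIST,
    ManualCase,
)

ROUND_HALF_UP_MODE = "round_half_up"
TRUNCATE_MODE = "truncate"
PERCENT_MODES = (ROUND_HALF_UP_MODE, TRUNCATE_MODE)


def percent_format(
    numerator: int,
    denominator: int,
    places: int = 2,
    mode: str = ROUND_HALF_UP_MODE,
) -> str:
    """Format ``100 * numerator / denominator`` to ``places`` decimals.

    ``round_half_up`` rounds ties away from zero; ``truncate`` drops digits.
    Computed on exact rationals, so e.g. (1224, 1324) truncates to "92.44"
    and (13931, 19709) rounds to "70.68" without binary-float artifacts.
    """
    if denominator <= 0:
        raise ValidationError("percent_format: denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValidationError("percent_format: numerator outside [0, denominator]")
    if mode not in PERCENT_MODES:
        raise ValidationError(f"unknown percent mode {mode!r}")
    exact = Fraction(100 * numerator, denominator)
    value = Decimal(exact.numerator) / Decimal(exact.denominator)
    quantum = Decimal(1).scaleb(-places)
    rounding = ROUND_HALF_UP if mode == ROUND_HALF_UP_MODE else ROUND_DOWN
    return str(value.quantize(quantum, rounding=rounding))


@dataclass
class FunnelCounts:
    visitors: int
    screened: int
    eligible: int
    consented: int
    contact_verified: int
    started_baseline: int
    referred_manual: int
    enrolled: int

    STAGES = (
        "visitors", "screened", "eligible", "consented",
        "contact_verified", "started_baseline", "referred_manual", "enrolled",
    )

    def validate(self) -> None:
        values = [getattr(self, s) for s in self.STAGES]
        if any(v < 0 for v in values):
            raise ValidationError("funnel counts must be nonnegative")
        if any(b > a for a, b in zip(values, values[1:])):
            raise ValidationError("funnel counts must be non-increasing down the stages")


@dataclass
class ReportRow:
    label: str
    count: int
    percent: str


@dataclass
class ReportTable:
    title: str
    denominator: int
    rows: list[ReportRow] = field(default_factory=list)
    percent_mode: str = ROUND_HALF_UP_MODE
    places: int = 2
    partition: bool = True  # counts must sum to the denominator

    def validate(self) -> None:
        if self.partition and self.denominator and (
            sum(r.count for r in self.rows) != self.denominator
        ):
            raise ValidationError(
                f"table {self.title!r}: row counts do not sum to denominator"
            )

    def to_text(self) -> str:
        width = max([len(r.label) for r in self.rows] + [len(self.title)]) + 2
        lines = [f"{self.title} (N={self.denominator})"]
        for r in self.rows:
            lines.append(f"  {r.label:<{width}} {r.count:>6}  ({r.percent}%)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "title": self.title,
            "denominator": self.denominator,
            "percent_mode": self.percent_mode,
            "rows": [
                {"label": r.label, "count": r.count, "percent": r.percent} for r in self.rows
            ],
        }


def funnel_report(
    counts: FunnelCounts,
    places: int = 2,
    mode: str = ROUND_HALF_UP_MODE,
) -> ReportTable:
    """Stage-over-stage funnel percentages with the conventional denominators:
    screened/visitors, eligible/screened, consented/eligible, and
    started-baseline/contact-verified."""
    counts.validate()
    pairs = [
        ("visitors", counts.visitors, None),
        ("screened", counts.screened, counts.visitors),
        ("eligible", counts.eligible, counts.screened),
        ("consented", counts.consented, counts.eligible),
        ("contact_verified", counts.contact_verified, counts.consented),
        ("started_baseline", counts.started_baseline, counts.contact_verified),
        ("referred_manual", counts.referred_manual, counts.started_baseline),
        ("enrolled", counts.enrolled, counts.referred_manual),
    ]
    table = ReportTable(
        "Enrollment funnel", counts.visitors, percent_mode=mode, places=places,
        partition=False,
    )
    for label, n, d in pairs:
        if d is None:  # top of the funnel: percentage of itself
            d = n or 1
        pct = percent_format(n, d, places, mode) if d else "0." + "0" * places
        table.rows.append(ReportRow(label, n, pct))
    return table


AUTO_STATUS_LABELS = {
    "eligibility_fail": "Failed eligibility recheck",
    "duplicate": "Duplication or already enrolled",
    "ip_foreign": "IP address outside the United States",
    "completion_fail": "Failed completion score requirements",
    "cluster_case": "Address-cluster case attempts",
    "referred_manual": "Passed, referred to manual authentication",
}

DISPOSITION_LABELS = {
    "failed_duplicate_no_checklist": "Failed, no checklist completed (duplicate)",
    "failed_checklist": "Failed manual checklist and removed",
    "enrolled": "Passed and enrolled",
}

REASON_ITEMS = (
    ("time_stamp", "Time stamp fail"),
    ("age_comparison", "Age comparison screener and baseline fail"),
    ("duplicate_check", "Duplicate check fail"),
    ("pattern_check", "Suspicious pattern survey response fail"),
    ("social_media_check", "Social media check fail (if provided)"),
)


def status_tables(
    decisions: Sequence[AutoDecision],
    manual_cases: Sequence[ManualCase],
    places: int = 2,
    mode: str = ROUND_HALF_UP_MODE,
) -> tuple[ReportTable, ReportTable, ReportTable]:
    """The three status tables of one pipeline run.

    (1) automated statuses over all baseline-starting dossiers, (2) manual
    dispositions over the referred subset, (3) checklist failure reasons over
    the checklist-failure subset (reasons are not mutually exclusive, so no
    partition constraint applies).
    """
    n_auto = len(decisions)
    auto = ReportTable("Automated authentication status", n_auto,
                       percent_mode=mode, places=places)
    counts = {s: 0 for s in AUTO_STATUSES}
    for d in decisions:
        counts[d.status] += 1
    for status in AUTO_STATUSES:
        pct = percent_format(counts[status], n_auto, places, mode) if n_auto else "0.00"
        auto.rows.append(ReportRow(AUTO_STATUS_LABELS[status], counts[status], pct))
    auto.validate()

    n_manual = len(manual_cases)
    manual = ReportTable("Manual authentication status", n_manual,
                         percent_mode=mode, places=places)
    disp = {d: 0 for d in DISPOSITIONS}
    for case in manual_cases:
        disp[case.disposition] += 1
    for d in ("failed_duplicate_no_checklist", "failed_checklist", "enrolled"):
        pct = percent_format(disp[d], n_manual, places, mode) if n_manual else "0.00"
        manual.rows.append(ReportRow(DISPOSITION_LABELS[d], disp[d], pct))
    manual.validate()

    failures = [c for c in manual_cases if c.disposition == FAILED_CHECKLIST]
    reasons = ReportTable(
        "Manual authentication failure reasons", len(failures),
        percent_mode=mode, places=places, partition=False,
    )
    for item, label in REASON_ITEMS:
        n = sum(1 for c in failures if c.items[item].outcome == FAIL)
        pct = percent_format(n, len(failures), places, mode) if failures else "0.00"
        reasons.rows.append(ReportRow(label, n, pct))
    return auto, manual, reasons


def write_report(
    tables: Sequence[ReportTable],
    json_path=None,
    text_path=None,
) -> str:
    text = "\n\n".join(t.to_text() for t in tables)
    if text_path is not None:
        with open(text_path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump([t.to_dict() for t in tables], fh, indent=2)
    return text
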