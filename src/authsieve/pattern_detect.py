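"""Suspicious response-pattern operators used during manual survey review.

Three operators cover the classic careless/fraudulent signatures on Likert
blocks: straight-lining (one long constant run), the high-amplitude zigzag
("Christmas tree") alternation, and pairwise logical conflicts between items
that should agree.  Skipped items are excluded before any run or alternation
arithmetic, so the operators see only the answered subsequence in its original
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .cohort_model import (
    FAIL,
    PASS,
    BaselineRecord,
    CheckResult,
    ThresholdConfig,
    ValidationError,
)


@dataclass
class PatternReport:
    straightline: bool
    straightline_fraction: float
    zigzag: bool
    zigzag_index: float
    conflicts: list["ConflictViolation"] = field(default_factory=list)


def _answered(block: Sequence[int | None]) -> list[int]:
    return [v for v in block if v is not None]


def detect_straightline(
    block: Sequence[int | None], config: ThresholdConfig
) -> tuple[bool, float]:
    """Longest-constant-run fraction of the answered items.

    Returns ``(flagged, fraction)`` where fraction = (longest run of one
    repeated response) / (answered length); flagged iff the fraction reaches
    ``straightline_threshold``.  An all-missing block yields ``(False, 0.0)``.
    """
    values = _answered(block)
    if not values:
        return False, 0.0
    if len(values) < config.pattern_min_items:
        raise ValidationError(
            f"straight-line check needs >= {config.pattern_min_items} answered items, "
            f"got {len(values)}"
        )
    best = run = 1
    for prev, cur in zip(values, values[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    fraction = best / len(values)
    return fraction >= config.straightline_threshold, fraction


def detect_zigzag(block: Sequence[int | None], config: ThresholdConfig) -> tuple[bool, float]:
    """High-amplitude alternation index over the answered items.

    With consecutive answered differences ``d_i``, the index is the fraction of
    adjacent difference pairs ``(d_i, d_{i+1})`` that reverse sign with both
    amplitudes at least half the scale span.  Flagged iff the index reaches
    ``zigzag_threshold``.
    """
    values = _answered(block)
    if len(values) < config.pattern_min_items:
        raise ValidationError(
            f"zigzag check needs >= {config.pattern_min_items} answered items, got {len(values)}"
        )
    diffs = [b - a for a, b in zip(values, values[1:])]
    pairs = list(zip(diffs, diffs[1:]))
    if not pairs:
        return False, 0.0
    half_span = config.scale_span / 2
    hits = sum(
        1
        for d1, d2 in pairs
        if d1 * d2 < 0 and abs(d1) >= half_span and abs(d2) >= half_span
    )
    index = hits / len(pairs)
    return index >= config.zigzag_threshold, index


# ---------------------------------------------------------------------------
# conflict rules
# ---------------------------------------------------------------------------

RULE_KINDS = ("mutually_exclusive", "requires", "max_abs_difference")


@dataclass(frozen=True)
class ConflictRule:
    """A pairwise incompatibility between two items.

    * ``mutually_exclusive`` — violated when both items are answered.
    * ``requires`` — violated when item A is answered but item B is not.
    * ``max_abs_difference`` — violated when both answered and
      ``|value_a - value_b| > param``.
    """

    kind: str
    item_a: str
    item_b: str
    param: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ValidationError(f"unknown conflict-rule kind {self.kind!r}")
        if self.kind == "max_abs_difference" and self.param is None:
            raise ValidationError("max_abs_difference rule needs a param")


@dataclass(frozen=True)
class ConflictViolation:
    rule: ConflictRule
    value_a: int | None
    value_b: int | None


def load_rules(path: str | Path) -> list[ConflictRule]:
    raw = yaml.safe_load(Path(path).read_text()) or []
    return [
        ConflictRule(
            kind=entry["kind"],
            item_a=entry["item_a"],
            item_b=entry["item_b"],
            param=entry.get("param"),
        )
        for entry in raw
    ]


def detect_conflicts(
    responses: Mapping[str, int | None], rules: Sequence[ConflictRule]
) -> list[ConflictViolation]:
    """Every violated rule, with both item values attached.

    Order-invariant in the response mapping; a rule naming an item absent from
    the instrument is a configuration error.
    """
    violations = []
    for rule in rules:
        if rule.item_a not in responses or rule.item_b not in responses:
            missing = rule.item_a if rule.item_a not in responses else rule.item_b
            raise ValidationError(f"conflict rule references unknown item {missing!r}")
        va, vb = responses[rule.item_a], responses[rule.item_b]
        if rule.kind == "mutually_exclusive":
            bad = va is not None and vb is not None
        elif rule.kind == "requires":
            bad = va is not None and vb is None
        else:  # max_abs_difference
            bad = va is not None and vb is not None and abs(va - vb) > rule.param
        if bad:
            violations.append(ConflictViolation(rule, va, vb))
    return violations


def pattern_report(
    baseline: BaselineRecord,
    config: ThresholdConfig,
    rules: Sequence[ConflictRule] = (),
) -> PatternReport:
    sl_hit, sl_frac = False, 0.0
    zz_hit, zz_idx = False, 0.0
    for _, block in baseline.likert_blocks:
        if len(_answered(block)) < config.pattern_min_items:
            continue
        hit, frac = detect_straightline(block, config)
        if frac > sl_frac or (hit and not sl_hit):
            sl_frac = max(sl_frac, frac)
        sl_hit = sl_hit or hit
        hit, idx = detect_zigzag(block, config)
        zz_idx = max(zz_idx, idx)
        zz_hit = zz_hit or hit
    conflicts = detect_conflicts(baseline.items(), rules) if rules else []
    return PatternReport(sl_hit, sl_frac, zz_hit, zz_idx, conflicts)


def pattern_review(
    baseline: BaselineRecord,
    config: ThresholdConfig,
    rules: Sequence[ConflictRule] = (),
) -> CheckResult:
    """Survey review verdict: fail if any block straight-lines or zigzags, or
    any conflict rule is violated; else pass.  A failed review means the
    participant is not enrolled."""
    report = pattern_report(baseline, config, rules)
    reasons = []
    if report.straightline:
        reasons.append(f"straightline fraction {report.straightline_fraction:.2f}")
    if report.zigzag:
        reasons.append(f"zigzag index {report.zigzag_index:.2f}")
    if report.conflicts:
        reasons.append(f"{len(report.conflicts)} conflicting answer pair(s)")
    if reasons:
        return CheckResult(
            "pattern", FAIL, "; ".join(reasons),
            evidence={
                "straightline_fraction": round(report.straightline_fraction, 4),
                "zigzag_index": round(report.zigzag_index, 4),
                "conflicts": [
                    f"{v.rule.kind}({v.rule.item_a},{v.rule.item_b})" for v in report.conflicts
                ],
            },
        )
    return CheckResult("pattern", PASS)
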