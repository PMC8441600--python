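"""Record invariants, CSV round-trips, quarantine behaviour, and the audit log."""

import dataclasses
import json

import pandas as pd
import pytest

from authsieve.cohort_model import (
    AutoDecision,
    AuditLog,
    CheckResult,
    OrphanRecordError,
    SchemaError,
    ThresholdConfig,
    ValidationError,
    read_audit,
    read_cohort,
    read_decisions,
    write_audit,
    write_cohort,
    write_decisions,
)
from authsieve.cohort_model import AUTO_STATUSES
from authsieve.synth_cohort import ArchetypeSpec, generate_cohort


@pytest.fixture()
def small_cohort_dir(tmp_path, config):
    cohort = generate_cohort([ArchetypeSpec("clean", 8)], seed=11, config=config)
    paths = cohort.write(tmp_path)
    return tmp_path, paths, cohort


def test_round_trip_is_lossless(small_cohort_dir, tmp_path, config):
    """Read → write → read preserves every dossier field exactly."""
    base, paths, cohort = small_cohort_dir
    dossiers, lookups, rejects = read_cohort(paths, config)
    assert rejects == []
    assert len(dossiers) == len(cohort.dossiers)

    out = tmp_path / "again"
    paths2 = write_cohort(dossiers, lookups, out, config)
    dossiers2, lookups2, rejects2 = read_cohort(paths2, config)
    assert rejects2 == []
    for a, b in zip(
        sorted(dossiers, key=lambda d: d.participant_id),
        sorted(dossiers2, key=lambda d: d.participant_id),
    ):
        assert dataclasses.asdict(a) == dataclasses.asdict(b)
    assert lookups.geoip == lookups2.geoip
    assert lookups.gazetteer == lookups2.gazetteer


def test_timestamps_are_utc_aware(small_cohort_dir, config):
    _, paths, _ = small_cohort_dir
    dossiers, _, _ = read_cohort(paths, config)
    for d in dossiers:
        for ts in (d.screening.started_at, d.screening.ended_at,
                   d.baseline.started_at, d.baseline.ended_at, d.contact.submitted_at):
            assert ts.tzinfo is not None and ts.utcoffset().total_seconds() == 0


def test_invalid_rows_are_quarantined_not_dropped_silently(small_cohort_dir, config):
    """A baseline row with a wrong slot count lands in the rejects with a
    length diagnostic; its dossier is quarantined too, and valid rows load."""
    base, paths, cohort = small_cohort_dir
    frame = pd.read_csv(paths["baseline"], dtype=str, keep_default_na=False)
    victim = frame.loc[0, "participant_id"]
    frame.loc[0, "rs_01"] = "99"  # Likert value outside the configured scale
    frame.to_csv(paths["baseline"], index=False)

    dossiers, _, rejects = read_cohort(paths, config)
    assert len(dossiers) == len(cohort.dossiers) - 1
    assert any(r.participant_id == victim and "Likert" in r.reason for r in rejects)


def test_missing_column_names_the_column(small_cohort_dir, config):
    _, paths, _ = small_cohort_dir
    frame = pd.read_csv(paths["screening"], dtype=str, keep_default_na=False)
    frame.drop(columns=["hiv_status"]).to_csv(paths["screening"], index=False)
    with pytest.raises(SchemaError, match="hiv_status"):
        read_cohort(paths, config)


def test_orphan_baseline_rows_raise_with_ids(small_cohort_dir, config):
    _, paths, _ = small_cohort_dir
    frame = pd.read_csv(paths["contacts"], dtype=str, keep_default_na=False)
    orphan = frame.loc[0, "participant_id"]
    frame.iloc[1:].to_csv(paths["contacts"], index=False)
    with pytest.raises(OrphanRecordError, match=orphan):
        read_cohort(paths, config)


def test_check_result_requires_reason_on_flag_or_fail():
    with pytest.raises(ValidationError):
        CheckResult("duplicate", "fail")
    assert CheckResult("duplicate", "pass").reason == ""


def test_threshold_config_gate_arithmetic_and_yaml_round_trip(tmp_path):
    config = ThresholdConfig()
    assert (config.subset_fail_min, config.outcome_fail_min) == (17, 44)
    assert (config.subset_flag_min, config.outcome_flag_min) == (22, 50)
    path = tmp_path / "config.yaml"
    config.to_yaml(path)
    assert ThresholdConfig.from_yaml(path) == config
    with pytest.raises(ValidationError):
        ThresholdConfig(min_age=19, max_age=18)
    with pytest.raises(ValidationError):
        ThresholdConfig(subset_fail_frac=0.9, manual_flag_frac=0.8)


def test_write_decisions_round_trip_covers_every_status(tmp_path):
    decisions = [AutoDecision(f"P{i:03d}", status) for i, status in enumerate(AUTO_STATUSES)]
    path = tmp_path / "decisions.csv"
    write_decisions(decisions, path)
    again = read_decisions(path)
    assert [d.status for d in again] == list(AUTO_STATUSES)
    assert len(path.read_text().splitlines()) == len(AUTO_STATUSES) + 1  # header + rows


def test_write_decisions_rejects_duplicate_ids_and_empty_input(tmp_path):
    path = tmp_path / "decisions.csv"
    with pytest.raises(ValidationError):
        write_decisions([], path)
    dupes = [AutoDecision("P1", "duplicate"), AutoDecision("P1", "referred_manual")]
    with pytest.raises(ValidationError, match="P1"):
        write_decisions(dupes, path)


def test_audit_log_appends_json_lines_and_replays(tmp_path):
    path = tmp_path / "audit.jsonl"
    results = [
        ("P1", CheckResult("completion_time", "flag", "too fast")),
        ("P2", CheckResult("duplicate", "pass")),
    ]
    assert write_audit(results, path, run_id="run-a") == 2
    assert write_audit(results, path, run_id="run-b") == 2  # append-only
    lines = read_audit(path)
    assert len(lines) == 4
    assert {line["run_id"] for line in lines} == {"run-a", "run-b"}
    by_run = {}
    for line in lines:
        by_run.setdefault(line["run_id"], []).append(
            (line["participant_id"], line["check_id"], line["outcome"])
        )
    assert by_run["run-a"] == by_run["run-b"]  # identical outcomes per run


def test_empty_audit_stream_writes_empty_file(tmp_path):
    path = tmp_path / "audit.jsonl"
    assert write_audit([], path) == 0
    assert path.read_text() == ""
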