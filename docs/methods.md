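# Methods

This note documents the models, thresholds and design choices behind
`authsieve`, in the order the pipeline runs, and states what the synthetic
cohort does and does not demonstrate.

## Records and conventions

All inputs are UTF-8, comma-delimited text with headers; a missing survey
response is an empty field.  Dates are ISO-8601; timestamps carry a `Z` suffix
and are stored and compared in UTC, so no outcome depends on the host
timezone.  Rows violating type invariants (bad Likert values, wrong slot
counts, malformed timestamps, out-of-vocabulary enums) are quarantined to a
rejects list with row-level diagnostics rather than aborting the batch —
enrollment processing is a recurring bulk job and one bad row must not block
the rest.  A baseline row whose participant id is missing from the contact or
screening table entirely is an orphan and raises, since silently judging a
partial dossier would be worse than stopping.

Likert blocks default to a 1–5 scale (configurable); the baseline instrument
carries a 27-item random-subset block and a 62-item primary-outcome block.

## Canonicalization and matching

Emails are lowercased, trimmed, and (by default) stripped of `+tag` local
parts; phones reduce to a 10-digit key after dropping a leading country code
`1`; names are lowercased with punctuation removed and whitespace collapsed;
street suffixes normalize through a fixed synonym table (st/street, rd/road,
ave/avenue, blvd/boulevard, ln/lane, dr/drive, ct/court).  All canonicalizers
are idempotent.

Matching semantics per field family:

* **exact** on key equality for every family;
* **partial** for names and emails within an edit-distance budget of 1
  (emails: same domain, edits confined to the local part) — small budgets
  bound false positives and are configurable;
* phones, IPs and social handles are exact-only; phone comparison is
  cross-slot (a new primary number matching a registry alternate counts);
* addresses admit the **partial-street** match: street, city, state and zip
  equal with a different house number.

The registry holds canonical contacts of both enrolled participants and prior
(failed) attempts; either blocks re-entry.  Lookups are index-backed (hashed
exact keys; domain blocking for partial emails; street-group blocking for
addresses; a length-filtered scan for partial names below 10 000 entries) and
are required by a property test to equal the quadratic all-pairs comparison.

A **cluster** is declared when at least `cluster_min_size` (default 3)
registry addresses partial-street-match the probe.  The threshold of 3 keeps
two records on one street — ordinary in dense housing — from clustering, while
still firing on every attempt of a coordinated run once three prior records
from that street are on file.

## Automated battery

Every check runs on every dossier and is audited; a single status is then
assigned by precedence: eligibility fail → exact duplicate → foreign IP →
completion-score fail → cluster → referred to manual.  The precedence order
mirrors the reporting order of the automated-status table and resolves
multi-failure records deterministically; flags never exclude on their own.

Specific choices:

* **Age** is civil whole-years (calendar difference, decremented before the
  birthday).  A screener age that disagrees with the age derived from the
  baseline date of birth flags; a DOB up to 31 days in the future is annotated
  "explainable" (a common keying slip) but still flags for human review.
* **IP geolocation** excludes only a *confirmed* non-US baseline IP.  An IP
  absent from the lookup table flags "unknown location" instead of failing —
  an incomplete offline table must not exclude anyone on its own.
* **Completion time** flags strictly below 20 minutes (the instrument is
  designed for ~30) and above a configurable 72-hour ceiling.
* **Completion scores** derive integer gates as `ceil(frac × N)`:
  fail below 17/27 or 44/62 answered; flag below 22/27 or 50/62.
* The eligibility recheck includes a generic boolean quota predicate
  (`quota_ok`) standing in for enrollment-quota rules (e.g. race or region
  quotas) whose internal logic is site-specific; it is configurable off.

The battery judges a batch against the registry snapshot taken when the run
starts, modeling periodic bulk processing.  Within-batch duplicates are
deliberately left to the manual stage's session registry (below), which is
also where they surface in practice when a batch is processed in bulk.

## Manual stage

Cases are worked in participant-id order against a *session registry* (main
registry plus every case already processed this run).  An exact contact match
confirmed before the checklist is worked closes the case as "failed, no
checklist (duplicate)".  Otherwise carried flags pre-populate checklist items
as pending; the mapping sends completion-time flags to the time-stamp item,
age flags to the age item, partial-match flags to the duplicate item,
near-threshold completion flags to the pattern item (near-threshold completion
is precisely the trigger for survey review), social flags to the social item,
and all location-consistency flags (IP-state mismatch, screening-vs-baseline
IP, unknown location, zip mismatch) to the zip/location item.

* **Survey review** runs for any case carrying flags.  Straight-lining is the
  longest-constant-run fraction of answered items (threshold 0.95); the
  "Christmas tree" zigzag is operationalized as the fraction of adjacent
  answered-difference pairs that reverse sign with both amplitudes ≥ half the
  scale span (threshold 0.9); conflicts come from configurable pairwise rules
  (`mutually_exclusive`, `requires`, `max_abs_difference`).  The zigzag index
  is a declared stand-in for a pattern the literature names but does not
  define geometrically; both thresholds are defaults, not reconstructions.
  Blocks with fewer than 10 answered items are skipped.
* **Zip verification** compares the submitted zip with the gazetteer zip for
  the normalized (street, city); a mismatch triggers a similar-address review
  against the registry.  Addresses absent from the gazetteer flag "unknown".
* **Social-media evidence** is modeled as structured profile facts (age,
  gender, location); any contradiction fails the item, corroboration passes
  it, no usable facts leaves it pending.  Participation is not contingent on
  providing a handle — no handle means "not applicable".
* **Email verification**: 30-day response window from issuance, reminders at
  7-day marks (7/14/21/28), expiry on day 31 without a response.  No case is
  enrolled without a verified email; an expired verification fails the case.
* Resolutions marking an item *resolved-explainable* require a free-text note
  (travel and moving are the canonical explanations for location flags),
  preserving the audit trail.

Dispositions partition every manual cohort; failure *reasons* do not — a case
can fail several items, so reason tallies may exceed the failure count.

## Post-enrollment QA

Follow-up waves (3/6/9/12/15 months) re-collect an age or DOB; a reported DOB
wins over an integer age when both are present.  Disagreement with the
baseline DOB flags for a study-team determination.  Alternate phones/emails
collected at follow-up are swept against every other participant's primary
contact keys to catch dual enrollment; the sweep equals a quadratic oracle by
property test.  Discontinuation keeps the participant's canonical contact in
the registry so the same identity can never re-enroll; a `fraud_confirmed`
reason is kept internally and exported under the standard administrative
vocabulary.

## Synthetic cohort

The generator's default mix *is* the study condition the pipeline is tested
against: 1224 baseline-starting dossiers composed of 30 quota failures + 2
HIV-positive records, 177 exact registry duplicates (cycling the six field
families), 8 foreign-IP records, 126 + 126 low-completion records (subset /
outcome side), 23 street-cluster attempts, and 732 referral-stage records —
540 clean, 30 IP-state mismatches resolved as travel, 30 slow outliers
resolved as interruptions (600 enrolled); 9 within-batch exact duplicates; and
123 checklist failures planted so the (overlapping) reason tallies are 33 time
stamp, 20 age, 28 duplicate, 33 pattern and 20 social — 11 records carry two
reasons (5 speeder+straight-liner, 3 age+partial-duplicate,
3 partial-duplicate+social).  The splits within aggregate categories
(126/126, 540/30/30, the double-reason composition) are this package's own
choices where only the aggregates are published.

Mechanics worth knowing:

* Identities come from deterministic word lists keyed by the seed; no real
  personal data is generated.  Name and email codes carry a check digit so
  distinct synthetic identities are always ≥ 2 edits apart — one-edit partial
  matches occur only where planted.
* The registry (200 prior/enrolled contacts) includes three seeded
  Wisteria-street entries — the enrolled household and two recorded attempts
  by the same actor, who reused the household's secondary phone — so every
  batch attempt from that street immediately sees ≥ 3 partial-street matches
  and clusters.  The cluster attempts themselves share no exact key with the
  registry, keeping `duplicate` and `cluster_case` disjoint under precedence.
* Pattern archetypes are planted with near-threshold completion counts,
  which is what routes an otherwise-unflagged record into survey review.
* Every generated IP is present in the geo-IP table with the country/state
  its archetype requires, and every address is gazetteered with its own zip.
* Per-case manual evidence (social profile facts, email response day, item
  resolutions) is generated alongside the cohort; truth labels are written to
  `truth.csv` and never read by the pipeline.

What passing tests show: the pipeline recovers 100 % of planted labels under
the default configuration, with zero false positives on all-clean cohorts of
10 000 records.  What they do not show: performance on real survey data —
real careless responding is noisier than the planted patterns, real contact
data contains legitimate near-duplicates (households, institutional IPs,
shared devices), and the generator does not model strategic adversaries who
adapt to the checks.  The specificity result in particular holds only because
clean synthetic identities are constructed to be well separated.

## Reporting

Percent strings are computed on exact rationals and rendered under two
conventions — round-half-up and truncation — because published enrollment
reports mix both (e.g. a stage percentage printed as 92.44 is a truncation of
92.447…, while 20.59 is rounded); each table pins its convention explicitly
rather than silently normalizing.  Funnel percentages use the conventional
stage-over-stage denominators.  Default funnel counts (19 709 visitors →
13 931 screened → 3 253 eligible → 2 544 consented → 1 324 contact-verified →
1 224 started baseline) match the enrollment flow the default cohort models.

## Problem sizes and determinism

The default cohort (1224 records, 203-entry registry) runs both stages in a
few seconds; the specificity test uses 10 000 clean records and the oracle-
equivalence tests use 500-record cohorts — sizes chosen so the whole suite
exercises every code path at desk scale.  All randomness flows from a single
`random.Random(seed)`; identical (specs, seed, config) triples produce
byte-identical output files, and the planted composition — hence every
reported count — is invariant to the seed itself.

## Known limitations

* GeoIP and gazetteer are offline lookup tables; there is no proxy/VPN
  detection and no live geocoding.
* Social-media review consumes structured evidence records; there is no
  platform access.
* Partial matching is edit-distance based; no phonetic encodings or
  probabilistic (Fellegi–Sunter) linkage.
* The checklist models the six published reason categories plus the zip
  check; site-specific checklist items would extend the enum.
* Batch scheduling is modeled as a single run; the session registry stands in
  for the within-batch ordering effects of recurring runs.
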