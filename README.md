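# authsieve

A two-stage participant-authentication pipeline for fully web-based study
enrollment, built for trials that recruit online and must weed out fraudulent,
duplicate, bot and ineligible enrollment attempts before randomization.  It is
aimed at study data managers and methodologists who need an auditable,
deterministic implementation of the standard playbook: an automated
(electronic) battery that excludes the clear-cut cases in bulk, followed by a
checklist-driven manual review for everything the battery merely flags.

## The pipeline

Each enrollment attempt is a **dossier**: the joined contact-information,
screening-survey and baseline-questionnaire records for one participant.  The
**automated battery** runs six check families on every dossier and assigns a
single mutually exclusive status by precedence:

1. *eligibility recheck* — age within [13, 18], assigned-male and identifying
   as a man, same-sex attracted, not HIV-positive, region/quota predicates;
2. *duplicate search* — exact and partial matches of canonicalized name,
   email, phone (cross-slot: primary vs alternates), mailing address, social
   handle and IP against a registry of prior attempts and enrolled
   participants;
3. *IP geolocation* — baseline IP outside the US excludes; state
   inconsistencies (IP vs mailing address, screening vs baseline IP) flag;
4. *completion scores* — answered-item gates on a 27-item random subset and a
   62-item primary-outcome block: hard fail below ceil(0.60·27) = 17 or
   ceil(0.70·62) = 44 answered, manual-review flag below the 80 % band
   (22 / 50);
5. *address clusters* — ≥ 3 registry addresses matching on street/city/state/
   zip with different house numbers (the "same street, new house number"
   fraud signature);
6. everything else is **referred to manual review**, carrying its flags.

The **manual stage** works each referred case through a six-item checklist
(time stamp, age comparison, duplicate check, survey pattern review,
social-media check, zip check).  Flags become pending items; pending items are
resolved pass / fail / *resolved-explainable* (with a mandatory note); survey
review applies straight-lining, high-amplitude zigzag ("Christmas tree") and
conflict-rule detectors; enrollment additionally requires an email
verification completed within a 30-day window with weekly reminders.  Cases
end as *enrolled*, *failed checklist*, or *failed, no checklist (duplicate)*
for within-batch duplicates caught before the checklist is worked.

A seeded **synthetic-cohort generator** plants labeled anomaly archetypes
(each violating exactly one check) and emits the matching registry, geo-IP and
gazetteer lookup tables, and manual-review evidence, so the whole pipeline is
testable end to end with exact expected outcomes.

## Worked example

```bash
authsieve synth  --seed 20210831 --out cohort
authsieve auto   --in cohort --registry cohort/registry.csv \
                 --config cohort/config.yaml --out decisions.csv --audit audit.jsonl
authsieve manual --in cohort --decisions decisions.csv \
                 --registry cohort/registry.csv --evidence cohort/manual_evidence.csv \
                 --rules cohort/rules.yaml --config cohort/config.yaml \
                 --out manual_cases.csv --audit audit.jsonl
authsieve report --decisions decisions.csv --cases manual_cases.csv
```

prints

```
Automated authentication status (N=1224)
  Failed eligibility recheck                      32  (2.61%)
  Duplication or already enrolled                177  (14.46%)
  IP address outside the United States             8  (0.65%)
  Failed completion score requirements           252  (20.59%)
  Address-cluster case attempts                   23  (1.88%)
  Passed, referred to manual authentication      732  (59.80%)

Manual authentication status (N=732)
  Failed, no checklist completed (duplicate)        9  (1.23%)
  Failed manual checklist and removed             123  (16.80%)
  Passed and enrolled                             600  (81.97%)

Manual authentication failure reasons (N=123)
  Time stamp fail                                 33  (26.83%)
  Age comparison screener and baseline fail       20  (16.26%)
  Duplicate check fail                            28  (22.76%)
  Suspicious pattern survey response fail         33  (26.83%)
  Social media check fail (if provided)           20  (16.26%)
```

Of 1224 attempts that started the baseline questionnaire, the automated
battery excludes 492 and refers 732; the manual stage removes another 132
(9 late duplicates + 123 checklist failures) and enrolls 600.  In total
624 attempts are prevented from enrolling, 492/624 ≈ 79 % of them by the
automated stage alone.  Failure reasons in the third table are not mutually
exclusive — a case can fail on several checklist items at once.

## Layout

| Module | Role |
| --- | --- |
| `authsieve.cohort_model` | record types, thresholds, CSV/JSONL readers & writers, audit log |
| `authsieve.matching` | contact canonicalization, exact/partial matching, registry, clusters |
| `authsieve.auto_battery` | the automated checks and the status precedence rule |
| `authsieve.pattern_detect` | straight-line, zigzag and conflict-rule survey review |
| `authsieve.manual_review` | checklist lifecycle, zip/social/email verification, dispositions |
| `authsieve.qa_followup` | post-enrollment age checks, alternate-contact sweeps, discontinuation |
| `authsieve.synth_cohort` | seeded generator of labeled synthetic cohorts and lookup tables |
| `authsieve.report` / `authsieve.cli` | funnel & status tables, percent conventions, CLI |

See `docs/methods.md` for the modeling decisions, thresholds and limitations.
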