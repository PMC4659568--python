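# Methods

## The linkage procedure

`steplink` implements deterministic relaxation matching between two
patient tables that share no direct identifier. Each record is reduced to
a six-variable key *(site, gender, birth year, birth month, event year,
event month)*; the event is the effective enrollment date on the trial
side (the transfer date supersedes the enrollment date when present,
because a transferred patient first appears at the linked hospital on
transfer, not on enrollment) and the index admission date on the
administrative side.

The cascade runs an ordered list of steps, each a comparison rule for the
event date only — the four demographic variables are blocking variables
compared exactly at every step. Within a step, a trial record's candidate
set is every available administrative patient whose key agrees under the
step's rule. Classification is:

* 0 candidates → `NO_MATCH`;
* ≥2 candidates → `MULTIPLE_ADMIN` (forward ambiguity takes precedence:
  such a record is never reclassified by reverse contention);
* exactly 1 candidate claimed by ≥2 available trial records →
  `MULTIPLE_TRIAL` for all claimants;
* exactly 1 uncontested candidate → `UNIQUE`.

Unique pairs are removed from both sides before the next step. Removing
the administrative patient as well as the trial record (not just the
trial side) is what guarantees the final assignment is injective — one
administrative patient can never be linked to two trial patients.
Ambiguous groups are never auto-resolved by any closeness score; they
simply carry forward, since the procedure is deliberately score-free.

The default schedule relaxes event month, then event year, then restores
the year within a ±1 calendar-year tolerance (|2008 − 2007| = 1,
not day-count arithmetic). On this schedule the per-record candidate sets
nest as step 1 ⊆ step 2 ⊆ step 4 ⊆ step 3, which implies a record with no
step-3 candidates can never match at step 4 — the test suite checks this
monotonicity directly. The schedule is configuration data
(`default_steps.yaml`), so ±k tolerances or ablated schedules can be run
without code changes; the only structural constraint is that a step
comparing the event month exactly must also compare the year exactly.

Records missing a matching field (e.g. unknown gender) are classified
`NO_MATCH` at every step with a logged warning, rather than aborting the
run: this keeps the per-step accounting identity
`available = unique + no_match + multiple_admin + multiple_trial` intact
for every input.

## Cohort construction

The administrative side is first restricted to admissions inside the
closed trial window carrying at least one ICD-9-CM code with three-digit
root 205, 206, 207 or 208 (myeloid and unspecified leukemias; malformed
code strings are warned about and treated as non-qualifying). Qualifying
admissions are then collapsed to one **index record** per
(site, encrypted patient id) — the earliest qualifying admission — so
matching is patient-level and "multiple admin matches" means multiple
distinct patients, not repeat admissions of one patient. When a patient's
admissions disagree on demographics, the earliest admission's values win,
with a warning. Matching on the index admission (rather than any
admission in the window) is a design choice: the index admission is the
natural administrative analogue of trial enrollment for a condition whose
first admission follows diagnosis closely.

## The direct comparator and concordance

The direct merge matches exactly on (full birth date, site, gender) in a
single pass, with the same unique / no-match / duplicates / contested
classification. It requires full birth dates and raises a `DialectError`
on indirect-only tables (birth year/month only). For each unique indirect
match, Criterion 1 counts concordance only against a unique direct match
to the same patient; Criterion 2 additionally counts an indirect match
contained in the direct merge's duplicate set. A direct `NO_MATCH` or a
contested direct candidate counts as discordant under both criteria — the
conservative choice, and the one that makes "C2 ≥ C1" provable for every
step and cumulatively. Concordance proportions are reported among that
step's unique matches, per step and cumulatively.

## The synthetic-data generator

`simulate_pair` emulates the matching-relevant structure of a pediatric
AML trial linked to a children's-hospital admissions database. Defaults
(chosen once as the package's study conditions):

| parameter | default | meaning |
|---|---|---|
| `n_trial` | 415 | enrolled patients at linked hospitals |
| `n_sites` | 44 | participating hospitals |
| `window` | 2006-08-14 … 2010-06-15 | trial enrollment window |
| `p_captured` | 0.95 | probability a trial patient appears in the admissions table |
| `n_distractors` | 200 | non-trial leukemia patients in the admissions table |
| `p_transfer` | 0.05 | probability of a transfer-date record (transfer 1–45 d after enrollment) |
| `admission_lag_days` | 0–21 | uniform lag from effective enrollment to admission |
| `p_gross_error` | 0.05 | probability the admission year and/or month is re-drawn at random |
| `p_collision` | 0.01 | probability a patient receives another patient's blocking key |
| `birth_year_range` | 1988–2005 | pediatric cohort, all births precede the window |
| `p_readmission` | 0.35 | probability of a second, later admission (exercises index derivation) |

Date discrepancies arise from two mechanisms, mirroring how they arise in
practice: a benign admission **lag** that can cross month or year
boundaries naturally, and **gross re-draws** of the recorded year and/or
month emulating data-entry errors in the administrative source. Both are
modest by default; the gross-error draws are consumed from the random
stream whether or not they apply, so two runs differing only in
`p_gross_error` share common random numbers and differ only on the
corrupted records — this is what makes "more noise never helps step 1,
and steps 2–4 recover the losses" testable as a coupled comparison.

Blocking keys are sampled **without replacement** across all generated
patients (trial and distractor): the collision rate is an experimental
condition fully controlled by `p_collision`, never a sampling accident.
This is a deliberate departure from fully independent demographics — it
makes "zero collisions" exactly realizable, so perfect-recovery
properties (sensitivity = PPV = 1 with no noise and no collisions) are
sharp rather than probabilistic. The corresponding limitation is stated
below. A config whose patient count exceeds the key space, or whose birth
years reach into the window, is rejected as infeasible. Everything is
reproducible from `seed`; truth links are written to a separate file the
matcher never reads.

What the generator does **not** emulate: real AML incidence or hospital
volumes; seasonality of admissions; missing-not-at-random demographics;
site-coding disagreements between sources (site harmonization is assumed
upstream); and — by the design above — *accidental* demographic
collisions, which in real data make coarse identifiers "not unique
enough" at rates the analyst does not control. Passing tests therefore
demonstrate the algorithm's correctness and its recovery behavior under
the stated noise model, not the unique-match rate to expect on any
particular real cohort; with more prevalent diseases or larger cohorts,
collision rates (and hence multiple matches) would be materially higher.

## Evaluation against truth

Against simulation ground truth, **sensitivity** is correct unique
matches over truly captured trial records (uncaptured patients cannot be
matched, so the capture rate is deliberately excluded from the
denominator) and **PPV** is correct unique matches over all unique
matches, defined as 1 when there are no unique matches; sensitivity is
reported as NA when nothing was captured.

## Numerical and reporting choices

Percentages are rendered to one decimal place; within-step percentages
use that step's available count, cumulative percentages the initial
count, and zero denominators render as `NA`. Rendered tables recompute
all percentages from raw counts at render time. The JSON report is
versioned (`schema_version`). Fitting sorts both tables by identifier
before classification, so results are invariant to input row order; all
comparison rules are symmetric, so swapping the roles of the two tables
yields the same linked pairs.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data:
the acceptance script uses the default conditions above (415 trial
records, ~590 administrative patients); the property suites use hundreds
of small randomized instances (≤30 records per side) cross-checked
against an independent brute-force oracle, and 1,000 randomized
small-cohort simulations for the accounting identities.

## Known limitations

* Deterministic equality only: no probabilistic (Fellegi–Sunter) scoring,
  no string-distance comparators, no race/insurance matching.
* Follow-up admissions after the index match are out of scope.
* Ambiguous groups are reported, never adjudicated.
* The direct comparator needs full birth dates; indirect-only tables can
  run the cascade but not the concordance analysis.
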