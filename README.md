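# steplink

Deterministic, stepwise record linkage on **indirect patient identifiers**,
for merging a clinical-trial roster with an administrative
hospital-admissions database when direct identifiers (full date of birth)
cannot be shared.

## The problem

Cooperative-group oncology trials carry rich clinical detail (diagnosis,
risk group, outcomes) but no resource-utilization or cost data;
administrative hospital databases carry the opposite. Linking the two
enables comparative- and cost-effectiveness research, but sharing direct
identifiers raises privacy and regulatory barriers. `steplink` links the
two sources using only six coarse variables:

> treatment site, gender, birth **year**, birth **month**,
> event **year**, event **month**

where the "event" is the trial enrollment date (replaced by the transfer
date for patients who transferred into a participating hospital) on one
side and the index — earliest qualifying — admission on the other.

## The algorithm

Matching is a strict-to-loose cascade. Site, gender, birth year and birth
month must agree exactly at every step; the steps relax only the event
date:

| step | event year | event month |
|------|-----------|-------------|
| 1    | exact     | exact       |
| 2    | exact     | ignored     |
| 3    | ignored   | ignored     |
| 4    | within ±1 | ignored     |

At each step every still-unmatched trial record is classified as a
**unique match** (exactly one agreeing administrative patient, contested
by no other trial record), **no match**, **multiple admin matches**
(forward ambiguity), or **multiple trial matches** (two or more trial
records claiming the same sole candidate). Uniquely matched patients on
both sides are removed before the next step, so the final assignment is
one-to-one.

A **direct merge** comparator (exact match on full date of birth, site,
gender) supports two concordance criteria for the indirect uniques:
Criterion 1 counts a unique indirect match as concordant only when the
direct merge uniquely found the same patient; Criterion 2 additionally
credits it when the direct merge returned a duplicate set containing that
patient.

Because real trial and claims tables are protected health data, the
package includes a synthetic cohort generator
(`steplink.simulate.simulate_pair`) producing a trial roster, an
admissions table (pediatric AML ICD-9 cohort: codes 205.xx–208.xx), and
the ground-truth links, with controllable capture rate, admission lag,
gross date-error rate and blocking-key collision rate — so sensitivity and
PPV of the cascade are measurable against known truth.

## Worked example

```python
import steplink as sl

trial, admissions, truth, _ = sl.make_worked_fixture()
index = sl.derive_index_records(admissions)      # one record per patient

result = sl.StepwiseLinkage(trial, index).fit()  # indirect cascade
direct = sl.DirectLinkage(trial, index).fit()    # DOB comparator
summaries = [sl.concordance(result, direct, c) for c in ("C1", "C2")]
print(result.summary(concordance=summaries).to_text())
```

```
                                                  Step 1      Step 2      Step 3      Step 4
Patients available for match                           5           4           3           2
Unique match, n (%)                            1 (20.0%)   1 (25.0%)   1 (33.3%)   1 (50.0%)
No match, n (%)                                4 (80.0%)   3 (75.0%)   1 (33.3%)   1 (50.0%)
Multiple admin matches, n (%)                   0 (0.0%)    0 (0.0%)   1 (33.3%)    0 (0.0%)
Multiple trial matches, n (%)                   0 (0.0%)    0 (0.0%)    0 (0.0%)    0 (0.0%)
Cumulative unique matches, n (%)               1 (20.0%)   2 (40.0%)   3 (60.0%)   4 (80.0%)
Criterion 1: concordant among uniques, n (%)  1 (100.0%)  1 (100.0%)  1 (100.0%)  1 (100.0%)
Criterion 1: cumulative concordant, n (%)     1 (100.0%)  2 (100.0%)  3 (100.0%)  4 (100.0%)
Criterion 2: concordant among uniques, n (%)  1 (100.0%)  1 (100.0%)  1 (100.0%)  1 (100.0%)
Criterion 2: cumulative concordant, n (%)     1 (100.0%)  2 (100.0%)  3 (100.0%)  4 (100.0%)
```

The five fixture patients illustrate each mechanism: patient A agrees on
all six variables (step 1); B's admission month differs (recovered at
step 2); C's admission year is off by three (step 3); D's is off by one
and a demographic look-alike makes D ambiguous at step 3 but unique at
step 4 when ±1 year excludes the look-alike; E never appears in the
admissions table. The per-record history:

```
trial_id admin_id matched_step classification_history
       A       PA            1                      U
       B       PB            2                    N;U
       C       PC            3                  N;N;U
       D       PD            4               N;N;MA;U
       E                                      N;N;N;N
```

Cumulative unique matches: 4/5 (80.0%), all concordant with the direct
merge under both criteria.

## Command line

```bash
steplink simulate --seed 7 --out-trial trial.csv --out-admin admin.csv --out-truth truth.csv
steplink match --trial trial.csv --admin admin.csv \
    --window-start 2006-08-14 --window-end 2010-06-15 --out matches.csv
steplink concordance --trial trial.csv --admin admin.csv --out concordance.json
steplink evaluate --trial trial.csv --admin admin.csv --truth truth.csv --out metrics.json
steplink pipeline --config config.yaml --out-dir out --seed 7
```

The step schedule is data, not code: pass `--steps my_steps.yaml` to any
matching command (the shipped default, `steplink/default_steps.yaml`,
encodes the four-step schedule above).

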